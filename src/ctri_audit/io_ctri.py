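"""Readers and writers: record-page HTML, SQLite registries, report export.

The HTML dialect is the fixture dialect this package itself renders (a
field-label/value table plus one table each for sites and ethics
committees); live registry layout drift is out of scope — reproducibility
over scraping.  The SQLite schema mirrors the audited field set with child
tables for sites, committees and unrecognized extras, and the loader accepts
a column-mapping so databases with renamed columns can be adapted.
"""

from __future__ import annotations

import csv
import html as _html
import json
import sqlite3
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import lxml.html

from .record_model import (
    AuditReport,
    EthicsCommittee,
    Site,
    TrialRecord,
    parse_date_permissive,
    parse_phase,
    parse_sample_size,
    parse_type_of_trial,
)
from .temporal_audit import format_rate


class ParseError(ValueError):
    """Raised when a document cannot be interpreted as a CTRI record."""


class SchemaError(ValueError):
    """Raised when a registry database lacks an expected table or column."""


# ---------------------------------------------------------------------------
# HTML fixture dialect

FIELD_LABELS: dict[str, str] = {
    "ctri_number": "CTRI Number",
    "registered_on": "Registered on",
    "type_of_study_raw": "Type of Study",
    "type_of_trial": "Type of Trial",
    "phase": "Phase of Trial",
    "countries": "Countries of Recruitment",
    "recruit_status_global": "Recruitment Status of Trial (Global)",
    "recruit_status_india": "Recruitment Status of Trial (India)",
    "date_first_enroll_global": "Date of First Enrollment (Global)",
    "date_first_enroll_india": "Date of First Enrollment (India)",
    "total_sample_size": "Total Sample Size",
    "sample_size_india": "Sample Size from India",
    "pi_name": "Name of Principal Investigator",
    "sponsor_name": "Name of Primary Sponsor",
    "sponsor_classification": "Type of Sponsor",
    "public_title": "Public Title of Study",
    "scientific_title": "Scientific Title of Study",
}
_LABEL_TO_FIELD = {v: k for k, v in FIELD_LABELS.items()}


def _cell(value: Optional[str]) -> str:
    return _html.escape(value if value is not None else "")


def render_record_html(record: TrialRecord) -> str:
    """Render one record as a fixture-dialect HTML page.

    ``parse_record_html(render_record_html(r))`` is the identity on all
    audited fields.
    """
    rows = []

    def add(label: str, value: Optional[str]) -> None:
        rows.append(f"<tr><td>{_cell(label)}</td><td>{_cell(value)}</td></tr>")

    add(FIELD_LABELS["ctri_number"], record.ctri_number)
    add(FIELD_LABELS["registered_on"],
        record.registered_on.isoformat() if record.registered_on else None)
    add(FIELD_LABELS["type_of_study_raw"], record.type_of_study_raw)
    add(FIELD_LABELS["type_of_trial"],
        record.type_of_trial.value if record.type_of_trial else None)
    add(FIELD_LABELS["phase"], record.phase.value if record.phase else None)
    add(FIELD_LABELS["countries"], ", ".join(sorted(record.countries)))
    add(FIELD_LABELS["recruit_status_global"], record.recruit_status_global)
    add(FIELD_LABELS["recruit_status_india"], record.recruit_status_india)
    add(FIELD_LABELS["date_first_enroll_global"],
        record.date_first_enroll_global.isoformat() if record.date_first_enroll_global else None)
    add(FIELD_LABELS["date_first_enroll_india"],
        record.date_first_enroll_india.isoformat() if record.date_first_enroll_india else None)
    add(FIELD_LABELS["total_sample_size"],
        str(record.total_sample_size) if record.total_sample_size is not None else None)
    add(FIELD_LABELS["sample_size_india"],
        str(record.sample_size_india) if record.sample_size_india is not None else None)
    add(FIELD_LABELS["pi_name"], record.pi_name)
    add(FIELD_LABELS["sponsor_name"], record.sponsor_name)
    add(FIELD_LABELS["sponsor_classification"], record.sponsor_classification)
    add(FIELD_LABELS["public_title"], record.public_title)
    add(FIELD_LABELS["scientific_title"], record.scientific_title)
    for key, value in record.extras.items():
        add(key, value)

    site_rows = "".join(
        f"<tr><td>{_cell(s.institution_name)}</td><td>{_cell(s.city)}</td>"
        f"<td>{_cell(s.state)}</td><td>{_cell(s.country)}</td></tr>"
        for s in record.sites
    )
    ec_rows = "".join(
        f"<tr><td>{_cell(e.name)}</td><td>{_cell(e.affiliation)}</td>"
        f"<td>{_cell(e.address)}</td></tr>"
        for e in record.ethics_committees
    )
    return (
        "<!DOCTYPE html>\n<html><head><title>"
        f"{_cell(record.ctri_number)}</title></head><body>\n"
        f'<table class="fields">\n{"".join(rows)}\n</table>\n'
        '<table class="sites">\n'
        "<tr><th>Name of Institution</th><th>City</th><th>State</th><th>Country</th></tr>"
        f"{site_rows}\n</table>\n"
        '<table class="ethics">\n'
        "<tr><th>Name of Committee</th><th>Affiliation</th><th>Address</th></tr>"
        f"{ec_rows}\n</table>\n</body></html>\n"
    )


def _text(node) -> Optional[str]:
    value = node.text_content().strip()
    return value if value else None


def parse_record_html(document: str) -> TrialRecord:
    """Parse one fixture-dialect record page into a :class:`TrialRecord`.

    Raw text is kept verbatim for the free-text fields; typed fields are
    parsed permissively with malformed values kept as missing.  A document
    without a CTRI registration number is a hard parse error; unknown field
    labels are preserved in ``extras``.
    """
    try:
        tree = lxml.html.fromstring(document)
    except (lxml.etree.ParserError, ValueError) as exc:
        raise ParseError(f"not an HTML document: {exc}") from exc

    fields: dict[str, Optional[str]] = {}
    extras: dict[str, str] = {}
    fields_table = tree.find_class("fields")
    if not fields_table:
        raise ParseError("document lacks the field table")
    for row in fields_table[0].iter("tr"):
        cells = row.findall("td")
        if len(cells) != 2:
            continue
        label = (cells[0].text_content() or "").strip()
        value = _text(cells[1])
        if label in _LABEL_TO_FIELD:
            fields[_LABEL_TO_FIELD[label]] = value
        elif label and value is not None:
            extras[label] = value

    ctri_number = fields.get("ctri_number")
    if not ctri_number:
        raise ParseError("document lacks a CTRI registration number")

    sites = []
    for table in tree.find_class("sites"):
        for row in table.iter("tr"):
            cells = row.findall("td")
            if len(cells) == 4:
                sites.append(Site(*(_text(c) for c in cells)))
    committees = []
    for table in tree.find_class("ethics"):
        for row in table.iter("tr"):
            cells = row.findall("td")
            if len(cells) == 3:
                name, affiliation, address = (_text(c) for c in cells)
                if name:
                    committees.append(EthicsCommittee(name, affiliation, address))

    countries_raw = fields.get("countries")
    countries = frozenset(
        c.strip() for c in (countries_raw or "").split(",") if c.strip()
    )
    return TrialRecord(
        ctri_number=ctri_number,
        registered_on=parse_date_permissive(fields.get("registered_on")),
        type_of_study_raw=fields.get("type_of_study_raw"),
        type_of_trial=parse_type_of_trial(fields.get("type_of_trial")),
        phase=parse_phase(fields.get("phase")),
        countries=countries,
        recruit_status_global=fields.get("recruit_status_global"),
        recruit_status_india=fields.get("recruit_status_india"),
        date_first_enroll_global=parse_date_permissive(fields.get("date_first_enroll_global")),
        date_first_enroll_india=parse_date_permissive(fields.get("date_first_enroll_india")),
        total_sample_size=parse_sample_size(fields.get("total_sample_size")),
        sample_size_india=parse_sample_size(fields.get("sample_size_india")),
        pi_name=fields.get("pi_name"),
        sponsor_name=fields.get("sponsor_name"),
        sponsor_classification=fields.get("sponsor_classification"),
        sites=tuple(sites),
        ethics_committees=tuple(committees),
        public_title=fields.get("public_title"),
        scientific_title=fields.get("scientific_title"),
        extras=extras,
    )


# ---------------------------------------------------------------------------
# SQLite registry

#: logical field -> column name in the trials table; pass a modified copy to
#: ``load_registry_sqlite`` to adapt a database with renamed columns.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "ctri_number": "ctri_number",
    "registered_on": "registered_on",
    "type_of_study_raw": "type_of_study",
    "type_of_trial": "type_of_trial",
    "phase": "phase",
    "countries": "countries",
    "recruit_status_global": "recruit_status_global",
    "recruit_status_india": "recruit_status_india",
    "date_first_enroll_global": "date_first_enroll_global",
    "date_first_enroll_india": "date_first_enroll_india",
    "total_sample_size": "total_sample_size",
    "sample_size_india": "sample_size_india",
    "pi_name": "pi_name",
    "sponsor_name": "sponsor_name",
    "sponsor_classification": "sponsor_classification",
    "public_title": "public_title",
    "scientific_title": "scientific_title",
}

_SCHEMA = """
CREATE TABLE IF NOT EXISTS trials (
    ctri_number TEXT PRIMARY KEY,
    registered_on TEXT,
    type_of_study TEXT,
    type_of_trial TEXT,
    phase TEXT,
    countries TEXT,
    recruit_status_global TEXT,
    recruit_status_india TEXT,
    date_first_enroll_global TEXT,
    date_first_enroll_india TEXT,
    total_sample_size INTEGER,
    sample_size_india INTEGER,
    pi_name TEXT,
    sponsor_name TEXT,
    sponsor_classification TEXT,
    public_title TEXT,
    scientific_title TEXT
);
CREATE TABLE IF NOT EXISTS sites (
    ctri_number TEXT NOT NULL,
    position INTEGER NOT NULL,
    institution_name TEXT,
    city TEXT,
    state TEXT,
    country TEXT
);
CREATE TABLE IF NOT EXISTS ethics_committees (
    ctri_number TEXT NOT NULL,
    position INTEGER NOT NULL,
    name TEXT NOT NULL,
    affiliation TEXT,
    address TEXT
);
CREATE TABLE IF NOT EXISTS extras (
    ctri_number TEXT NOT NULL,
    key TEXT NOT NULL,
    value TEXT
);
"""


def _check_schema(conn: sqlite3.Connection, column_map: Mapping[str, str]) -> None:
    tables = {
        row[0] for row in conn.execute("SELECT name FROM sqlite_master WHERE type='table'")
    }
    for table in ("trials", "sites", "ethics_committees"):
        if table not in tables:
            raise SchemaError(f"missing table: {table}")
    columns = {row[1] for row in conn.execute("PRAGMA table_info(trials)")}
    for logical, column in column_map.items():
        if column not in columns:
            raise SchemaError(f"missing column: trials.{column}")


def write_registry_sqlite(records: Iterable[TrialRecord], path: str | Path) -> None:
    """Write records to a registry database (lossless for audited fields)."""
    conn = sqlite3.connect(path)
    try:
        conn.executescript(_SCHEMA)
        for r in records:
            conn.execute(
                "INSERT OR REPLACE INTO trials VALUES (?,?,?,?,?,?,?,?,?,?,?,?,?,?,?,?,?)",
                (
                    r.ctri_number,
                    r.registered_on.isoformat() if r.registered_on else None,
                    r.type_of_study_raw,
                    r.type_of_trial.value if r.type_of_trial else None,
                    r.phase.value if r.phase else None,
                    "|".join(sorted(r.countries)),
                    r.recruit_status_global,
                    r.recruit_status_india,
                    r.date_first_enroll_global.isoformat() if r.date_first_enroll_global else None,
                    r.date_first_enroll_india.isoformat() if r.date_first_enroll_india else None,
                    r.total_sample_size,
                    r.sample_size_india,
                    r.pi_name,
                    r.sponsor_name,
                    r.sponsor_classification,
                    r.public_title,
                    r.scientific_title,
                ),
            )
            conn.execute("DELETE FROM sites WHERE ctri_number = ?", (r.ctri_number,))
            conn.execute(
                "DELETE FROM ethics_committees WHERE ctri_number = ?", (r.ctri_number,)
            )
            conn.execute("DELETE FROM extras WHERE ctri_number = ?", (r.ctri_number,))
            for i, site in enumerate(r.sites):
                conn.execute(
                    "INSERT INTO sites VALUES (?,?,?,?,?,?)",
                    (r.ctri_number, i, site.institution_name, site.city, site.state, site.country),
                )
            for i, ec in enumerate(r.ethics_committees):
                conn.execute(
                    "INSERT INTO ethics_committees VALUES (?,?,?,?,?)",
                    (r.ctri_number, i, ec.name, ec.affiliation, ec.address),
                )
            for key, value in r.extras.items():
                conn.execute(
                    "INSERT INTO extras VALUES (?,?,?)", (r.ctri_number, key, value)
                )
        conn.commit()
    finally:
        conn.close()


def load_registry_sqlite(
    path: str | Path, column_map: Optional[Mapping[str, str]] = None
) -> list[TrialRecord]:
    """Load a registry database into typed records.

    The loaded record count equals the row count of the trials table; a
    missing table or column raises :class:`SchemaError` naming the first
    missing element.
    """
    if not Path(path).exists():
        raise FileNotFoundError(path)
    column_map = dict(column_map or DEFAULT_COLUMN_MAP)
    conn = sqlite3.connect(path)
    conn.row_factory = sqlite3.Row
    try:
        _check_schema(conn, column_map)
        tables = {
            row[0] for row in conn.execute("SELECT name FROM sqlite_master WHERE type='table'")
        }
        sites_by_id: dict[str, list[Site]] = {}
        for row in conn.execute(
            "SELECT * FROM sites ORDER BY ctri_number, position"
        ):
            sites_by_id.setdefault(row["ctri_number"], []).append(
                Site(row["institution_name"], row["city"], row["state"], row["country"])
            )
        ecs_by_id: dict[str, list[EthicsCommittee]] = {}
        for row in conn.execute(
            "SELECT * FROM ethics_committees ORDER BY ctri_number, position"
        ):
            ecs_by_id.setdefault(row["ctri_number"], []).append(
                EthicsCommittee(row["name"], row["affiliation"], row["address"])
            )
        extras_by_id: dict[str, dict[str, str]] = {}
        if "extras" in tables:
            for row in conn.execute("SELECT * FROM extras"):
                extras_by_id.setdefault(row["ctri_number"], {})[row["key"]] = row["value"]

        records = []
        cm = column_map
        for row in conn.execute(f"SELECT * FROM trials ORDER BY {cm['ctri_number']}"):
            ctri = row[cm["ctri_number"]]
            countries_raw = row[cm["countries"]] or ""
            total = row[cm["total_sample_size"]]
            india = row[cm["sample_size_india"]]
            records.append(
                TrialRecord(
                    ctri_number=ctri,
                    registered_on=parse_date_permissive(row[cm["registered_on"]]),
                    type_of_study_raw=row[cm["type_of_study_raw"]],
                    type_of_trial=parse_type_of_trial(row[cm["type_of_trial"]]),
                    phase=parse_phase(row[cm["phase"]]),
                    countries=frozenset(
                        c.strip() for c in countries_raw.split("|") if c.strip()
                    ),
                    recruit_status_global=row[cm["recruit_status_global"]],
                    recruit_status_india=row[cm["recruit_status_india"]],
                    date_first_enroll_global=parse_date_permissive(
                        row[cm["date_first_enroll_global"]]
                    ),
                    date_first_enroll_india=parse_date_permissive(
                        row[cm["date_first_enroll_india"]]
                    ),
                    total_sample_size=int(total) if total is not None else None,
                    sample_size_india=int(india) if india is not None else None,
                    pi_name=row[cm["pi_name"]],
                    sponsor_name=row[cm["sponsor_name"]],
                    sponsor_classification=row[cm["sponsor_classification"]],
                    sites=tuple(sites_by_id.get(ctri, [])),
                    ethics_committees=tuple(ecs_by_id.get(ctri, [])),
                    public_title=row[cm["public_title"]],
                    scientific_title=row[cm["scientific_title"]],
                    extras=extras_by_id.get(ctri, {}),
                )
            )
        return records
    finally:
        conn.close()


# ---------------------------------------------------------------------------
# Report / findings export

REPORT_COLUMNS = ("rule_id", "cohort", "bin", "numerator", "denominator", "rate")


def report_rows(report: AuditReport) -> list[dict[str, str]]:
    """Report cells as export rows, sorted by (rule, cohort, bin)."""
    rows = []
    for (rule_id, bin_label, cohort), cell in sorted(
        report.cells.items(), key=lambda kv: (kv[0][0], kv[0][2], kv[0][1])
    ):
        rows.append(
            {
                "rule_id": rule_id,
                "cohort": cohort,
                "bin": bin_label,
                "numerator": str(cell.numerator),
                "denominator": str(cell.denominator),
                "rate": format_rate(cell.rate_percent),
            }
        )
    return rows


def export_report(report: AuditReport, fmt: str, path: str | Path) -> None:
    """Write a report as CSV (RFC-4180, UTF-8) or JSON.

    Column order is fixed: rule_id, cohort, bin, numerator, denominator,
    rate.  Rates are rendered with a trailing '.0' stripped.
    """
    if fmt not in ("csv", "json"):
        raise ValueError(f"unsupported report format: {fmt!r}")
    rows = report_rows(report)
    if fmt == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=REPORT_COLUMNS)
            writer.writeheader()
            writer.writerows(rows)
    else:
        payload = {"out_of_range": report.out_of_range, "cells": rows}
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")


def export_findings_csv(findings: Sequence, path: str | Path) -> None:
    """Findings CSV with columns ctri_number, rule_id, evidence."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(("ctri_number", "rule_id", "evidence"))
        for f in findings:
            writer.writerow((f.ctri_number, f.rule_id, f.evidence))
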