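"""Temporal error-rate series over four 3-year registration bins.

Registration dates are binned into 2007-2009, 2010-2012, 2013-2015 and
2016-2018, the last bin ending 2018-04-04 exclusive (the snapshot the audit
is modelled on runs to 3 April 2018).  Each quantified rule yields one
(numerator, denominator, rate) cell per bin for its cohort; the cohorts
follow the data-processing funnel: all records -> Drug type -> country-list
scope -> unambiguous records -> Interventional (or a redefined alternative
type filter).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence

from .config import AuditConfig, DEFAULT_CONFIG
from .record_model import (
    AuditFinding,
    AuditReport,
    ReportCell,
    Scope,
    ScopeResult,
    TrialRecord,
    TypeOfTrial,
)
from .rule_engine import evaluate_record
from .scope_classifier import is_drug_trial, scope_result


@dataclass(frozen=True)
class TimeBin:
    """Half-open registration-date interval [start, end)."""

    label: str
    start: date
    end: date

    def __contains__(self, day: date) -> bool:
        return self.start <= day < self.end


TIME_BINS: tuple[TimeBin, ...] = (
    TimeBin("P1:2007-2009", date(2007, 1, 1), date(2010, 1, 1)),
    TimeBin("P2:2010-2012", date(2010, 1, 1), date(2013, 1, 1)),
    TimeBin("P3:2013-2015", date(2013, 1, 1), date(2016, 1, 1)),
    TimeBin("P4:2016-2018", date(2016, 1, 1), date(2018, 4, 4)),
)

BIN_LABELS: tuple[str, ...] = tuple(b.label for b in TIME_BINS)

#: report cohort names
COHORT_INDIAN = "Indian"
COHORT_MULTINATIONAL = "Multinational"
COHORT_RD_PMS = "redefined-Indian-PMS"
COHORT_RD_BABE = "redefined-Indian-BABE"
COHORT_RD_TOSNA = "redefined-Indian-TOSNA"
COHORT_ALL = "All"

#: pseudo-rule key for the category-to-trial ratio series (not a per-record
#: finding; the numerator counts distinct Type of Study strings per bin)
CATEGORY_RATIO = "CATEGORY-RATIO"


@dataclass(frozen=True)
class OutOfRange:
    """Verdict for a record that belongs to no bin."""

    reason: str


def assign_bin(record: TrialRecord) -> TimeBin | OutOfRange:
    """Bin containing the registration date, or an OutOfRange verdict."""
    if record.registered_on is None:
        return OutOfRange("registration date missing")
    for time_bin in TIME_BINS:
        if record.registered_on in time_bin:
            return time_bin
    return OutOfRange(f"registration date {record.registered_on.isoformat()} outside bins")


def round_rate(numerator: int, denominator: int) -> float:
    """100*num/den rounded half-up to one decimal."""
    if denominator == 0:
        raise ZeroDivisionError("rate undefined for zero denominator")
    value = Decimal(100 * numerator) / Decimal(denominator)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def format_rate(rate: Optional[float]) -> str:
    """Render a one-decimal rate, stripping a trailing '.0' ('3', '0.9')."""
    if rate is None:
        return ""
    text = f"{rate:.1f}"
    return text[:-2] if text.endswith(".0") else text


def format_share(numerator: int, denominator: int) -> str:
    """Whole-percent share of a count within its parent count ('85' for
    1764 of 2070), rounded half-up."""
    if denominator == 0:
        return ""
    value = Decimal(100 * numerator) / Decimal(denominator)
    return str(value.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def _bin_partition(records: Iterable[TrialRecord]) -> tuple[dict[str, list[TrialRecord]], int]:
    by_bin: dict[str, list[TrialRecord]] = {label: [] for label in BIN_LABELS}
    out_of_range = 0
    for record in records:
        verdict = assign_bin(record)
        if isinstance(verdict, OutOfRange):
            out_of_range += 1
        else:
            by_bin[verdict.label].append(record)
    return by_bin, out_of_range


def error_rate_series(
    cohort: Sequence[TrialRecord],
    rule_id: str,
    findings_by_id: Mapping[str, frozenset[str]],
) -> dict[str, ReportCell]:
    """Per-bin cells for one rule over one cohort.

    ``findings_by_id`` maps a CTRI number to the set of rule ids found
    against that record.  Zero-denominator bins become empty cells.
    """
    by_bin, _ = _bin_partition(cohort)
    cells = {}
    for label in BIN_LABELS:
        members = by_bin[label]
        denominator = len(members)
        numerator = sum(
            1 for r in members if rule_id in findings_by_id.get(r.ctri_number, frozenset())
        )
        rate = round_rate(numerator, denominator) if denominator else None
        cells[label] = ReportCell(numerator, denominator, rate)
    return cells


def category_ratio_series(records: Sequence[TrialRecord]) -> dict[str, ReportCell]:
    """Distinct Type of Study strings per bin as a percentage of the bin's
    record count — the category-explosion series, computed over all records
    (no drug filter).  Distinctness is over verbatim raw values, with an
    absent field counting as one shared category."""
    by_bin, _ = _bin_partition(records)
    cells = {}
    for label in BIN_LABELS:
        members = by_bin[label]
        denominator = len(members)
        distinct = {
            (r.type_of_study_raw.strip() if r.type_of_study_raw is not None else None)
            for r in members
        }
        numerator = len(distinct) if denominator else 0
        rate = round_rate(numerator, denominator) if denominator else None
        cells[label] = ReportCell(numerator, denominator, rate)
    return cells


def category_first_appearance_series(records: Sequence[TrialRecord]) -> dict[str, ReportCell]:
    """Share of all distinct Type of Study categories first appearing in each
    bin (the four shares sum to ~100).

    This is the complementary reading of the category-explosion series: how
    the growth of the category list distributes over time, rather than the
    per-bin distinct-to-record ratio of :func:`category_ratio_series`.
    Categories appearing only in out-of-range records are excluded.
    """
    by_bin, _ = _bin_partition(records)
    seen: set[Optional[str]] = set()
    new_per_bin: dict[str, int] = {}
    for label in BIN_LABELS:
        fresh = {
            (r.type_of_study_raw.strip() if r.type_of_study_raw is not None else None)
            for r in by_bin[label]
        } - seen
        new_per_bin[label] = len(fresh)
        seen |= fresh
    total = len(seen)
    return {
        label: ReportCell(
            new_per_bin[label], total, round_rate(new_per_bin[label], total) if total else None
        )
        for label in BIN_LABELS
    }


@dataclass
class Cohorts:
    """The funnel's record sets, shared by the report builder and the funnel
    summary."""

    all_records: list[TrialRecord]
    drug: list[TrialRecord]
    indian_drug: list[TrialRecord]
    mn_drug: list[TrialRecord]
    foreign_drug: list[TrialRecord]
    nocountry_drug: list[TrialRecord]
    unambiguous_indian: list[TrialRecord]
    unambiguous_mn: list[TrialRecord]
    indian_interventional: list[TrialRecord]
    indian_pms: list[TrialRecord]
    mn_interventional: list[TrialRecord]
    mn_pms: list[TrialRecord]
    redefined_babe: list[TrialRecord]
    redefined_tosna: list[TrialRecord]


def build_cohorts(
    records: Sequence[TrialRecord],
    scope_results: Mapping[str, ScopeResult],
) -> Cohorts:
    """Materialize the funnel.

    Drug-filtered branches drive the main series; the redefined BA/BE and
    Type-of-Study-missing cohorts start from *all* records (a record without
    a Type of Study cannot pass the Drug filter) and apply the unambiguity
    filters with the alternative type filter.  The redefined PMS cohort is
    the PMS branch of the unambiguous Indian drug funnel.
    """
    drug = [r for r in records if is_drug_trial(r)]

    def of_scope(rs: Sequence[TrialRecord], scope: Scope) -> list[TrialRecord]:
        return [r for r in rs if scope_results[r.ctri_number].scope is scope]

    indian_drug = of_scope(drug, Scope.INDIAN)
    mn_drug = of_scope(drug, Scope.MULTINATIONAL)
    unamb_indian = [r for r in indian_drug if scope_results[r.ctri_number].unambiguous]
    unamb_mn = [r for r in mn_drug if scope_results[r.ctri_number].unambiguous]
    unamb_indian_all = [
        r
        for r in of_scope(list(records), Scope.INDIAN)
        if scope_results[r.ctri_number].unambiguous
    ]
    return Cohorts(
        all_records=list(records),
        drug=drug,
        indian_drug=indian_drug,
        mn_drug=mn_drug,
        foreign_drug=of_scope(drug, Scope.FOREIGN),
        nocountry_drug=of_scope(drug, Scope.UNCLASSIFIABLE),
        unambiguous_indian=unamb_indian,
        unambiguous_mn=unamb_mn,
        indian_interventional=[
            r for r in unamb_indian if r.type_of_trial is TypeOfTrial.INTERVENTIONAL
        ],
        indian_pms=[r for r in unamb_indian if r.type_of_trial is TypeOfTrial.PMS],
        mn_interventional=[r for r in unamb_mn if r.type_of_trial is TypeOfTrial.INTERVENTIONAL],
        mn_pms=[r for r in unamb_mn if r.type_of_trial is TypeOfTrial.PMS],
        redefined_babe=[r for r in unamb_indian_all if r.type_of_trial is TypeOfTrial.BABE],
        redefined_tosna=[r for r in unamb_indian_all if not r.type_of_study_tokens],
    )


#: the quantified series: (rule, cohort-name) -> attribute of Cohorts
SERIES_PLAN: tuple[tuple[str, str, str], ...] = (
    ("R-SCOPE", COHORT_INDIAN, "indian_drug"),
    ("R-SCOPE", COHORT_MULTINATIONAL, "mn_drug"),
    ("R-INT-PMSPHASE", COHORT_INDIAN, "indian_interventional"),
    ("R-PMS-PH4", COHORT_RD_PMS, "indian_pms"),
    ("R-BABE-PHASE", COHORT_RD_BABE, "redefined_babe"),
    ("R-TOSNA-PHASE", COHORT_RD_TOSNA, "redefined_tosna"),
    ("R-CITY", COHORT_INDIAN, "indian_interventional"),
    ("R-CITY", COHORT_MULTINATIONAL, "mn_interventional"),
    ("R-PI-NIL", COHORT_INDIAN, "indian_interventional"),
    ("R-PI-NIL", COHORT_MULTINATIONAL, "mn_interventional"),
    ("R-SPONSOR-NIL", COHORT_INDIAN, "indian_interventional"),
    ("R-STATE-NIL", COHORT_INDIAN, "indian_interventional"),
    ("R-STATE-NIL", COHORT_MULTINATIONAL, "mn_interventional"),
    ("R-EC-EXCESS", COHORT_INDIAN, "indian_interventional"),
    ("R-EC-EXCESS", COHORT_MULTINATIONAL, "mn_interventional"),
)


def build_report(
    records: Sequence[TrialRecord],
    config: AuditConfig = DEFAULT_CONFIG,
    scope_results: Optional[Mapping[str, ScopeResult]] = None,
    findings: Optional[Sequence[AuditFinding]] = None,
) -> AuditReport:
    """Run the full scope -> rules -> per-bin series pipeline.

    Scope results and findings are recomputed unless supplied (the model
    layer supplies them to avoid duplicate work).
    """
    if scope_results is None:
        scope_results = {r.ctri_number: scope_result(r, config) for r in records}
    if findings is None:
        findings = [f for r in records for f in evaluate_record(r, config)]
    findings_by_id: dict[str, frozenset[str]] = {}
    grouped: dict[str, set[str]] = {}
    for finding in findings:
        grouped.setdefault(finding.ctri_number, set()).add(finding.rule_id)
    findings_by_id = {k: frozenset(v) for k, v in grouped.items()}

    cohorts = build_cohorts(records, scope_results)
    report = AuditReport()
    _, report.out_of_range = _bin_partition(records)
    for rule_id, cohort_name, attr in SERIES_PLAN:
        cells = error_rate_series(getattr(cohorts, attr), rule_id, findings_by_id)
        for label, cell in cells.items():
            report.cells[(rule_id, label, cohort_name)] = cell
    for label, cell in category_ratio_series(records).items():
        report.cells[(CATEGORY_RATIO, label, COHORT_ALL)] = cell
    return report
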