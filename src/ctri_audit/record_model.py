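"""Typed representation of a CTRI trial-registration record and audit outputs.

A :class:`TrialRecord` stores the audited fields of one registered trial in
typed form while keeping raw text verbatim where the audit rules need it
(``type_of_study_raw``, ``pi_name``, ``sponsor_name``...).  Internally
inconsistent content — e.g. an Interventional trial whose Phase is PMS — is
legal at this layer: inconsistency is what the audit measures, never a parse
error.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Mapping, Optional

from dateutil import parser as _dateparser

from ._lexicons import MISSING_TOKENS, STUDY_TYPE_VOCAB

logger = logging.getLogger(__name__)

#: The fixed audit-rule catalogue.  Every AuditFinding.rule_id is one of these.
RULE_CATALOGUE: tuple[str, ...] = (
    "R-SCOPE",
    "R-INT-PMSPHASE",
    "R-PMS-PH4",
    "R-BABE-PHASE",
    "R-TOSNA-PHASE",
    "R-CITY",
    "R-PI-NIL",
    "R-SPONSOR-NIL",
    "R-STATE-NIL",
    "R-EC-EXCESS",
    "R-EC-FOREIGN",
    "R-EC-UNIDENT",
)


class TypeOfTrial(str, enum.Enum):
    OBSERVATIONAL = "Observational"
    INTERVENTIONAL = "Interventional"
    PMS = "PMS"
    BABE = "BA/BE"


class Phase(str, enum.Enum):
    PHASE_1 = "Phase 1"
    PHASE_1_2 = "Phase 1/2"
    PHASE_2 = "Phase 2"
    PHASE_2_3 = "Phase 2/3"
    PHASE_3 = "Phase 3"
    PHASE_3_4 = "Phase 3/4"
    PHASE_4 = "Phase 4"
    NA = "N/A"
    PMS = "PMS"


#: Phases 1 through 4 (including the split phases) — the set that is
#: inconsistent with a BA/BE trial type or an absent Type of Study.
NUMBERED_PHASES: frozenset[Phase] = frozenset(
    {Phase.PHASE_1, Phase.PHASE_1_2, Phase.PHASE_2, Phase.PHASE_2_3,
     Phase.PHASE_3, Phase.PHASE_3_4, Phase.PHASE_4}
)


class Scope(str, enum.Enum):
    INDIAN = "Indian"
    MULTINATIONAL = "Multinational"
    FOREIGN = "Foreign"
    UNCLASSIFIABLE = "Unclassifiable"


def is_missing_token(raw: Optional[str], missing_tokens: frozenset[str] = MISSING_TOKENS) -> bool:
    """True iff ``raw`` is absent, whitespace-only or a configured missing token."""
    if raw is None:
        return True
    stripped = raw.strip()
    return not stripped or stripped.lower() in missing_tokens


def parse_date_permissive(raw: Optional[str]) -> Optional[date]:
    """Parse a date leniently (day-first and ISO dialects).

    Unparseable non-missing text is retained as missing with a logged
    warning rather than raised: malformed dates are audit input.
    """
    if raw is None or is_missing_token(raw):
        return None
    text = raw.strip()
    try:
        if re.fullmatch(r"\d{4}-\d{2}-\d{2}", text):
            return date.fromisoformat(text)
        return _dateparser.parse(text, dayfirst=True).date()
    except (ValueError, OverflowError):
        logger.warning("unparseable date %r kept as missing", raw)
        return None


def tokenize_study_type(
    raw: Optional[str],
    vocabulary: Iterable[str] = STUDY_TYPE_VOCAB,
    missing_tokens: frozenset[str] = MISSING_TOKENS,
) -> list[str]:
    """Decompose a stored Type of Study string into category tokens.

    CTRI stores multi-selections as an undelimited concatenation of category
    labels ("DrugAyurveda").  Decomposition is longest-match left-to-right
    against the category vocabulary, case-insensitive; each maximal run of
    unmatched text becomes a single ``"Other:<residue>"`` token.  A missing
    token yields the empty list.
    """
    if is_missing_token(raw, missing_tokens):
        return []
    text = raw.strip()
    vocab = sorted(vocabulary, key=len, reverse=True)
    lower = text.lower()
    tokens: list[str] = []
    residue: list[str] = []
    i = 0
    n = len(text)

    def flush_residue() -> None:
        chunk = "".join(residue).strip(" ,;")
        if chunk:
            tokens.append(f"Other:{chunk}")
        residue.clear()

    while i < n:
        if text[i] in " ,;":
            if residue:
                residue.append(text[i])
            i += 1
            continue
        for term in vocab:
            if lower.startswith(term.lower(), i):
                flush_residue()
                tokens.append(term)
                i += len(term)
                break
        else:
            residue.append(text[i])
            i += 1
    flush_residue()
    return tokens


@dataclass(frozen=True)
class Site:
    institution_name: Optional[str] = None
    city: Optional[str] = None
    state: Optional[str] = None
    country: Optional[str] = None


@dataclass(frozen=True)
class EthicsCommittee:
    name: str
    affiliation: Optional[str] = None
    address: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("ethics committee name must be non-empty")


@dataclass
class TrialRecord:
    """One registered trial, audited fields in typed form.

    ``type_of_study_tokens`` is always the token decomposition of
    ``type_of_study_raw`` (empty iff the raw value is a missing token); it is
    recomputed rather than stored independently.
    """

    ctri_number: str
    registered_on: Optional[date] = None
    type_of_study_raw: Optional[str] = None
    type_of_trial: Optional[TypeOfTrial] = None
    phase: Optional[Phase] = None
    countries: frozenset[str] = frozenset()
    recruit_status_global: Optional[str] = None
    recruit_status_india: Optional[str] = None
    date_first_enroll_global: Optional[date] = None
    date_first_enroll_india: Optional[date] = None
    total_sample_size: Optional[int] = None
    sample_size_india: Optional[int] = None
    pi_name: Optional[str] = None
    sponsor_name: Optional[str] = None
    sponsor_classification: Optional[str] = None
    sites: tuple[Site, ...] = ()
    ethics_committees: tuple[EthicsCommittee, ...] = ()
    public_title: Optional[str] = None
    scientific_title: Optional[str] = None
    extras: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not re.match(r"CTRI/\d{4}/\d{2}/\d+", self.ctri_number):
            raise ValueError(f"malformed CTRI number: {self.ctri_number!r}")
        self.countries = frozenset(self.countries)
        self.sites = tuple(self.sites)
        self.ethics_committees = tuple(self.ethics_committees)
        for size_field in ("total_sample_size", "sample_size_india"):
            value = getattr(self, size_field)
            if value is not None and value < 0:
                raise ValueError(f"{size_field} must be non-negative")

    @property
    def type_of_study_tokens(self) -> list[str]:
        return tokenize_study_type(self.type_of_study_raw)


@dataclass(frozen=True)
class ScopeResult:
    """Geographic scope class plus the ambiguity flags raised against it."""

    scope: Scope
    flags: tuple[str, ...] = ()

    @property
    def unambiguous(self) -> bool:
        return not self.flags


@dataclass(frozen=True)
class AuditFinding:
    """One (record, rule) violation with a text rendering of the evidence."""

    ctri_number: str
    rule_id: str
    evidence: str

    def __post_init__(self) -> None:
        if self.rule_id not in RULE_CATALOGUE:
            raise ValueError(f"unknown rule id: {self.rule_id!r}")


@dataclass(frozen=True)
class ReportCell:
    """One (rule, bin, cohort) cell: numerator / denominator / percentage.

    ``rate_percent`` is 100*numerator/denominator rounded half-up to one
    decimal, or None for an empty cell (zero denominator).
    """

    numerator: int
    denominator: int
    rate_percent: Optional[float]

    def __post_init__(self) -> None:
        if not 0 <= self.numerator <= self.denominator:
            raise ValueError("cell requires 0 <= numerator <= denominator")
        if (self.rate_percent is None) != (self.denominator == 0):
            raise ValueError("rate is None exactly when the denominator is 0")
        if self.rate_percent is not None and not 0.0 <= self.rate_percent <= 100.0:
            raise ValueError("rate must lie in [0, 100]")


@dataclass
class AuditReport:
    """Machine form of the per-rule x per-bin x per-cohort error-rate table."""

    cells: dict[tuple[str, str, str], ReportCell] = field(default_factory=dict)
    #: records excluded from every bin (date missing or out of range)
    out_of_range: int = 0

    def cell(self, rule_id: str, time_bin: str, cohort: str) -> ReportCell:
        return self.cells[(rule_id, time_bin, cohort)]

    def series(self, rule_id: str, cohort: str) -> dict[str, ReportCell]:
        return {
            b: c for (r, b, co), c in sorted(self.cells.items()) if r == rule_id and co == cohort
        }


def parse_type_of_trial(raw: Optional[str]) -> Optional[TypeOfTrial]:
    """Map stored text to the Type of Trial enumeration; unknown/missing -> None."""
    if is_missing_token(raw):
        return None
    text = raw.strip()
    for member in TypeOfTrial:
        if text.lower() == member.value.lower():
            return member
    logger.warning("unrecognised Type of Trial %r kept as missing", raw)
    return None


def parse_phase(raw: Optional[str]) -> Optional[Phase]:
    """Map stored text to the Phase enumeration.

    "N/A" maps to the explicit N/A member (meaningful: the phase field does
    not apply), so only truly absent text becomes None.
    """
    if raw is None or not raw.strip():
        return None
    text = raw.strip()
    for member in Phase:
        if text.lower() == member.value.lower():
            return member
    if text.lower() in MISSING_TOKENS - {"n/a", "na"}:
        return None
    if text.lower() == "na":
        return Phase.NA
    logger.warning("unrecognised Phase %r kept as missing", raw)
    return None


def parse_sample_size(raw: Optional[str]) -> Optional[int]:
    """Parse a sample-size cell; missing tokens and junk -> None."""
    if is_missing_token(raw):
        return None
    text = raw.strip().replace(",", "")
    if not re.fullmatch(r"\d+", text):
        logger.warning("unparseable sample size %r kept as missing", raw)
        return None
    return int(text)


def records_by_id(records: Iterable[TrialRecord]) -> Mapping[str, TrialRecord]:
    return {r.ctri_number: r for r in records}
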