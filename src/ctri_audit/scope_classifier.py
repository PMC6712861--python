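"""Geographic scope classification and cross-field consistency filtering.

CTRI records carry four fields (or field pairs) that jointly say where a
trial recruits: the country list, the global/India recruitment statuses, the
global/India first-enrollment dates, and the total/India sample sizes.  The
country list alone classifies a record as Indian, Multinational, Foreign or
Unclassifiable; the other three pairs then either corroborate that class or
raise ambiguity flags.  A record is *unambiguous* iff no flag is raised.

The flag catalogue here is the package's normative definition of the
unambiguity filter, config-extensible through ``AuditConfig``.
"""

from __future__ import annotations

from typing import Optional

from .config import AuditConfig, DEFAULT_CONFIG
from .record_model import Scope, ScopeResult, TrialRecord, is_missing_token

#: flags that may be raised against an Indian-scope record
INDIAN_FLAGS = ("IN-STATUS", "IN-DATE", "IN-SIZE", "IN-SIZE-MISMATCH", "IN-GDATE")
#: flags that may be raised against a Multinational-scope record
MULTINATIONAL_FLAGS = ("MN-GSTATUS", "MN-ISTATUS", "MN-GDATE", "MN-GSIZE",
                       "MN-ISIZE-EXCESS", "MN-IDATE")

_NOT_APPLICABLE = "not applicable"


def _is_not_applicable(status: Optional[str]) -> bool:
    return status is not None and status.strip().lower() == _NOT_APPLICABLE


def _status_missing(status: Optional[str], config: AuditConfig) -> bool:
    # "Not applicable" is data for status fields, never a missing token.
    return is_missing_token(status, config.missing_tokens)


def is_drug_trial(record: TrialRecord) -> bool:
    """True iff the Type of Study is exactly the single category Drug.

    Multi-category selections that merely include Drug ("DrugAyurveda") are
    their own categories and do not qualify.
    """
    tokens = record.type_of_study_tokens
    return len(tokens) == 1 and tokens[0].strip().lower() == "drug"


def classify_scope(record: TrialRecord) -> Scope:
    """Classify by the country set: {India} -> Indian; India plus others ->
    Multinational; non-empty without India -> Foreign; empty -> Unclassifiable."""
    countries = {c.strip().lower() for c in record.countries if c and c.strip()}
    if not countries:
        return Scope.UNCLASSIFIABLE
    if "india" in countries:
        return Scope.INDIAN if len(countries) == 1 else Scope.MULTINATIONAL
    return Scope.FOREIGN


def ambiguity_flags(
    record: TrialRecord, scope: Scope, config: AuditConfig = DEFAULT_CONFIG
) -> list[str]:
    """Flags raised by the three corroborating field pairs, given the scope.

    Only Indian and Multinational records are filterable; any other scope is
    a contract violation.
    """
    if scope is Scope.INDIAN:
        flags = []
        if _status_missing(record.recruit_status_india, config) or _is_not_applicable(
            record.recruit_status_india
        ):
            flags.append("IN-STATUS")
        if record.date_first_enroll_india is None:
            flags.append("IN-DATE")
        if record.sample_size_india is None or record.sample_size_india == 0:
            flags.append("IN-SIZE")
        if (
            record.total_sample_size is not None
            and record.sample_size_india is not None
            and record.total_sample_size != record.sample_size_india
        ):
            flags.append("IN-SIZE-MISMATCH")
        if (
            record.date_first_enroll_global is not None
            and record.date_first_enroll_global != record.date_first_enroll_india
        ):
            flags.append("IN-GDATE")
        return flags
    if scope is Scope.MULTINATIONAL:
        flags = []
        if _status_missing(record.recruit_status_global, config) or _is_not_applicable(
            record.recruit_status_global
        ):
            flags.append("MN-GSTATUS")
        if _status_missing(record.recruit_status_india, config) or _is_not_applicable(
            record.recruit_status_india
        ):
            flags.append("MN-ISTATUS")
        if record.date_first_enroll_global is None:
            flags.append("MN-GDATE")
        if record.total_sample_size is None or record.total_sample_size == 0:
            flags.append("MN-GSIZE")
        if (
            record.sample_size_india is not None
            and record.total_sample_size is not None
            and record.sample_size_india > record.total_sample_size
        ):
            flags.append("MN-ISIZE-EXCESS")
        if config.include_mn_idate and record.date_first_enroll_india is None:
            flags.append("MN-IDATE")
        return flags
    raise ValueError(f"ambiguity filtering undefined for scope {scope}")


def scope_result(record: TrialRecord, config: AuditConfig = DEFAULT_CONFIG) -> ScopeResult:
    """Scope class plus ambiguity flags (empty flags for Foreign/Unclassifiable)."""
    scope = classify_scope(record)
    if scope in (Scope.INDIAN, Scope.MULTINATIONAL):
        return ScopeResult(scope, tuple(ambiguity_flags(record, scope, config)))
    return ScopeResult(scope)


def is_truly_foreign(record: TrialRecord, config: AuditConfig = DEFAULT_CONFIG) -> bool:
    """The three-criteria test for a Foreign-listed record with no India arm.

    (1) the global recruitment status is real data while the India status is
    "Not applicable"; (2) a global first-enrollment date exists while the
    India one does not; (3) the total sample size is non-zero while the India
    sample size is nil or zero.
    """
    if classify_scope(record) is not Scope.FOREIGN:
        raise ValueError("is_truly_foreign requires a Foreign-scope record")
    status_ok = (
        not _status_missing(record.recruit_status_global, config)
        and not _is_not_applicable(record.recruit_status_global)
        and _is_not_applicable(record.recruit_status_india)
    )
    date_ok = record.date_first_enroll_global is not None and record.date_first_enroll_india is None
    size_ok = (
        record.total_sample_size is not None
        and record.total_sample_size > 0
        and (record.sample_size_india is None or record.sample_size_india == 0)
    )
    return status_ok and date_ok and size_ok
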