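"""Per-record deficiency rules: type/phase consistency, completeness,
city validity and ethics-committee checks.

Every rule is a pure function ``TrialRecord -> list[AuditFinding]``;
``evaluate_record`` concatenates the enabled rules' findings in a fixed
order.  Rules never mutate the record and are mutually independent, so the
dispatcher's output is exactly the union of the individual rules' outputs.
"""

from __future__ import annotations

import re
from functools import lru_cache
from typing import Optional

from .config import AuditConfig, DEFAULT_CONFIG
from .record_model import (
    NUMBERED_PHASES,
    AuditFinding,
    Phase,
    Scope,
    TrialRecord,
    TypeOfTrial,
    is_missing_token,
)
from .scope_classifier import ambiguity_flags, classify_scope


def is_missing_value(
    raw: Optional[str], field_kind: str = "general", config: AuditConfig = DEFAULT_CONFIG
) -> bool:
    """Missing-token test with field-class semantics.

    For ``field_kind="status"`` the literal "Not applicable" is NOT missing —
    it is meaningful data for the two recruitment-status fields.  (It is not
    in the default token list either; the kind argument makes the contract
    explicit and guards against config lists that add it.)
    """
    if field_kind not in ("general", "status", "phase"):
        raise ValueError(f"unknown field kind {field_kind!r}")
    if field_kind == "status" and raw is not None and raw.strip().lower() == "not applicable":
        return False
    return is_missing_token(raw, config.missing_tokens)


def rule_scope_ambiguity(
    record: TrialRecord, config: AuditConfig = DEFAULT_CONFIG
) -> list[AuditFinding]:
    """R-SCOPE: an Indian or Multinational record whose corroborating field
    pairs contradict its country-list scope."""
    scope = classify_scope(record)
    if scope not in (Scope.INDIAN, Scope.MULTINATIONAL):
        return []
    flags = ambiguity_flags(record, scope, config)
    if not flags:
        return []
    return [AuditFinding(record.ctri_number, "R-SCOPE", f"{scope.value}: {','.join(flags)}")]


def rule_type_phase_consistency(record: TrialRecord) -> list[AuditFinding]:
    """Type-of-trial / phase contradictions.

    R-INT-PMSPHASE: Interventional type with Phase listed as PMS.
    R-PMS-PH4:      PMS type with Phase 4 (CTRI defines PMS and Phase 4 as
                    mutually exclusive).
    R-BABE-PHASE:   BA/BE type carrying any numbered phase.
    R-TOSNA-PHASE:  Type of Study absent but a numbered phase listed.
    """
    findings = []
    evidence = f"type={record.type_of_trial.value if record.type_of_trial else None}, " \
               f"phase={record.phase.value if record.phase else None}"
    if record.type_of_trial is TypeOfTrial.INTERVENTIONAL and record.phase is Phase.PMS:
        findings.append(AuditFinding(record.ctri_number, "R-INT-PMSPHASE", evidence))
    if record.type_of_trial is TypeOfTrial.PMS and record.phase is Phase.PHASE_4:
        findings.append(AuditFinding(record.ctri_number, "R-PMS-PH4", evidence))
    if record.type_of_trial is TypeOfTrial.BABE and record.phase in NUMBERED_PHASES:
        findings.append(AuditFinding(record.ctri_number, "R-BABE-PHASE", evidence))
    if not record.type_of_study_tokens and record.phase in NUMBERED_PHASES:
        findings.append(
            AuditFinding(
                record.ctri_number,
                "R-TOSNA-PHASE",
                f"type_of_study={record.type_of_study_raw!r}, phase={record.phase.value}",
            )
        )
    return findings


def _city_invalid(city: Optional[str], config: AuditConfig) -> bool:
    if is_missing_token(city, config.missing_tokens):
        return True
    text = city.strip()
    if len(text) < 2 or re.search(r"\d", text):
        return True
    if config.strict_city and text not in config.city_gazetteer:
        return True
    return False


def rule_completeness(record: TrialRecord, config: AuditConfig = DEFAULT_CONFIG) -> list[AuditFinding]:
    """Missing-data and non-standard-site checks.

    R-PI-NIL / R-SPONSOR-NIL: the principal-investigator or primary-sponsor
    name is a missing token.  R-STATE-NIL: some site lacks its state.
    R-CITY: some site city is structurally invalid (missing, digits, shorter
    than two characters) or — in strict mode — absent from the gazetteer.
    """
    findings = []
    if is_missing_value(record.pi_name, "general", config):
        findings.append(AuditFinding(record.ctri_number, "R-PI-NIL", f"pi_name={record.pi_name!r}"))
    if is_missing_value(record.sponsor_name, "general", config):
        findings.append(
            AuditFinding(record.ctri_number, "R-SPONSOR-NIL", f"sponsor_name={record.sponsor_name!r}")
        )
    bad_states = [s for s in record.sites if is_missing_token(s.state, config.missing_tokens)]
    if bad_states:
        findings.append(
            AuditFinding(record.ctri_number, "R-STATE-NIL", f"{len(bad_states)} site(s) without state")
        )
    bad_cities = [s.city for s in record.sites if _city_invalid(s.city, config)]
    if bad_cities:
        findings.append(
            AuditFinding(record.ctri_number, "R-CITY", f"invalid cities: {bad_cities!r}")
        )
    return findings


@lru_cache(maxsize=8)
def _foreign_country_regex(lexicon: tuple[str, ...], denylist: frozenset[str]):
    usable = sorted(
        (c for c in lexicon if c.lower() != "india" and c not in denylist),
        key=len,
        reverse=True,
    )
    pattern = "|".join(re.escape(c.lower()) for c in usable)
    return re.compile(r"(?<!\w)(" + pattern + r")(?!\w)"), {c.lower(): c for c in usable}


def _foreign_tokens(text: str, config: AuditConfig) -> list[str]:
    regex, canonical = _foreign_country_regex(
        tuple(config.country_lexicon), config.ec_country_denylist
    )
    return sorted({canonical[m] for m in regex.findall(text.lower())})


def rule_ethics(record: TrialRecord, config: AuditConfig = DEFAULT_CONFIG) -> list[AuditFinding]:
    """Ethics-committee checks.

    R-EC-EXCESS: more committees than trial sites (e.g. 28 committees for 7
    sites).  R-EC-FOREIGN: a committee whose name/affiliation/address names a
    non-India country.  R-EC-UNIDENT: a committee with neither affiliation
    nor address, so its identity cannot be established unambiguously.
    """
    findings = []
    n_ec, n_sites = len(record.ethics_committees), len(record.sites)
    if n_ec > n_sites:
        findings.append(
            AuditFinding(record.ctri_number, "R-EC-EXCESS", f"{n_ec} committees for {n_sites} site(s)")
        )
    foreign = []
    for ec in record.ethics_committees:
        text = " ".join(t for t in (ec.name, ec.affiliation, ec.address) if t)
        hits = _foreign_tokens(text, config)
        if hits:
            foreign.append((ec.name, hits))
    if foreign:
        findings.append(AuditFinding(record.ctri_number, "R-EC-FOREIGN", f"foreign ECs: {foreign!r}"))
    unident = [
        ec.name
        for ec in record.ethics_committees
        if is_missing_token(ec.affiliation, config.missing_tokens)
        and is_missing_token(ec.address, config.missing_tokens)
    ]
    if unident:
        findings.append(
            AuditFinding(record.ctri_number, "R-EC-UNIDENT", f"unidentifiable ECs: {unident!r}")
        )
    return findings


def evaluate_record(record: TrialRecord, config: AuditConfig = DEFAULT_CONFIG) -> list[AuditFinding]:
    """All enabled rules' findings for one record, ordered by rule id.

    Pure and idempotent; disabling a rule removes exactly its findings.
    """
    findings: list[AuditFinding] = []
    findings.extend(rule_scope_ambiguity(record, config))
    findings.extend(rule_type_phase_consistency(record))
    findings.extend(rule_completeness(record, config))
    findings.extend(rule_ethics(record, config))
    return sorted(
        (f for f in findings if f.rule_id in config.enabled_rules),
        key=lambda f: f.rule_id,
    )
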