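"""The deficiency-rule battery: examples, independence, purity."""

import copy

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctri_audit.config import AuditConfig
from ctri_audit.record_model import (
    EthicsCommittee,
    Phase,
    Site,
    TrialRecord,
    TypeOfTrial,
)
from ctri_audit.rule_engine import (
    evaluate_record,
    is_missing_value,
    rule_completeness,
    rule_ethics,
    rule_scope_ambiguity,
    rule_type_phase_consistency,
)


def _record(**kwargs):
    kwargs.setdefault("ctri_number", "CTRI/2014/09/000042")
    return TrialRecord(**kwargs)


def test_is_missing_value_semantics():
    assert is_missing_value("nil") is True
    assert is_missing_value("  ") is True
    assert is_missing_value("Not applicable", "status") is False
    assert is_missing_value("Not Available", "general") is True
    with pytest.raises(ValueError):
        is_missing_value("x", "unknown-kind")


@pytest.mark.parametrize(
    "type_of_trial, phase, expected",
    [
        (TypeOfTrial.INTERVENTIONAL, Phase.PMS, ["R-INT-PMSPHASE"]),
        (TypeOfTrial.PMS, Phase.PHASE_4, ["R-PMS-PH4"]),
        (TypeOfTrial.PMS, Phase.NA, []),
        (TypeOfTrial.BABE, Phase.PHASE_1, ["R-BABE-PHASE"]),
        (TypeOfTrial.BABE, Phase.PHASE_3_4, ["R-BABE-PHASE"]),
        (TypeOfTrial.BABE, Phase.NA, []),
        (TypeOfTrial.INTERVENTIONAL, Phase.PHASE_3, []),
        (TypeOfTrial.OBSERVATIONAL, Phase.NA, []),
    ],
)
def test_type_phase_consistency(type_of_trial, phase, expected):
    record = _record(type_of_study_raw="Drug", type_of_trial=type_of_trial, phase=phase)
    assert [f.rule_id for f in rule_type_phase_consistency(record)] == expected


def test_missing_study_type_with_numbered_phase():
    record = _record(type_of_study_raw="Not Available",
                     type_of_trial=TypeOfTrial.INTERVENTIONAL, phase=Phase.PHASE_2)
    assert [f.rule_id for f in rule_type_phase_consistency(record)] == ["R-TOSNA-PHASE"]
    # a PMS phase on a missing study type is not in the numbered set
    record2 = _record(type_of_study_raw=None, phase=Phase.PMS)
    assert rule_type_phase_consistency(record2) == []


def _sites(*cities, state="Karnataka"):
    return tuple(Site("Some Hospital", c, state, "India") for c in cities)


def test_completeness_rules():
    record = _record(
        pi_name="nil",
        sponsor_name="Real Sponsor Ltd",
        sites=_sites("Bengaluru", "Mysuru"),
    )
    assert [f.rule_id for f in rule_completeness(record)] == ["R-PI-NIL"]

    clean = _record(pi_name="Dr A Rao", sponsor_name="S", sites=_sites("Bengaluru"))
    assert rule_completeness(clean) == []

    one_empty_city = _record(
        pi_name="Dr A Rao", sponsor_name="S",
        sites=_sites("Bengaluru", "", "Chennai"),
    )
    assert [f.rule_id for f in rule_completeness(one_empty_city)] == ["R-CITY"]


@pytest.mark.parametrize(
    "city, invalid",
    [
        ("Bengaluru", False),
        ("", True),
        ("X", True),
        ("Sector 12", True),
        ("Not-in-gazetteer-town", False),  # structural checks only by default
    ],
)
def test_city_structural_checks(city, invalid):
    record = _record(pi_name="P", sponsor_name="S", sites=_sites(city))
    rule_ids = [f.rule_id for f in rule_completeness(record)]
    assert ("R-CITY" in rule_ids) is invalid


def test_city_gazetteer_strict_mode():
    config = AuditConfig(strict_city=True)
    record = _record(pi_name="P", sponsor_name="S", sites=_sites("Not-in-gazetteer-town"))
    assert any(f.rule_id == "R-CITY" for f in rule_completeness(record, config))


def test_state_missing():
    record = _record(pi_name="P", sponsor_name="S",
                     sites=_sites("Bengaluru", state=None))
    assert [f.rule_id for f in rule_completeness(record)] == ["R-STATE-NIL"]


def _ec(name, affiliation="Aff", address="Addr"):
    return EthicsCommittee(name, affiliation, address)


def test_ethics_rules():
    sites = _sites(*(["Bengaluru"] * 7))
    committees = tuple(_ec(f"EC {i}") for i in range(28))
    record = _record(sites=sites, ethics_committees=committees,
                     pi_name="P", sponsor_name="S")
    assert any(f.rule_id == "R-EC-EXCESS" for f in rule_ethics(record))

    foreign = _record(
        sites=_sites("Mumbai"),
        ethics_committees=(
            _ec("Comite National D'Ethique pour la Recherche en Sante, Senegal"),
        ),
    )
    rule_ids = [f.rule_id for f in rule_ethics(foreign)]
    assert "R-EC-FOREIGN" in rule_ids

    balanced = _record(
        sites=_sites("Mumbai", "Pune", "Nagpur"),
        ethics_committees=tuple(_ec(f"EC {i}") for i in range(3)),
    )
    assert rule_ethics(balanced) == []


def test_ethics_unidentifiable():
    record = _record(
        sites=_sites("Mumbai"),
        ethics_committees=(EthicsCommittee("Integrity Ethics Committee"),),
    )
    assert [f.rule_id for f in rule_ethics(record)] == ["R-EC-UNIDENT"]


def test_ec_denylist_token_not_foreign():
    record = _record(
        sites=_sites("Mumbai"),
        ethics_committees=(_ec("Georgia Medical Ethics Board"),),
    )
    assert not any(f.rule_id == "R-EC-FOREIGN" for f in rule_ethics(record))


@given(n_sites=st.integers(0, 50), n_ecs=st.integers(0, 50))
@settings(max_examples=60, deadline=None)
def test_ec_excess_quantified(n_sites, n_ecs):
    """R-EC-EXCESS fires exactly when committees outnumber sites."""
    record = _record(
        pi_name="P", sponsor_name="S",
        sites=_sites(*(["Bengaluru"] * n_sites)),
        ethics_committees=tuple(_ec(f"EC {i}") for i in range(n_ecs)),
    )
    fired = any(f.rule_id == "R-EC-EXCESS" for f in rule_ethics(record))
    assert fired == (n_ecs > n_sites)


def test_evaluate_is_union_of_rules(messy_registry):
    """The dispatcher output equals the multiset union of individual rules."""
    records, _ = messy_registry
    for record in records[:400]:
        combined = sorted(
            rule_scope_ambiguity(record)
            + rule_type_phase_consistency(record)
            + rule_completeness(record)
            + rule_ethics(record),
            key=lambda f: f.rule_id,
        )
        assert evaluate_record(record) == combined


def test_evaluate_pure_and_idempotent(messy_registry):
    records, _ = messy_registry
    record = records[0]
    snapshot = copy.deepcopy(record)
    first = evaluate_record(record)
    second = evaluate_record(record)
    assert first == second
    assert record == snapshot


def test_disabling_a_rule_removes_exactly_its_findings(messy_registry):
    records, _ = messy_registry
    full_config = AuditConfig()
    reduced = AuditConfig(enabled_rules=full_config.enabled_rules - {"R-PI-NIL"})
    for record in records[:300]:
        full = evaluate_record(record, full_config)
        without = evaluate_record(record, reduced)
        assert without == [f for f in full if f.rule_id != "R-PI-NIL"]


def test_clean_records_have_no_findings(clean_registry):
    records, _ = clean_registry
    assert all(evaluate_record(r) == [] for r in records)
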