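"""Scope classification, ambiguity flags, and the truly-foreign test."""

from datetime import date

import pytest

from ctri_audit.config import AuditConfig
from ctri_audit.record_model import Scope, TrialRecord
from ctri_audit.scope_classifier import (
    ambiguity_flags,
    classify_scope,
    is_drug_trial,
    is_truly_foreign,
    scope_result,
)
from ctri_audit.synthetic_registry import SyntheticConfig, generate_registry


def _record(**kwargs):
    kwargs.setdefault("ctri_number", "CTRI/2015/06/000001")
    return TrialRecord(**kwargs)


@pytest.mark.parametrize(
    "raw, expected",
    [
        ("Drug", True),
        ("drug ", True),
        ("DrugAyurveda", False),
        ("Not Available", False),
        (None, False),
        ("Ayurveda", False),
    ],
)
def test_is_drug_trial(raw, expected):
    assert is_drug_trial(_record(type_of_study_raw=raw)) is expected


@pytest.mark.parametrize(
    "countries, expected",
    [
        ({"India"}, Scope.INDIAN),
        ({"India", "USA"}, Scope.MULTINATIONAL),
        ({"Senegal"}, Scope.FOREIGN),
        (set(), Scope.UNCLASSIFIABLE),
        ({"india"}, Scope.INDIAN),  # case-insensitive country matching
    ],
)
def test_classify_scope(countries, expected):
    assert classify_scope(_record(countries=frozenset(countries))) is expected


def test_consistent_indian_record_has_no_flags():
    record = _record(
        countries=frozenset({"India"}),
        recruit_status_india="Open to recruitment",
        date_first_enroll_india=date(2015, 7, 1),
        total_sample_size=200,
        sample_size_india=200,
    )
    assert ambiguity_flags(record, Scope.INDIAN) == []


def test_misfiled_foreign_trial_reconstructed_as_indian_is_consistent():
    """A no-country record whose India-side fields are fully populated and
    whose 200 subjects are all Indian behaves as a clean Indian trial once
    the country is fixed."""
    record = _record(
        countries=frozenset({"India"}),
        recruit_status_global="Not applicable",
        recruit_status_india="Open to recruitment",
        date_first_enroll_india=date(2012, 1, 15),
        total_sample_size=200,
        sample_size_india=200,
    )
    assert ambiguity_flags(record, Scope.INDIAN) == []


@pytest.mark.parametrize(
    "overrides, expected_flags",
    [
        ({"recruit_status_india": None}, {"IN-STATUS", }),
        ({"recruit_status_india": "Not applicable"}, {"IN-STATUS"}),
        ({"date_first_enroll_india": None}, {"IN-DATE"}),
        ({"sample_size_india": 0}, {"IN-SIZE", "IN-SIZE-MISMATCH"}),
        ({"total_sample_size": 300}, {"IN-SIZE-MISMATCH"}),
        ({"date_first_enroll_global": date(2015, 1, 1)}, {"IN-GDATE"}),
        ({"date_first_enroll_global": date(2015, 7, 1)}, set()),  # equal dates OK
    ],
)
def test_indian_flags(overrides, expected_flags):
    base = dict(
        countries=frozenset({"India"}),
        recruit_status_india="Open to recruitment",
        date_first_enroll_india=date(2015, 7, 1),
        total_sample_size=200,
        sample_size_india=200,
    )
    base.update(overrides)
    assert set(ambiguity_flags(_record(**base), Scope.INDIAN)) == expected_flags


def test_multinational_flags():
    record = _record(
        countries=frozenset({"India", "Germany"}),
        recruit_status_global="Open to recruitment",
        recruit_status_india="Open to recruitment",
        date_first_enroll_global=date(2014, 2, 1),
        date_first_enroll_india=date(2014, 3, 1),
        total_sample_size=1000,
        sample_size_india=1200,
    )
    assert ambiguity_flags(record, Scope.MULTINATIONAL) == ["MN-ISIZE-EXCESS"]
    # the India-date condition only counts when explicitly enabled
    record2 = _record(
        countries=frozenset({"India", "Germany"}),
        recruit_status_global="Completed",
        recruit_status_india="Completed",
        date_first_enroll_global=date(2014, 2, 1),
        total_sample_size=1000,
        sample_size_india=400,
    )
    assert ambiguity_flags(record2, Scope.MULTINATIONAL) == []
    strict = AuditConfig(include_mn_idate=True)
    assert ambiguity_flags(record2, Scope.MULTINATIONAL, strict) == ["MN-IDATE"]


def test_flags_reject_wrong_scope():
    with pytest.raises(ValueError):
        ambiguity_flags(_record(countries=frozenset({"Senegal"})), Scope.FOREIGN)


def _foreign_record(**overrides):
    base = dict(
        countries=frozenset({"Senegal"}),
        recruit_status_global="Completed",
        recruit_status_india="Not applicable",
        date_first_enroll_global=date(2013, 5, 1),
        date_first_enroll_india=None,
        total_sample_size=500,
        sample_size_india=None,
    )
    base.update(overrides)
    return _record(**base)


def test_truly_foreign_criteria():
    assert is_truly_foreign(_foreign_record()) is True
    # any recruitment from India disqualifies
    assert is_truly_foreign(_foreign_record(sample_size_india=1)) is False
    assert is_truly_foreign(_foreign_record(date_first_enroll_india=date(2013, 6, 1))) is False
    assert is_truly_foreign(_foreign_record(recruit_status_india="Open to recruitment")) is False
    assert is_truly_foreign(_foreign_record(recruit_status_global="Not applicable")) is False
    assert is_truly_foreign(_foreign_record(total_sample_size=0)) is False
    # zero India sample size counts as no India recruitment
    assert is_truly_foreign(_foreign_record(sample_size_india=0)) is True


def test_truly_foreign_requires_foreign_scope():
    with pytest.raises(ValueError):
        is_truly_foreign(_record(countries=frozenset({"India"})))


def test_scope_partition(messy_registry):
    """Every record maps to exactly one scope class; counts sum to size."""
    records, _ = messy_registry
    counts = {s: 0 for s in Scope}
    for record in records:
        counts[classify_scope(record)] += 1
    assert sum(counts.values()) == len(records)


def test_unambiguous_iff_no_flags(messy_registry):
    records, _ = messy_registry
    for record in records:
        result = scope_result(record)
        assert result.unambiguous == (len(result.flags) == 0)


def _oracle_indian_flags(r):
    """Independent literal re-statement of the Indian-side filter."""
    flags = []
    status = (r.recruit_status_india or "").strip().lower()
    if status in ("", "nil", "na", "n/a", "not available", "not applicable"):
        flags.append("IN-STATUS")
    if r.date_first_enroll_india is None:
        flags.append("IN-DATE")
    if not r.sample_size_india:
        flags.append("IN-SIZE")
    if r.total_sample_size is not None and r.sample_size_india is not None \
            and r.total_sample_size != r.sample_size_india:
        flags.append("IN-SIZE-MISMATCH")
    if r.date_first_enroll_global is not None \
            and r.date_first_enroll_global != r.date_first_enroll_india:
        flags.append("IN-GDATE")
    return flags


def _oracle_mn_flags(r):
    flags = []
    for field_value, flag in (
        (r.recruit_status_global, "MN-GSTATUS"),
        (r.recruit_status_india, "MN-ISTATUS"),
    ):
        status = (field_value or "").strip().lower()
        if status in ("", "nil", "na", "n/a", "not available", "not applicable"):
            flags.append(flag)
    if r.date_first_enroll_global is None:
        flags.append("MN-GDATE")
    if not r.total_sample_size:
        flags.append("MN-GSIZE")
    if r.sample_size_india is not None and r.total_sample_size is not None \
            and r.sample_size_india > r.total_sample_size:
        flags.append("MN-ISIZE-EXCESS")
    return flags


def test_flags_match_brute_force_oracle(messy_registry):
    """The flag engine agrees with a literal per-condition re-check."""
    records, _ = messy_registry
    checked = 0
    for record in records:
        scope = classify_scope(record)
        if scope is Scope.INDIAN:
            assert ambiguity_flags(record, scope) == _oracle_indian_flags(record)
            checked += 1
        elif scope is Scope.MULTINATIONAL:
            assert ambiguity_flags(record, scope) == _oracle_mn_flags(record)
            checked += 1
    assert checked >= 200


def test_clean_generation_is_unambiguous(clean_registry):
    records, _ = clean_registry
    for record in records:
        if classify_scope(record) in (Scope.INDIAN, Scope.MULTINATIONAL):
            assert scope_result(record).unambiguous
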