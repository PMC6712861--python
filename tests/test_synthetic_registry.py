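"""The synthetic generator: determinism, templates, injection semantics."""

import random

import pytest

from ctri_audit.name_audit import (
    CAPITALS,
    CATEGORIES,
    EXTRANEOUS,
    MIDDLE_NAME,
    ORDERING,
    SPACING,
    SPELLING,
    DISTINCT,
    classify_name_variant,
    normalize_person_name,
)
from ctri_audit.io_ctri import parse_record_html
from ctri_audit.record_model import RULE_CATALOGUE, Scope
from ctri_audit.rule_engine import evaluate_record
from ctri_audit.scope_classifier import classify_scope, is_truly_foreign, scope_result
from ctri_audit.synthetic_registry import (
    ConfigError,
    SyntheticConfig,
    generate_registry,
    perturb_name,
    sample_distinct_pis,
    write_fixture_html,
)
from ctri_audit._strdist import damerau_levenshtein

BINS = {"P1": 120, "P2": 120, "P3": 120, "P4": 120}


def test_identical_config_and_seed_identical_output():
    config = SyntheticConfig(bin_counts=BINS, seed=7)
    first_records, first_truth = generate_registry(config)
    second_records, second_truth = generate_registry(config)
    assert first_records == second_records
    assert first_truth.injected == second_truth.injected
    assert first_truth.true_pi == second_truth.true_pi
    # byte-identical once rendered
    assert [write_fixture_html(r) for r in first_records[:20]] == [
        write_fixture_html(r) for r in second_records[:20]
    ]


def test_different_seed_different_registry():
    a, _ = generate_registry(SyntheticConfig(bin_counts=BINS, injections={}, seed=1))
    b, _ = generate_registry(SyntheticConfig(bin_counts=BINS, injections={}, seed=2))
    assert a != b


def test_clean_baseline(clean_registry):
    """With all injection probabilities zero: no findings anywhere, and every
    Indian/Multinational record is unambiguous."""
    records, truth = clean_registry
    assert truth.injected == {}
    for record in records:
        assert evaluate_record(record) == []
        if classify_scope(record) in (Scope.INDIAN, Scope.MULTINATIONAL):
            assert scope_result(record).unambiguous
        if classify_scope(record) is Scope.FOREIGN:
            assert is_truly_foreign(record)


def test_saturation_every_p1_record_has_ec_excess():
    config = SyntheticConfig(
        bin_counts=BINS, injections={"R-EC-EXCESS": {"P1": 1.0}}, seed=3
    )
    records, _ = generate_registry(config)
    for record in records:
        in_p1 = record.registered_on.year <= 2009
        has_excess = len(record.ethics_committees) > len(record.sites)
        assert has_excess == in_p1


def test_unique_ctri_numbers(messy_registry):
    records, _ = messy_registry
    ids = [r.ctri_number for r in records]
    assert len(set(ids)) == len(ids)


def test_infeasible_config_is_rejected():
    """A positive injection probability with no applicable records must name
    the conflicting rule."""
    config = SyntheticConfig(
        bin_counts=BINS,
        drug_fraction=1.0,
        indian_interventional_fraction=1.0,
        mn_interventional_fraction=1.0,
        injections={"R-PMS-PH4": 0.5},
        seed=5,
    )
    with pytest.raises(ConfigError, match="R-PMS-PH4"):
        generate_registry(config)


def test_invalid_probability_rejected():
    with pytest.raises(ConfigError):
        SyntheticConfig(injections={"R-PI-NIL": 1.5})
    with pytest.raises(ConfigError):
        SyntheticConfig(injections={"R-BOGUS": 0.5})
    with pytest.raises(ConfigError):
        SyntheticConfig(bin_counts={"P1": -1})


def test_injected_records_trip_exactly_their_rules(messy_registry):
    """Ground-truth labels match audited findings rule-for-rule on the rules
    whose findings are record-local (cohort membership plays no role)."""
    records, truth = messy_registry
    local_rules = set(RULE_CATALOGUE) - {"R-SCOPE"}
    for record in records:
        found = {f.rule_id for f in evaluate_record(record)}
        injected = truth.injected.get(record.ctri_number, frozenset())
        assert found & local_rules == injected & local_rules
        # R-SCOPE findings appear iff injected, too, for scope-bearing records
        if classify_scope(record) in (Scope.INDIAN, Scope.MULTINATIONAL):
            assert ("R-SCOPE" in found) == ("R-SCOPE" in injected)


def test_no_cross_contamination_single_rule():
    """Injecting only one rule yields findings for that rule alone."""
    config = SyntheticConfig(bin_counts=BINS, injections={"R-PI-NIL": 0.5}, seed=9)
    records, truth = generate_registry(config)
    rule_ids = {f.rule_id for r in records for f in evaluate_record(r)}
    assert rule_ids <= {"R-PI-NIL"}
    assert sum(1 for v in truth.injected.values() if v) > 0


@pytest.mark.parametrize("category", CATEGORIES)
def test_perturbations_stay_within_their_category(category):
    rng = random.Random(13)
    canonical = "Dr Kavita Chandra Deshpande"
    base = normalize_person_name(canonical)
    for _ in range(25):
        variant = perturb_name(canonical, category, rng)
        verdict = classify_name_variant(base, normalize_person_name(variant))
        assert verdict != DISTINCT


def test_vacuous_perturbations_return_input():
    rng = random.Random(1)
    assert perturb_name("Dr Anita Rao", MIDDLE_NAME, rng) == "Dr Anita Rao"
    assert perturb_name("Jo", ORDERING, rng) == "Jo"
    with pytest.raises(ValueError):
        perturb_name("Dr Anita Rao", "NOT_A_CATEGORY", rng)


def test_middle_name_perturbation_drops_a_token():
    rng = random.Random(2)
    out = perturb_name("Dr Anita Kumar Rao", MIDDLE_NAME, rng)
    assert out == "Dr Anita Rao"


def test_extraneous_appends_degree():
    rng = random.Random(3)
    out = perturb_name("Anita Rao", EXTRANEOUS, rng)
    assert out == "Dr Anita Rao"
    out2 = perturb_name("Dr Anita Rao", EXTRANEOUS, rng)
    assert out2.startswith("Dr Anita Rao ") and out2.split()[-1] in {"MD", "MBBS", "PhD"}


def test_sampled_pis_are_pairwise_distinct():
    rng = random.Random(4)
    names = sample_distinct_pis(50, rng)
    normalized = [normalize_person_name(n) for n in names]
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            assert classify_name_variant(normalized[i], normalized[j]) == DISTINCT


def test_surname_pool_pairwise_separated():
    """The bundled surname list keeps every pair beyond the default matching
    cutoff (edit distance >= 3)."""
    from ctri_audit._lexicons import SURNAMES

    lowered = [s.lower() for s in SURNAMES]
    for i in range(len(lowered)):
        for j in range(i + 1, len(lowered)):
            assert damerau_levenshtein(lowered[i], lowered[j]) >= 3


def test_fixture_round_trip_on_random_records(messy_registry):
    records, _ = messy_registry
    step = max(1, len(records) // 100)
    for record in records[::step][:100]:
        assert parse_record_html(write_fixture_html(record)) == record


def test_clean_indian_template_renders_india_pair_only(clean_registry):
    records, _ = clean_registry
    indian = next(r for r in records if classify_scope(r) is Scope.INDIAN)
    page = write_fixture_html(indian)
    parsed = parse_record_html(page)
    assert parsed.date_first_enroll_global is None
    assert parsed.date_first_enroll_india is not None
    assert parsed.total_sample_size == parsed.sample_size_india


def test_many_committee_blocks_render():
    config = SyntheticConfig(bin_counts={"P1": 30, "P2": 0, "P3": 0, "P4": 0},
                             injections={"R-EC-EXCESS": 1.0}, seed=21)
    records, _ = generate_registry(config)
    record = records[0]
    page = write_fixture_html(record)
    assert page.count("<tr><td>Institutional Ethics Committee") + \
        page.count("<tr><td>Independent Ethics Committee") == len(record.ethics_committees)
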