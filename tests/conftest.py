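"""Shared fixtures: synthetic registries under different error regimes."""

import pytest

from ctri_audit.record_model import RULE_CATALOGUE
from ctri_audit.synthetic_registry import SyntheticConfig, generate_registry

SMALL_BINS = {"P1": 150, "P2": 150, "P3": 150, "P4": 150}


@pytest.fixture(scope="session")
def clean_registry():
    """A registry with no injected errors: every record internally consistent."""
    config = SyntheticConfig(bin_counts=SMALL_BINS, injections={}, seed=11)
    return generate_registry(config)


@pytest.fixture(scope="session")
def messy_registry():
    """A registry with every rule injected at a high rate (for oracle and
    round-trip tests that want structural variety)."""
    config = SyntheticConfig(
        bin_counts={"P1": 250, "P2": 250, "P3": 250, "P4": 250},
        injections={rule: 0.3 for rule in RULE_CATALOGUE},
        seed=23,
    )
    return generate_registry(config)
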