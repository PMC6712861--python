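"""Synthetic CTRI-like registries with ground-truth error injection.

Records are first built internally consistent for their geographic scope
(an Indian-template record recruits only in India, carries the India-side
status/date/size triple, and mirrors the India sample size into the total;
a truly-foreign template satisfies the three no-India-arm criteria), then
deficiencies are injected independently per rule and record with
configurable per-bin probabilities.  Independence makes the binomial oracle
exact: the audited rate of a rule over its cohort is a binomial proportion
around the injected probability.

The default injection rates and registry composition reproduce the April
2018 CTRI snapshot conditions the audit is modelled on (record counts,
drug/scope mix, per-bin deficiency rates); tests that need a clean or
saturated registry override them explicitly.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Mapping, Optional, Sequence, Union

from . import _lexicons
from .io_ctri import render_record_html
from .name_audit import (
    ABBREVIATION,
    CAPITALS,
    CATEGORIES,
    EXTRANEOUS,
    MIDDLE_NAME,
    ORDERING,
    SPACING,
    SPELLING,
)
from ._strdist import damerau_levenshtein
from .record_model import (
    EthicsCommittee,
    Phase,
    RULE_CATALOGUE,
    Site,
    TrialRecord,
    TypeOfTrial,
)
from .temporal_audit import BIN_LABELS, TIME_BINS

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised for an internally infeasible synthetic configuration."""


#: record kinds, in generation order
KINDS = (
    "indian_int", "indian_pms", "mn_int", "mn_pms", "foreign", "nocountry",
    "babe", "tosna", "observational",
)

_NUMBERED = (Phase.PHASE_1, Phase.PHASE_1_2, Phase.PHASE_2, Phase.PHASE_2_3,
             Phase.PHASE_3, Phase.PHASE_3_4, Phase.PHASE_4)

InjectionSpec = Union[float, Mapping[str, float]]

#: default per-bin injection rates: the snapshot's observed per-bin
#: deficiency rates, used as the generator's study conditions.
DEFAULT_INJECTIONS: dict[str, InjectionSpec] = {
    "R-SCOPE/Indian": {"P1": 0.631, "P2": 0.239, "P3": 0.044, "P4": 0.03},
    "R-SCOPE/Multinational": {"P1": 0.092, "P2": 0.051, "P3": 0.009, "P4": 0.038},
    "R-INT-PMSPHASE/Indian": {"P1": 0.0, "P2": 0.007, "P3": 0.042, "P4": 0.046},
    "R-PMS-PH4": {"P1": 1.0, "P2": 0.333, "P3": 0.225, "P4": 0.379},
    "R-BABE-PHASE": {"P1": 0.833, "P2": 0.196, "P3": 0.065, "P4": 0.137},
    "R-TOSNA-PHASE": {"P1": 0.875, "P2": 0.207, "P3": 0.062, "P4": 0.134},
    "R-CITY/Indian": {"P1": 0.0, "P2": 0.025, "P3": 0.028, "P4": 0.053},
    "R-CITY/Multinational": {"P1": 0.003, "P2": 0.013, "P3": 0.033, "P4": 0.013},
    "R-PI-NIL/Indian": {"P1": 0.103, "P2": 0.09, "P3": 0.044, "P4": 0.035},
    "R-PI-NIL/Multinational": {"P1": 0.541, "P2": 0.421, "P3": 0.32, "P4": 0.331},
    "R-SPONSOR-NIL/Indian": {"P1": 0.015, "P2": 0.027, "P3": 0.018, "P4": 0.01},
    "R-STATE-NIL/Indian": {"P1": 0.059, "P2": 0.021, "P3": 0.002, "P4": 0.001},
    "R-STATE-NIL/Multinational": {"P1": 0.125, "P2": 0.033, "P3": 0.013, "P4": 0.001},
    "R-EC-EXCESS/Indian": {"P1": 0.094, "P2": 0.099, "P3": 0.046, "P4": 0.095},
    "R-EC-EXCESS/Multinational": {"P1": 0.074, "P2": 0.066, "P3": 0.071, "P4": 0.034},
    "R-EC-FOREIGN/Multinational": 0.003,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generation parameters.  Identical config + seed => identical output."""

    #: records per registration bin (keys may be full labels or P1..P4).
    #: Defaults reconstruct the 12,673-record snapshot's growth curve.
    bin_counts: Mapping[str, int] = field(
        default_factory=lambda: {"P1": 350, "P2": 2800, "P3": 3500, "P4": 6023}
    )
    #: fraction of records whose Type of Study is exactly Drug
    drug_fraction: float = 2732 / 12673
    #: scope mix among drug records
    scope_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "Indian": 2070 / 2732,
            "Multinational": 640 / 2732,
            "Foreign": 21 / 2732,
            "NoCountry": 1 / 2732,
        }
    )
    #: Interventional share among Indian (resp. Multinational) drug records;
    #: the remainder is PMS-type
    indian_interventional_fraction: float = 1655 / 1764
    mn_interventional_fraction: float = 606 / 609
    #: among non-drug records: BA/BE and Type-of-Study-missing shares, the
    #: rest being observational records with diverse study-type categories
    babe_fraction: float = 0.02
    tosna_fraction: float = 0.089
    #: rule -> injection probability; a key may be refined per scope
    #: ("R-PI-NIL/Indian") and a value may be a per-bin map keyed P1..P4
    injections: Mapping[str, InjectionSpec] = field(
        default_factory=lambda: dict(DEFAULT_INJECTIONS)
    )
    #: distinct PI identities and how often a record renders a PI's name as
    #: one of its precomputed variants rather than canonically
    pi_pool_size: int = 50
    pi_variant_prob: float = 0.3
    variants_per_pi: int = 3
    sponsor_variant_prob: float = 0.3
    sponsor_conflict_prob: float = 0.1
    #: how each kind's global count distributes over bins (keys P1..P4 or
    #: full labels; kinds absent here follow the bin_counts profile).  The
    #: defaults skew drug trials toward the registry's early years, matching
    #: the snapshot in which per-bin ambiguity rates integrate to the
    #: overall unambiguity shares.
    kind_bin_weights: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "indian_int": {"P1": 150, "P2": 700, "P3": 600, "P4": 620},
            "indian_pms": {"P1": 150, "P2": 700, "P3": 600, "P4": 620},
            "mn_int": {"P1": 120, "P2": 260, "P3": 130, "P4": 130},
            "mn_pms": {"P1": 120, "P2": 260, "P3": 130, "P4": 130},
        }
    )
    #: size of the study-type category pool for observational records and the
    #: share of it first introduced in each bin (category-explosion shape)
    n_categories: int = 120
    category_bin_shares: tuple[float, float, float, float] = (0.065, 0.193, 0.252, 0.489)
    seed: int = 0

    def __post_init__(self) -> None:
        for label, count in self.bin_counts.items():
            if count < 0:
                raise ConfigError(f"negative record count for bin {label}")
        for frac_name in ("drug_fraction", "indian_interventional_fraction",
                          "mn_interventional_fraction", "babe_fraction",
                          "tosna_fraction", "pi_variant_prob",
                          "sponsor_variant_prob", "sponsor_conflict_prob"):
            value = getattr(self, frac_name)
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{frac_name} must lie in [0, 1]")
        if abs(sum(self.scope_mix.values()) - 1.0) > 1e-9:
            raise ConfigError("scope_mix must sum to 1")
        if self.babe_fraction + self.tosna_fraction > 1.0:
            raise ConfigError("babe_fraction + tosna_fraction must not exceed 1")
        for rule_key, spec in self.injections.items():
            base = rule_key.split("/")[0]
            if base not in RULE_CATALOGUE:
                raise ConfigError(f"unknown rule in injections: {rule_key}")
            values = spec.values() if isinstance(spec, Mapping) else [spec]
            for p in values:
                if not 0.0 <= p <= 1.0:
                    raise ConfigError(f"injection probability for {rule_key} outside [0, 1]")
        if not 1 <= self.pi_pool_size <= len(_lexicons.SURNAMES):
            raise ConfigError(
                f"pi_pool_size must lie in 1..{len(_lexicons.SURNAMES)} "
                "(distinct surnames keep synthetic identities separable)"
            )

    def injection_prob(self, rule_id: str, scope_name: Optional[str], bin_label: str) -> float:
        """Effective injection probability for a rule on a record of the given
        scope in the given bin (scope-refined keys take precedence)."""
        spec = None
        if scope_name is not None:
            spec = self.injections.get(f"{rule_id}/{scope_name}")
        if spec is None:
            spec = self.injections.get(rule_id)
        if spec is None:
            return 0.0
        if isinstance(spec, Mapping):
            short = bin_label.split(":")[0]
            return float(spec.get(bin_label, spec.get(short, 0.0)))
        return float(spec)


@dataclass
class GroundTruth:
    """Injected-error labels and identity maps for a generated registry."""

    injected: dict[str, frozenset[str]] = field(default_factory=dict)
    true_pi: dict[str, int] = field(default_factory=dict)
    sponsor_identity: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# name perturbation


def _recase(token: str) -> str:
    return token[:1].upper() + token[1:].lower()


def perturb_name(true_name: str, category: str, rng: random.Random) -> str:
    """Apply exactly one variation category to a canonical name rendering.

    Vacuous transformations (e.g. no middle token to drop) return the input
    unchanged with a debug log entry.
    """
    if category not in CATEGORIES:
        raise ValueError(f"unknown variation category: {category!r}")
    tokens = true_name.split()
    honorific = tokens[0] if tokens and tokens[0].lower() in _lexicons.HONORIFICS else None
    core = tokens[1:] if honorific else list(tokens)

    def rebuild(parts: Sequence[str]) -> str:
        return " ".join(([honorific] if honorific else []) + list(parts))

    if category == MIDDLE_NAME:
        if len(core) < 3:
            logger.debug("vacuous MIDDLE_NAME perturbation for %r", true_name)
            return true_name
        return rebuild(core[:1] + core[2:])
    if category == ABBREVIATION:
        candidates = [i for i, t in enumerate(core[:-1]) if len(t) > 1]
        if not candidates:
            logger.debug("vacuous ABBREVIATION perturbation for %r", true_name)
            return true_name
        i = rng.choice(candidates)
        return rebuild(core[:i] + [core[i][0]] + core[i + 1:])
    if category == SPELLING:
        candidates = [i for i, t in enumerate(core) if len(t) >= 3]
        if not candidates:
            logger.debug("vacuous SPELLING perturbation for %r", true_name)
            return true_name
        i = rng.choice(candidates)
        token = core[i]
        pos = rng.randrange(len(token))
        if rng.random() < 0.5 and pos < len(token) - 1 and token[pos].lower() != token[pos + 1].lower():
            mutated = token[:pos] + token[pos + 1] + token[pos] + token[pos + 2:]
        else:
            alphabet = "abcdefghijklmnopqrstuvwxyz".replace(token[pos].lower(), "")
            mutated = token[:pos] + rng.choice(alphabet) + token[pos + 1:]
        return rebuild(core[:i] + [_recase(mutated)] + core[i + 1:])
    if category == ORDERING:
        if len(core) < 2:
            logger.debug("vacuous ORDERING perturbation for %r", true_name)
            return true_name
        return rebuild(core[::-1])
    if category == SPACING:
        if len(core) >= 2:
            i = rng.randrange(len(core) - 1)
            return rebuild(core[:i] + [core[i] + core[i + 1]] + core[i + 2:])
        token = core[0]
        if len(token) < 4:
            logger.debug("vacuous SPACING perturbation for %r", true_name)
            return true_name
        cut = rng.randrange(2, len(token) - 1)
        return rebuild([token[:cut], token[cut:].lower()])
    if category == CAPITALS:
        return true_name.upper() if rng.random() < 0.5 else true_name.lower()
    # EXTRANEOUS
    if honorific is None:
        return "Dr " + true_name
    return true_name + " " + rng.choice(["MD", "MBBS", "PhD"])


def sample_distinct_pis(n: int, rng: random.Random) -> list[str]:
    """Sample n canonical PI renderings representing n distinct people.

    Surnames are drawn without replacement from the bundled surname list,
    which is pairwise at edit distance >= 3, so no two sampled identities can
    be conflated by any rung of the matching ladder at max_edit <= 2.  (Two
    real people genuinely sharing a name is exactly the failure mode registry
    data cannot resolve; the generator represents distinguishable people.)
    """
    if n > len(_lexicons.SURNAMES):
        raise ConfigError(f"at most {len(_lexicons.SURNAMES)} distinct synthetic PIs")
    surnames = rng.sample(list(_lexicons.SURNAMES), n)
    names = []
    for surname in surnames:
        first = rng.choice(_lexicons.FIRST_NAMES)
        parts = ["Dr", first]
        if rng.random() < 0.4:
            parts.append(rng.choice(_lexicons.MIDDLE_NAMES))
        parts.append(surname)
        names.append(" ".join(parts))
    return names


# ---------------------------------------------------------------------------
# registry generation


def _largest_remainder(total: int, weights: Sequence[float]) -> list[int]:
    """Deterministic apportionment of ``total`` by ``weights``."""
    weight_sum = sum(weights)
    if total == 0 or weight_sum == 0:
        return [0] * len(weights)
    quotas = [total * w / weight_sum for w in weights]
    counts = [int(q) for q in quotas]
    shortfall = total - sum(counts)
    order = sorted(range(len(weights)), key=lambda i: (counts[i] - quotas[i], i))
    for i in order[:shortfall]:
        counts[i] += 1
    return counts


def _kind_fractions(config: SyntheticConfig) -> dict[str, float]:
    d = config.drug_fraction
    nd = 1.0 - d
    mix = config.scope_mix
    return {
        "indian_int": d * mix.get("Indian", 0.0) * config.indian_interventional_fraction,
        "indian_pms": d * mix.get("Indian", 0.0) * (1 - config.indian_interventional_fraction),
        "mn_int": d * mix.get("Multinational", 0.0) * config.mn_interventional_fraction,
        "mn_pms": d * mix.get("Multinational", 0.0) * (1 - config.mn_interventional_fraction),
        "foreign": d * mix.get("Foreign", 0.0),
        "nocountry": d * mix.get("NoCountry", 0.0),
        "babe": nd * config.babe_fraction,
        "tosna": nd * config.tosna_fraction,
        "observational": nd * (1 - config.babe_fraction - config.tosna_fraction),
    }


_SCOPE_OF_KIND = {
    "indian_int": "Indian", "indian_pms": "Indian", "babe": "Indian",
    "tosna": "Indian", "observational": "Indian",
    "mn_int": "Multinational", "mn_pms": "Multinational",
    "foreign": None, "nocountry": None,
}

_RULE_APPLIES = {
    "R-SCOPE": lambda kind: _SCOPE_OF_KIND[kind] is not None,
    "R-INT-PMSPHASE": lambda kind: kind in ("indian_int", "mn_int"),
    "R-PMS-PH4": lambda kind: kind in ("indian_pms", "mn_pms"),
    "R-BABE-PHASE": lambda kind: kind == "babe",
    "R-TOSNA-PHASE": lambda kind: kind == "tosna",
    "R-CITY": lambda kind: True,
    "R-PI-NIL": lambda kind: True,
    "R-SPONSOR-NIL": lambda kind: True,
    "R-STATE-NIL": lambda kind: True,
    "R-EC-EXCESS": lambda kind: True,
    "R-EC-FOREIGN": lambda kind: kind in ("mn_int", "mn_pms"),
    "R-EC-UNIDENT": lambda kind: True,
}


def _category_pool(config: SyntheticConfig, rng: random.Random) -> list[list[str]]:
    """Study-type category strings for observational records, partitioned into
    the cumulative pools available per bin (new categories appear over time)."""
    others = [v for v in _lexicons.STUDY_TYPE_VOCAB if v != "Drug"]
    combos = list(others)
    combos += [f"Drug{o}" for o in others]
    for i, a in enumerate(others):
        for b in others[i + 1:]:
            combos.append(f"{a}{b}")
    rng.shuffle(combos)
    pool = combos[: config.n_categories]
    per_bin = _largest_remainder(len(pool), list(config.category_bin_shares))
    cumulative, start = [], 0
    for count in per_bin:
        start += count
        cumulative.append(pool[:max(start, 1)])
    return cumulative


def _uniform_date(time_bin, rng: random.Random) -> date:
    span = (time_bin.end - time_bin.start).days
    return time_bin.start + timedelta(days=rng.randrange(span))


def generate_registry(config: SyntheticConfig) -> tuple[list[TrialRecord], GroundTruth]:
    """Generate a registry and its ground truth under ``config``.

    Raises :class:`ConfigError` when a rule has a positive injection
    probability but no applicable record exists (e.g. R-PMS-PH4 with zero
    PMS-type records).
    """
    rng = random.Random(config.seed)
    truth = GroundTruth()

    pis = sample_distinct_pis(config.pi_pool_size, rng)
    pi_variants = [
        [perturb_name(name, rng.choice(CATEGORIES), rng) for _ in range(config.variants_per_pi)]
        for name in pis
    ]
    sponsors = list(_lexicons.SPONSORS)
    sponsor_variants = []
    for name, _cls in sponsors:
        sponsor_variants.append([
            perturb_name(name, CAPITALS, rng),
            perturb_name(name, SPACING, rng),
            name + " Pvt Ltd" if not name.endswith(("Ltd", "Limited", "Inc", "Corp")) else name + ".",
        ])
    alt_class = {
        "Pharmaceutical industry-Indian": "Pharmaceutical industry-Global",
        "Pharmaceutical industry-Global": "Pharmaceutical industry-Indian",
        "Contract research organization": "Research institution",
        "Government funding agency": "Research institution",
        "Research institution": "Research institution and hospital",
        "Research institution and hospital": "Research institution",
        "Others": "Research institution",
    }

    fractions = _kind_fractions(config)
    bin_totals = {}
    for time_bin in TIME_BINS:
        short = time_bin.label.split(":")[0]
        bin_totals[time_bin.label] = int(
            config.bin_counts.get(time_bin.label, config.bin_counts.get(short, 0))
        )
    total = sum(bin_totals.values())
    # global-first apportionment: exact kind totals, then each kind spread
    # over bins by its own weight profile (default: the registry growth curve)
    global_counts = dict(zip(KINDS, _largest_remainder(total, [fractions[k] for k in KINDS])))
    kind_counts: dict[str, dict[str, int]] = {label: {} for label in BIN_LABELS}
    for kind in KINDS:
        weights_map = config.kind_bin_weights.get(kind)
        if weights_map is None:
            weights = [bin_totals[label] for label in BIN_LABELS]
        else:
            weights = [
                float(weights_map.get(label, weights_map.get(label.split(":")[0], 0.0)))
                for label in BIN_LABELS
            ]
        per_bin = _largest_remainder(global_counts[kind], weights)
        for label, count in zip(BIN_LABELS, per_bin):
            kind_counts[label][kind] = count

    # feasibility: a positive injection probability needs applicable records
    for rule_key, spec in config.injections.items():
        values = list(spec.values()) if isinstance(spec, Mapping) else [spec]
        if not any(v > 0 for v in values):
            continue
        base = rule_key.split("/")[0]
        applicable = sum(
            kind_counts[label][kind]
            for label in BIN_LABELS
            for kind in KINDS
            if _RULE_APPLIES[base](kind)
        )
        if applicable == 0:
            raise ConfigError(
                f"injection {rule_key} has positive probability but no applicable records"
            )

    category_pools = _category_pool(config, rng)
    foreign_countries = [c for c in _lexicons.COUNTRIES if c != "India"]

    records: list[TrialRecord] = []
    serial = 0
    for bin_index, time_bin in enumerate(TIME_BINS):
        label = time_bin.label
        for kind in KINDS:
            for _ in range(kind_counts[label][kind]):
                serial += 1
                registered = _uniform_date(time_bin, rng)
                record = _build_clean(
                    kind, serial, registered, bin_index, config, rng,
                    pis, pi_variants, sponsors, sponsor_variants, alt_class,
                    category_pools, foreign_countries, truth,
                )
                injected = _inject(record, kind, label, config, rng, foreign_countries)
                if injected:
                    truth.injected[record.ctri_number] = frozenset(injected)
                records.append(record)
    return records, truth


def _make_sites(n: int, rng: random.Random, foreign_country: Optional[str] = None) -> tuple[Site, ...]:
    sites = []
    for _ in range(n):
        if foreign_country is None:
            city = rng.choice(_lexicons.INDIA_CITIES)
            state = rng.choice(_lexicons.INDIA_STATES)
            country = "India"
        else:
            city = rng.choice(("Geneva", "Boston", "Nairobi", "Lyon", "Osaka"))
            state = "Overseas Region"
            country = foreign_country
        institution = rng.choice(_lexicons.HOSPITAL_TEMPLATES).format(city=city)
        sites.append(Site(institution, city, state, country))
    return tuple(sites)


def _make_ecs(sites: Sequence[Site]) -> tuple[EthicsCommittee, ...]:
    return tuple(
        EthicsCommittee(
            f"Institutional Ethics Committee, {s.institution_name}",
            s.institution_name,
            f"{s.city}, {s.state}",
        )
        for s in sites
    )


def _build_clean(
    kind, serial, registered, bin_index, config, rng,
    pis, pi_variants, sponsors, sponsor_variants, alt_class,
    category_pools, foreign_countries, truth,
) -> TrialRecord:
    ctri = f"CTRI/{registered.year}/{registered.month:02d}/{serial:06d}"

    pi_id = rng.randrange(len(pis))
    if rng.random() < config.pi_variant_prob:
        pi_name = rng.choice(pi_variants[pi_id])
    else:
        pi_name = pis[pi_id]
    truth.true_pi[ctri] = pi_id

    sponsor_id = rng.randrange(len(sponsors))
    canonical_name, canonical_class = sponsors[sponsor_id]
    sponsor_name = (
        rng.choice(sponsor_variants[sponsor_id])
        if rng.random() < config.sponsor_variant_prob
        else canonical_name
    )
    sponsor_class = (
        alt_class[canonical_class]
        if rng.random() < config.sponsor_conflict_prob
        else canonical_class
    )
    truth.sponsor_identity[sponsor_name] = sponsor_id

    enroll = registered + timedelta(days=rng.randrange(20, 120))
    size = int(rng.randrange(20, 2000))

    study_raw = "Drug"
    type_of_trial = TypeOfTrial.INTERVENTIONAL
    phase = rng.choice(_NUMBERED)
    countries: frozenset[str] = frozenset({"India"})
    status_g: Optional[str] = "Not applicable"
    status_i: Optional[str] = rng.choice(("Open to recruitment", "Completed"))
    date_g: Optional[date] = None
    date_i: Optional[date] = enroll
    total: Optional[int] = size
    india: Optional[int] = size
    foreign_site_country = None

    if kind == "indian_pms":
        type_of_trial = TypeOfTrial.PMS
        phase = Phase.NA
    elif kind in ("mn_int", "mn_pms"):
        others = rng.sample(foreign_countries, rng.randrange(1, 4))
        countries = frozenset({"India", *others})
        status_g = rng.choice(("Open to recruitment", "Completed"))
        date_g = enroll - timedelta(days=rng.randrange(0, 30))
        total = size + int(rng.randrange(10, 3000))
        if kind == "mn_pms":
            type_of_trial = TypeOfTrial.PMS
            phase = Phase.NA
    elif kind == "foreign":
        country = rng.choice(foreign_countries)
        countries = frozenset({country})
        status_g = rng.choice(("Completed", "Not yet recruiting"))
        status_i = "Not applicable"
        date_g = enroll
        date_i = None
        india = None
        foreign_site_country = country
    elif kind == "nocountry":
        countries = frozenset()
    elif kind == "babe":
        study_raw = "DrugOther"
        type_of_trial = TypeOfTrial.BABE
        phase = Phase.NA
    elif kind == "tosna":
        study_raw = "Not Available"
        phase = Phase.NA
    elif kind == "observational":
        study_raw = rng.choice(category_pools[bin_index])
        type_of_trial = TypeOfTrial.OBSERVATIONAL
        phase = Phase.NA

    sites = _make_sites(rng.randrange(1, 4), rng, foreign_site_country)
    return TrialRecord(
        ctri_number=ctri,
        registered_on=registered,
        type_of_study_raw=study_raw,
        type_of_trial=type_of_trial,
        phase=phase,
        countries=countries,
        recruit_status_global=status_g,
        recruit_status_india=status_i,
        date_first_enroll_global=date_g,
        date_first_enroll_india=date_i,
        total_sample_size=total,
        sample_size_india=india,
        pi_name=pi_name,
        sponsor_name=sponsor_name,
        sponsor_classification=sponsor_class,
        sites=sites,
        ethics_committees=_make_ecs(sites),
        public_title=f"A study of regimen {serial % 97} in adult participants",
        scientific_title=f"Protocol {serial:06d}",
    )


def _inject(
    record: TrialRecord, kind: str, bin_label: str,
    config: SyntheticConfig, rng: random.Random,
    foreign_countries: Sequence[str],
) -> list[str]:
    scope_name = _SCOPE_OF_KIND[kind]
    injected = []
    for rule_id in RULE_CATALOGUE:
        if not _RULE_APPLIES[rule_id](kind):
            continue
        p = config.injection_prob(rule_id, scope_name, bin_label)
        if p <= 0.0 or rng.random() >= p:
            continue
        _apply_mutation(record, rule_id, scope_name, rng, foreign_countries)
        injected.append(rule_id)
    return injected


def _apply_mutation(record, rule_id, scope_name, rng, foreign_countries) -> None:
    if rule_id == "R-SCOPE":
        if scope_name == "Indian":
            mode = rng.randrange(3)
            if mode == 0 and record.sample_size_india is not None:
                record.total_sample_size = record.sample_size_india + rng.randrange(1, 500)
            elif mode == 1:
                record.recruit_status_india = None
            else:
                record.date_first_enroll_india = None
        else:
            mode = rng.randrange(3)
            if mode == 0:
                record.date_first_enroll_global = None
            elif mode == 1:
                record.recruit_status_global = "Not applicable"
            elif record.total_sample_size is not None:
                record.sample_size_india = record.total_sample_size + rng.randrange(1, 500)
            else:
                record.date_first_enroll_global = None
    elif rule_id == "R-INT-PMSPHASE":
        record.phase = Phase.PMS
    elif rule_id == "R-PMS-PH4":
        record.phase = Phase.PHASE_4
    elif rule_id in ("R-BABE-PHASE", "R-TOSNA-PHASE"):
        record.phase = rng.choice(_NUMBERED)
    elif rule_id == "R-CITY":
        sites = list(record.sites)
        i = rng.randrange(len(sites))
        bad = rng.choice((None, "Area 51", "X"))
        sites[i] = Site(sites[i].institution_name, bad, sites[i].state, sites[i].country)
        record.sites = tuple(sites)
    elif rule_id == "R-PI-NIL":
        record.pi_name = rng.choice(("nil", "NIL", "NA", "Not Available"))
    elif rule_id == "R-SPONSOR-NIL":
        record.sponsor_name = rng.choice(("nil", "NA", "Not Available"))
    elif rule_id == "R-STATE-NIL":
        sites = list(record.sites)
        i = rng.randrange(len(sites))
        sites[i] = Site(sites[i].institution_name, sites[i].city, None, sites[i].country)
        record.sites = tuple(sites)
    elif rule_id == "R-EC-EXCESS":
        extra = rng.randrange(1, 4)
        committees = list(record.ethics_committees)
        for j in range(extra + max(0, len(record.sites) - len(committees))):
            committees.append(
                EthicsCommittee(
                    f"Independent Ethics Committee Unit {j + 1}",
                    "Independent review board",
                    f"{rng.choice(_lexicons.INDIA_CITIES)}, India",
                )
            )
        record.ethics_committees = tuple(committees)
    elif rule_id == "R-EC-FOREIGN":
        committees = list(record.ethics_committees)
        if committees:
            # skip denylisted tokens ("Georgia"): they are not detectable by
            # design, so injecting them would break ground-truth labels
            usable = [c for c in foreign_countries if c not in _lexicons.EC_COUNTRY_DENYLIST]
            country = rng.choice([c for c in usable if c in record.countries] or usable)
            committees[0] = EthicsCommittee(
                f"National Bioethics Committee for Health Research, {country}",
                committees[0].affiliation,
                committees[0].address,
            )
            record.ethics_committees = tuple(committees)
    elif rule_id == "R-EC-UNIDENT":
        committees = list(record.ethics_committees)
        if committees:
            i = rng.randrange(len(committees))
            committees[i] = EthicsCommittee(committees[i].name, None, None)
            record.ethics_committees = tuple(committees)


def write_fixture_html(record: TrialRecord) -> str:
    """Render a record as a fixture-dialect page (round-trips through
    :func:`ctri_audit.io_ctri.parse_record_html`)."""
    return render_record_html(record)
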