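"""Audit configuration: lexicons, thresholds and rule toggles.

One :class:`AuditConfig` object carries everything the rule battery and the
report builder need.  It can be loaded from a TOML file (see
``AuditConfig.from_toml``) so a run is reproducible from a single artifact;
CLI flags override file values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Optional

from . import _lexicons
from .record_model import RULE_CATALOGUE


@dataclass(frozen=True)
class AuditConfig:
    missing_tokens: frozenset[str] = _lexicons.MISSING_TOKENS
    country_lexicon: tuple[str, ...] = _lexicons.COUNTRIES
    city_gazetteer: frozenset[str] = frozenset(_lexicons.INDIA_CITIES)
    #: gazetteer matching for R-CITY is opt-in; the structural checks
    #: (empty / digits / too short) always run.
    strict_city: bool = False
    #: country tokens ignored by foreign-EC detection
    ec_country_denylist: frozenset[str] = _lexicons.EC_COUNTRY_DENYLIST
    enabled_rules: frozenset[str] = frozenset(RULE_CATALOGUE)
    #: count the MN-IDATE condition towards the Multinational unambiguity
    #: verdict (off by default: a missing India enrollment date alone does
    #: not disqualify a Multinational record)
    include_mn_idate: bool = False
    #: maximum edit distance for the name-variant matching ladder
    max_edit: int = 2

    def __post_init__(self) -> None:
        unknown = self.enabled_rules - set(RULE_CATALOGUE)
        if unknown:
            raise ValueError(f"unknown rule ids in config: {sorted(unknown)}")
        if self.max_edit < 0:
            raise ValueError("max_edit must be >= 0")

    def with_overrides(self, **kwargs: Any) -> "AuditConfig":
        return replace(self, **kwargs)

    @classmethod
    def from_toml(cls, path: str) -> "AuditConfig":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        section = data.get("audit", data)
        kwargs: dict[str, Any] = {}
        if "missing_tokens" in section:
            kwargs["missing_tokens"] = frozenset(t.lower() for t in section["missing_tokens"])
        if "country_lexicon" in section:
            kwargs["country_lexicon"] = tuple(section["country_lexicon"])
        if "city_gazetteer" in section:
            kwargs["city_gazetteer"] = frozenset(section["city_gazetteer"])
        for key in ("strict_city", "include_mn_idate", "max_edit"):
            if key in section:
                kwargs[key] = section[key]
        if "ec_country_denylist" in section:
            kwargs["ec_country_denylist"] = frozenset(section["ec_country_denylist"])
        if "enabled_rules" in section:
            kwargs["enabled_rules"] = frozenset(section["enabled_rules"])
        try:
            return cls(**kwargs)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"invalid audit config {path}: {exc}") from exc


DEFAULT_CONFIG = AuditConfig()
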