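"""Model-style front end: build an audit from records, fit, inspect results.

``RegistryAudit`` is constructed from a record list (or straight from a
SQLite registry / directory of record pages) plus an :class:`AuditConfig`;
``fit()`` runs scope classification, the rule battery, name clustering and
the temporal report, and returns an :class:`AuditResults` carrying the
estimates.  Every reported error rate is a binomial proportion, so the
results object attaches Wilson score intervals and renders a
statsmodels-style ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .config import AuditConfig, DEFAULT_CONFIG
from .io_ctri import load_registry_sqlite, parse_record_html
from .name_audit import NameCluster, cluster_names, sponsor_audit
from .record_model import (
    AuditFinding,
    AuditReport,
    ScopeResult,
    TrialRecord,
    is_missing_token,
)
from .rule_engine import evaluate_record
from .scope_classifier import is_truly_foreign, scope_result
from .temporal_audit import (
    build_cohorts,
    build_report,
    category_first_appearance_series,
    format_share,
)


@dataclass(frozen=True)
class FunnelCounts:
    """The data-processing funnel: total -> drug -> scope -> unambiguous ->
    type splits, plus the truly-foreign count."""

    total: int
    drug: int
    indian: int
    multinational: int
    foreign: int
    no_country: int
    unambiguous_indian: int
    unambiguous_multinational: int
    indian_interventional: int
    indian_pms: int
    mn_interventional: int
    mn_pms: int
    truly_foreign: int
    redefined_babe: int
    redefined_tosna: int

    def check_conservation(self) -> None:
        """Every funnel split must conserve its parent count."""
        assert self.indian + self.multinational + self.foreign + self.no_country == self.drug
        assert self.unambiguous_indian <= self.indian
        assert self.unambiguous_multinational <= self.multinational
        assert self.indian_interventional + self.indian_pms <= self.unambiguous_indian
        assert self.mn_interventional + self.mn_pms <= self.unambiguous_multinational
        assert self.truly_foreign <= self.foreign


class RegistryAudit:
    """The audit 'model': a registry plus the configuration to audit it."""

    def __init__(self, records: Sequence[TrialRecord], config: AuditConfig = DEFAULT_CONFIG):
        self.records = list(records)
        self.config = config
        ids = [r.ctri_number for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate CTRI numbers in registry")

    @classmethod
    def from_sqlite(cls, path: str | Path, config: AuditConfig = DEFAULT_CONFIG,
                    column_map: Optional[Mapping[str, str]] = None) -> "RegistryAudit":
        return cls(load_registry_sqlite(path, column_map), config)

    @classmethod
    def from_html_dir(cls, path: str | Path, config: AuditConfig = DEFAULT_CONFIG,
                      pattern: str = "*.html") -> "RegistryAudit":
        records = [
            parse_record_html(p.read_text(encoding="utf-8"))
            for p in sorted(Path(path).glob(pattern))
        ]
        return cls(records, config)

    def fit(self, cluster_pi_names: bool = True) -> "AuditResults":
        """Run the full pipeline.

        ``cluster_pi_names=False`` skips the quadratic PI-name clustering
        step for very large registries where only the rule/rate series are
        needed.
        """
        config = self.config
        scope_results = {r.ctri_number: scope_result(r, config) for r in self.records}
        findings = [f for r in self.records for f in evaluate_record(r, config)]
        report = build_report(self.records, config, scope_results, findings)
        cohorts = build_cohorts(self.records, scope_results)
        funnel = FunnelCounts(
            total=len(self.records),
            drug=len(cohorts.drug),
            indian=len(cohorts.indian_drug),
            multinational=len(cohorts.mn_drug),
            foreign=len(cohorts.foreign_drug),
            no_country=len(cohorts.nocountry_drug),
            unambiguous_indian=len(cohorts.unambiguous_indian),
            unambiguous_multinational=len(cohorts.unambiguous_mn),
            indian_interventional=len(cohorts.indian_interventional),
            indian_pms=len(cohorts.indian_pms),
            mn_interventional=len(cohorts.mn_interventional),
            mn_pms=len(cohorts.mn_pms),
            truly_foreign=sum(
                1 for r in cohorts.foreign_drug if is_truly_foreign(r, config)
            ),
            redefined_babe=len(cohorts.redefined_babe),
            redefined_tosna=len(cohorts.redefined_tosna),
        )
        pi_clusters: Optional[list[NameCluster]] = None
        if cluster_pi_names:
            pi_names = sorted(
                {r.pi_name for r in self.records
                 if not is_missing_token(r.pi_name, config.missing_tokens)}
            )
            pi_clusters = cluster_names(pi_names, config.max_edit) if pi_names else []
        sponsor_clusters, sponsor_conflicts = sponsor_audit(self.records, config.max_edit)
        return AuditResults(
            model=self,
            scope_results=scope_results,
            findings=findings,
            report=report,
            funnel=funnel,
            pi_clusters=pi_clusters,
            sponsor_clusters=sponsor_clusters,
            sponsor_conflicts=sponsor_conflicts,
        )


@dataclass
class AuditResults:
    """Fitted audit: findings, funnel, per-bin rate estimates and clusters."""

    model: RegistryAudit
    scope_results: dict[str, ScopeResult]
    findings: list[AuditFinding]
    report: AuditReport
    funnel: FunnelCounts
    pi_clusters: Optional[list[NameCluster]]
    sponsor_clusters: list[NameCluster]
    sponsor_conflicts: dict[str, frozenset[str]] = field(default_factory=dict)

    def rates_frame(self, alpha: float = 0.05) -> pd.DataFrame:
        """All report cells as a DataFrame with Wilson score intervals."""
        rows = []
        for (rule_id, bin_label, cohort), cell in sorted(
            self.report.cells.items(), key=lambda kv: (kv[0][0], kv[0][2], kv[0][1])
        ):
            if cell.denominator:
                low, high = proportion_confint(
                    cell.numerator, cell.denominator, alpha=alpha, method="wilson"
                )
                ci = (100 * low, 100 * high)
            else:
                ci = (float("nan"), float("nan"))
            rows.append(
                {
                    "rule": rule_id,
                    "cohort": cohort,
                    "bin": bin_label,
                    "numerator": cell.numerator,
                    "denominator": cell.denominator,
                    "rate_percent": cell.rate_percent,
                    "ci_low": round(ci[0], 2),
                    "ci_high": round(ci[1], 2),
                }
            )
        return pd.DataFrame(rows)

    def category_first_appearance(self) -> pd.DataFrame:
        cells = category_first_appearance_series(self.model.records)
        return pd.DataFrame(
            [
                {"bin": label, "new_categories": c.numerator,
                 "total_categories": c.denominator, "share_percent": c.rate_percent}
                for label, c in cells.items()
            ]
        )

    def findings_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"ctri_number": f.ctri_number, "rule_id": f.rule_id, "evidence": f.evidence}
             for f in self.findings]
        )

    def summary(self) -> str:
        """Human-readable audit summary: funnel, then per-cell rates."""
        f = self.funnel
        lines = [
            "Registry audit summary",
            "=" * 70,
            f"Records:                      {f.total}",
            f"Drug trials:                  {f.drug}",
            f"  Indian:                     {f.indian}",
            f"  Multinational:              {f.multinational}",
            f"  Foreign:                    {f.foreign}"
            f" (truly foreign: {f.truly_foreign})",
            f"  No country listed:          {f.no_country}",
            f"Unambiguously Indian:         {f.unambiguous_indian}"
            f" ({format_share(f.unambiguous_indian, f.indian) or '-'}% of Indian)",
            f"Unambiguously Multinational:  {f.unambiguous_multinational}"
            f" ({format_share(f.unambiguous_multinational, f.multinational) or '-'}% of Multinational)",
            f"  Indian Interventional/PMS:  {f.indian_interventional}/{f.indian_pms}",
            f"  MN Interventional/PMS:      {f.mn_interventional}/{f.mn_pms}",
            f"Findings:                     {len(self.findings)}",
            f"Sponsor clusters (conflicts): {len(self.sponsor_clusters)}"
            f" ({len(self.sponsor_conflicts)})",
        ]
        if self.pi_clusters is not None:
            lines.append(f"PI name clusters:             {len(self.pi_clusters)}")
        lines.append("")
        lines.append("Error rates (percent, Wilson 95% CI)")
        lines.append("-" * 70)
        frame = self.rates_frame()
        lines.append(frame.to_string(index=False))
        return "\n".join(lines)
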