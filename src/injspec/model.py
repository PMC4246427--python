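"""The top-level analysis model and its results object.

:class:`InjurySpecificityAnalysis` bundles the whole pipeline the way a
statsmodels model bundles an estimator: construct it from a mortality table
(plus the unspecified-cause map, standard population and configuration), call
``fit()``, and read the trend table, correlation screen, redistribution audit
and before/after change report off the returned
:class:`InjurySpecificityResults`.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import ConfigurationError, CoverageError
from .io import (
    AgeGroupScheme,
    MortalityTable,
    StandardPopulation,
    UnspecifiedCodeMap,
    _key,
    aggregate_to_groups,
    write_mortality_csv,
)
from .association import (
    DEFAULT_CAUSES_BY_INTENT,
    correlation_report,
    correlation_screen,
)
from .redistribution import (
    DEFAULT_TARGET_GROUPS,
    RedistributionResult,
    change_report,
    redistribute,
)
from .specificity import trend_report
from . import rates

logger = logging.getLogger(__name__)

#: Minimum mean unspecified proportion (percent) for the "auto" target rule.
AUTO_MIN_MEAN_PROPORTION = 5.0


class InjurySpecificityAnalysis:
    """Recording-specificity analysis of an injury mortality table.

    Parameters
    ----------
    table : MortalityTable
        Long-format counts; strata may be finer than the analysis groups.
    code_map : UnspecifiedCodeMap, optional
        Which cause labels are "unspecified" per intent (default: the single
        label ``unspecified`` for every intent).
    standard_population : StandardPopulation, optional
        Weights for direct standardization (default: U.S. 2000 standard
        collapsed to the four analysis groups).
    scheme : AgeGroupScheme, optional
        Stratum-to-group mapping (default: identity on the table's strata).
    causes_by_intent : mapping, optional
        Cause short-lists for correlation and the change report (default: the
        seven unintentional causes and four homicide mechanisms; suicide is
        excluded — its unspecified share is negligible).
    target_groups : sequence of (intent, age_group) or "auto"
        Groups whose excess unspecified deaths are redistributed.  ``"auto"``
        selects groups with a mean unspecified proportion of at least 5%, a
        significant trend, and at least one significant rank correlation.
    alpha : float
        Two-sided significance level for trend and correlation calls.
    year_start, year_end : int, optional
        Comparison years for the change report (default: first/last year).
    """

    def __init__(
        self,
        table: MortalityTable,
        code_map: UnspecifiedCodeMap | None = None,
        standard_population: StandardPopulation | None = None,
        scheme: AgeGroupScheme | None = None,
        causes_by_intent: Mapping[str, tuple[str, ...]] | None = None,
        target_groups: Sequence[tuple[str, str]] | str = DEFAULT_TARGET_GROUPS,
        alpha: float = 0.05,
        year_start: int | None = None,
        year_end: int | None = None,
    ) -> None:
        self.table = table
        self.code_map = code_map or UnspecifiedCodeMap.default()
        self.standard_population = (
            standard_population or StandardPopulation.us2000_four_groups()
        )
        self.scheme = scheme or AgeGroupScheme.identity(table.age_strata)
        self.causes_by_intent = {
            _key(k): tuple(v)
            for k, v in (causes_by_intent or DEFAULT_CAUSES_BY_INTENT).items()
        }
        self.target_groups = target_groups
        if not 0 < alpha < 1:
            raise ConfigurationError(f"alpha must be in (0, 1), got {alpha}")
        self.alpha = alpha
        years = table.years
        self.year_start = years[0] if year_start is None else year_start
        self.year_end = years[-1] if year_end is None else year_end
        if self.year_start >= self.year_end:
            raise ConfigurationError(
                f"year_start ({self.year_start}) must precede year_end ({self.year_end})"
            )
        for y in (self.year_start, self.year_end):
            if y not in years:
                raise CoverageError(f"year {y} not present in the table")

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, age_strata=None, **kwargs):
        return cls(MortalityTable.from_dataframe(df, age_strata=age_strata), **kwargs)

    @classmethod
    def from_csv(
        cls,
        path,
        schema: Mapping[str, str] | None = None,
        age_strata: Iterable[str] | None = None,
        **kwargs,
    ):
        from .io import read_mortality_csv

        return cls(read_mortality_csv(path, schema=schema, age_strata=age_strata), **kwargs)

    # -- fitting ------------------------------------------------------------

    def fit(self) -> "InjurySpecificityResults":
        """Run trends, correlations, redistribution and the change report."""
        grouped = aggregate_to_groups(self.table, self.scheme)
        group_scheme = AgeGroupScheme.identity(grouped.age_strata)

        intents = tuple(
            i for i in ("unintentional", "homicide", "suicide")
            if _key(i) in {_key(x) for x in grouped.intents}
        )
        trends = trend_report(
            grouped, self.code_map, intents, grouped.age_strata, group_scheme, self.alpha
        )

        corr_groups = [
            (intent, group)
            for intent in intents
            if _key(intent) in self.causes_by_intent
            for group in grouped.age_strata
        ]
        correlations = correlation_screen(
            grouped,
            self.code_map,
            self.standard_population,
            corr_groups,
            self.causes_by_intent,
            group_scheme,
        )
        corr_df = correlation_report(correlations)

        targets = self._resolve_targets(trends, corr_df)
        redis = redistribute(grouped, self.code_map, targets, group_scheme)
        changes = change_report(
            grouped,
            redis.adjusted,
            self.standard_population,
            self.year_start,
            self.year_end,
            self.causes_by_intent,
            targets,
            group_scheme,
        )
        return InjurySpecificityResults(
            model=self,
            grouped_table=grouped,
            trends=trends,
            correlations=corr_df,
            redistribution=redis,
            changes=changes,
            target_groups=tuple(targets),
        )

    def _resolve_targets(
        self, trends: pd.DataFrame, correlations: pd.DataFrame
    ) -> list[tuple[str, str]]:
        if self.target_groups != "auto":
            return [tuple(g) for g in self.target_groups]
        targets = []
        for _, row in trends.iterrows():
            if _key(row["intent"]) not in self.causes_by_intent:
                continue
            if row["classification"] == "no_significant_change":
                continue
            if row["mean_proportion"] < AUTO_MIN_MEAN_PROPORTION:
                continue
            sub = correlations[
                (correlations["intent"].map(_key) == _key(row["intent"]))
                & (correlations["age_group"].map(_key) == _key(row["age_group"]))
            ]
            if (sub["p"] < self.alpha).any():
                targets.append((row["intent"], row["age_group"]))
        logger.info("auto-selected redistribution targets: %s", targets)
        return targets


@dataclass(frozen=True)
class InjurySpecificityResults:
    """Fitted pipeline outputs with summary and export helpers."""

    model: InjurySpecificityAnalysis
    grouped_table: MortalityTable
    trends: pd.DataFrame
    correlations: pd.DataFrame
    redistribution: RedistributionResult
    changes: pd.DataFrame
    target_groups: tuple[tuple[str, str], ...]
    extra_reports: Mapping[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def adjusted_table(self) -> MortalityTable:
        return self.redistribution.adjusted

    # -- presentation -------------------------------------------------------

    def summary(self) -> str:
        """Human-readable report: trends, correlations, reference years, changes."""
        lines = []
        lines.append("Injury recording-specificity analysis")
        lines.append("=" * 72)
        y0, y1 = self.model.year_start, self.model.year_end
        lines.append(f"Years {y0}-{y1}; alpha = {self.model.alpha:g}")
        lines.append("")
        lines.append("Linear trend of unspecified proportion (percentage points / year)")
        lines.append("-" * 72)
        t = self.trends.copy()
        for col in ("b", "s_b", "ci_low", "ci_high", "adj_r2"):
            t[col] = t[col].map(lambda v: f"{v:.3f}")
        t["mean_proportion"] = t["mean_proportion"].map(lambda v: f"{v:.1f}%")
        lines.append(
            t[
                ["intent", "age_group", "b", "s_b", "ci_low", "ci_high", "adj_r2",
                 "stars", "classification", "mean_proportion"]
            ].to_string(index=False)
        )
        lines.append("")
        lines.append("Spearman correlation with the unspecified rate series")
        lines.append("-" * 72)
        c = self.correlations.copy()
        c["r_s"] = c["r_s"].map(lambda v: f"{v:.3f}")
        c["p"] = c["p"].map(lambda v: f"{v:.4f}")
        lines.append(c.to_string(index=False))
        lines.append("")
        lines.append("Redistribution reference years")
        lines.append("-" * 72)
        for (intent, group), year in self.redistribution.reference_year.items():
            total_excess = sum(
                v for (i, g, _), v in self.redistribution.excess.items()
                if (i, g) == (intent, group)
            )
            lines.append(
                f"  {intent}, {group}: reference {year}, "
                f"total excess {total_excess:.1f} deaths"
            )
        for flag in self.redistribution.flags:
            lines.append(f"  warning: {flag}")
        lines.append("")
        lines.append(
            f"Percent change in age-adjusted mortality, {y0} -> {y1} "
            "(before vs after adjustment)"
        )
        lines.append("-" * 72)
        ch = self.changes.copy()
        for col in ("rate_start_unadj", "rate_end_unadj", "rate_start_adj", "rate_end_adj"):
            ch[col] = ch[col].map(rates.format_rate)
        for col in ("pct_unadj", "pct_adj"):
            ch[col] = ch[col].map(lambda v: f"{v:+d}%")
        lines.append(ch.to_string(index=False))
        return "\n".join(lines)

    # -- export -------------------------------------------------------------

    def save(self, outdir) -> dict[str, Path]:
        """Write the report artifacts; returns name -> path."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "trend_report": outdir / "trend_report.csv",
            "correlation_report": outdir / "correlation_report.csv",
            "redistribution_audit": outdir / "redistribution_audit.csv",
            "change_report": outdir / "change_report.csv",
            "adjusted_table": outdir / "adjusted_table.csv",
            "run_log": outdir / "run.log",
        }
        self.trends.to_csv(paths["trend_report"], index=False)
        self.correlations.to_csv(paths["correlation_report"], index=False)
        self.redistribution.audit_frame().to_csv(paths["redistribution_audit"], index=False)
        self.changes.to_csv(paths["change_report"], index=False)
        write_mortality_csv(self.adjusted_table, paths["adjusted_table"])
        paths["run_log"].write_text(self.summary() + "\n", encoding="utf-8")
        for name, frame in self.extra_reports.items():
            p = outdir / f"{name}.csv"
            frame.to_csv(p, index=False)
            paths[name] = p
        return paths

    def with_extra_report(self, name: str, frame: pd.DataFrame) -> "InjurySpecificityResults":
        extra = dict(self.extra_reports)
        extra[name] = frame
        return InjurySpecificityResults(
            model=self.model,
            grouped_table=self.grouped_table,
            trends=self.trends,
            correlations=self.correlations,
            redistribution=self.redistribution,
            changes=self.changes,
            target_groups=self.target_groups,
            extra_reports=extra,
        )

    # -- plotting (optional; requires matplotlib) ----------------------------

    def plot_specificity(self, ax=None):
        """Line plot of the unspecified proportion per analyzed group."""
        import matplotlib.pyplot as plt

        from .specificity import unspecified_proportion

        if ax is None:
            _, ax = plt.subplots()
        scheme = AgeGroupScheme.identity(self.grouped_table.age_strata)
        for _, row in self.trends.iterrows():
            series = unspecified_proportion(
                self.grouped_table, self.model.code_map,
                row["intent"], row["age_group"], scheme,
            )
            ax.plot(
                series.by_year.index,
                series.by_year.values,
                marker="o",
                label=f"{row['intent']} {row['age_group']}",
            )
        ax.set_xlabel("year")
        ax.set_ylabel("unspecified proportion (%)")
        ax.legend(fontsize="small")
        return ax
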