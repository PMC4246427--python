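"""Proportionate redistribution of excess unspecified deaths.

The adjustment takes the year with the lowest unspecified proportion within a
group as the reference and assumes recording in every other year could have
been that specific.  Each year's "excess" unspecified deaths — those above the
reference proportion applied to the year's total — are moved onto the
specified causes in proportion to their observed shares in the same cell,
i.e. every specified cause is inflated by the same factor
1 + excess / (specified total).  Totals are conserved; ratios between
specified causes are untouched; after adjustment every year of a targeted
group sits exactly at the reference proportion.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import CoverageError, InjspecError, IntegrityError
from .io import (
    AgeGroupScheme,
    MortalityTable,
    StandardPopulation,
    UnspecifiedCodeMap,
    _key,
)
from . import rates
from .specificity import SpecificitySeries, unspecified_proportion

logger = logging.getLogger(__name__)

#: Groups the published analysis redistributed (significant drift + high share).
DEFAULT_TARGET_GROUPS: tuple[tuple[str, str], ...] = (
    ("unintentional", "65+"),
    ("homicide", "0-24"),
    ("homicide", "45-64"),
    ("homicide", "65+"),
)


@dataclass(frozen=True)
class RedistributionResult:
    """Adjusted table plus the audit trail of the adjustment."""

    adjusted: MortalityTable
    reference_year: Mapping[tuple[str, str], int]
    factors: Mapping[tuple[str, str, int], float]
    excess: Mapping[tuple[str, str, int], float]
    flags: tuple[str, ...] = field(default_factory=tuple)

    def audit_frame(self) -> pd.DataFrame:
        rows = []
        for (intent, group, year), factor in self.factors.items():
            rows.append(
                {
                    "intent": intent,
                    "age_group": group,
                    "year": year,
                    "reference_year": self.reference_year[(intent, group)],
                    "factor": factor,
                    "excess": self.excess[(intent, group, year)],
                }
            )
        return pd.DataFrame(
            rows, columns=["intent", "age_group", "year", "reference_year", "factor", "excess"]
        )


def select_reference_year(series: SpecificitySeries | pd.Series) -> int:
    """Year with the lowest unspecified proportion; ties go to the latest year."""
    s = series.by_year if isinstance(series, SpecificitySeries) else series
    if len(s) == 0:
        raise InjspecError("cannot select a reference year from an empty series")
    best = s.min()
    candidates = [int(y) for y, v in s.items() if v == best]
    return max(candidates)


def compute_excess(total: float, unspecified: float, ref_proportion: float) -> float:
    """Unspecified deaths above the reference proportion's implied level.

    ``ref_proportion`` is in percent.  Years already at or below the reference
    level carry zero excess (the method only lowers specificity-deficit years).
    """
    if not 0 <= ref_proportion <= 100:
        raise IntegrityError(f"reference proportion {ref_proportion} outside [0, 100]")
    if unspecified < 0 or total < 0:
        raise IntegrityError("deaths must be non-negative")
    if unspecified > total * (1 + 1e-12):
        raise IntegrityError(
            f"unspecified deaths ({unspecified}) exceed total deaths ({total})"
        )
    return max(0.0, unspecified - total * ref_proportion / 100.0)


def redistribute(
    table: MortalityTable,
    codemap: UnspecifiedCodeMap,
    groups: Sequence[tuple[str, str]] = DEFAULT_TARGET_GROUPS,
    scheme: AgeGroupScheme | None = None,
) -> RedistributionResult:
    """Redistribute excess unspecified deaths within each targeted (intent, group).

    One reference year and one inflation factor per (intent, age group, year)
    are derived from group-level totals; the factor multiplies the specified
    causes in every stratum of the group, and each stratum's unspecified
    deaths shrink by the complementary group-level ratio.  Non-targeted groups
    pass through untouched.  Cells with positive excess but no specified
    deaths are flagged and left as they are (their excess cannot be
    allocated).
    """
    if scheme is None:
        scheme = AgeGroupScheme.identity(table.age_strata)
    df = table.df.copy()
    df["deaths"] = df["deaths"].astype(float)  # redistributed counts are fractional
    ikey = df["intent"].map(_key)
    gkey = df["age_group"].map(_key)
    unspec_mask_all = codemap.unspecified_mask(df)

    reference_year: dict[tuple[str, str], int] = {}
    factors: dict[tuple[str, str, int], float] = {}
    excess_map: dict[tuple[str, str, int], float] = {}
    flags: list[str] = []

    for intent, group in groups:
        series = unspecified_proportion(table, codemap, intent, group, scheme)
        ref_year = select_reference_year(series)
        ref_prop = float(series.by_year.loc[ref_year])
        reference_year[(intent, group)] = ref_year

        strata_keys = {_key(s) for s in scheme.strata_of(group)}
        in_group = (ikey == _key(intent)) & gkey.isin(strata_keys)
        for year in series.years:
            in_cell = in_group & (df["year"] == year)
            unspec_cell = in_cell & unspec_mask_all
            spec_cell = in_cell & ~unspec_mask_all
            total = float(df.loc[in_cell, "deaths"].sum())
            unspec = float(df.loc[unspec_cell, "deaths"].sum())
            spec_total = total - unspec
            excess = compute_excess(total, unspec, ref_prop)
            if excess > 0 and spec_total <= 0:
                msg = (
                    f"unallocatable excess of {excess:.3f} deaths in cell "
                    f"(intent={intent}, age_group={group}, year={year}): "
                    "no specified deaths to receive them"
                )
                warnings.warn(msg, RuntimeWarning, stacklevel=2)
                logger.warning(msg)
                flags.append(msg)
                factors[(intent, group, year)] = 1.0
                excess_map[(intent, group, year)] = 0.0
                continue
            factor = 1.0 + (excess / spec_total if excess > 0 else 0.0)
            factors[(intent, group, year)] = factor
            excess_map[(intent, group, year)] = excess
            if excess > 0:
                df.loc[spec_cell, "deaths"] = df.loc[spec_cell, "deaths"] * factor
                # shrink every unspecified label by the shared group-level ratio
                df.loc[unspec_cell, "deaths"] = df.loc[unspec_cell, "deaths"] * (
                    (unspec - excess) / unspec
                )
        logger.info(
            "redistribution %s/%s: reference year %d (%.2f%%), total excess %.2f deaths",
            intent,
            group,
            ref_year,
            ref_prop,
            sum(excess_map[(intent, group, y)] for y in series.years),
        )

    adjusted = MortalityTable(df, table.age_strata, provenance=table.provenance)
    return RedistributionResult(
        adjusted=adjusted,
        reference_year=reference_year,
        factors=factors,
        excess=excess_map,
        flags=tuple(flags),
    )


def change_report(
    before: MortalityTable,
    after: MortalityTable,
    std: StandardPopulation,
    year_start: int,
    year_end: int,
    causes_by_intent: Mapping[str, Iterable[str]],
    groups: Sequence[tuple[str, str]] = DEFAULT_TARGET_GROUPS,
    scheme: AgeGroupScheme | None = None,
) -> pd.DataFrame:
    """Start/end age-adjusted rates and integer percent changes, before vs after.

    One row per (intent, age group, cause): the unadjusted columns come from
    ``before``, the adjusted columns from ``after``; percent changes are
    computed on the unrounded rates and then rounded to the nearest integer.
    """
    for tbl, name in ((before, "before"), (after, "after")):
        missing = {year_start, year_end} - set(tbl.years)
        if missing:
            raise CoverageError(f"{name} table missing year(s) {sorted(missing)}")
    known = set(before.df["cause"].map(_key)) | set(after.df["cause"].map(_key))
    rows = []
    for intent, group in groups:
        causes = causes_by_intent.get(_key(intent), causes_by_intent.get(intent, ()))
        for cause in causes:
            if _key(cause) not in known:
                raise CoverageError(f"cause '{cause}' absent from the tables")
            b = rates.cause_rate_series(before, std, intent, cause, group, scheme)
            a = rates.cause_rate_series(after, std, intent, cause, group, scheme)
            row = {
                "intent": intent,
                "age_group": group,
                "cause": cause,
                "rate_start_unadj": b.loc[year_start],
                "rate_end_unadj": b.loc[year_end],
                "pct_unadj": rates.round_percent(
                    rates.percent_change(b.loc[year_start], b.loc[year_end])
                ),
                "rate_start_adj": a.loc[year_start],
                "rate_end_adj": a.loc[year_end],
                "pct_adj": rates.round_percent(
                    rates.percent_change(a.loc[year_start], a.loc[year_end])
                ),
            }
            rows.append(row)
    return pd.DataFrame(
        rows,
        columns=[
            "intent",
            "age_group",
            "cause",
            "rate_start_unadj",
            "rate_end_unadj",
            "pct_unadj",
            "rate_start_adj",
            "rate_end_adj",
            "pct_adj",
        ],
    )
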