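"""Crude and directly age-standardized mortality rates, and percent change.

All rates are per 100,000 persons.  Direct standardization weights stratum
rates by a fixed standard population (normalized internally, so the result is
invariant to rescaling the weights).  The percent-change statistic is
100 x (rate_end - rate_start) / rate_start, computed on unrounded rates; the
reporting layer rounds to the nearest integer percent (half away from zero).
"""
from __future__ import annotations

import math
from typing import Iterable, Mapping

import pandas as pd

from .exceptions import CoverageError, DomainError, UndefinedChangeError
from .io import (
    AgeGroupScheme,
    MortalityTable,
    StandardPopulation,
    UnspecifiedCodeMap,
    _key,
)

PER = 100_000.0


def crude_rate(deaths: float, population: float) -> float:
    """Deaths per 100,000 persons."""
    if population <= 0:
        raise DomainError(f"population must be positive, got {population}")
    if deaths < 0:
        raise DomainError(f"deaths must be non-negative, got {deaths}")
    return PER * deaths / population


def age_adjusted_rate(
    stratum_rates: Mapping[str, float],
    weights: StandardPopulation | Mapping[str, float],
) -> float:
    """Directly standardized rate: sum of w_s * rate_s with w normalized to 1."""
    if not isinstance(weights, StandardPopulation):
        weights = StandardPopulation(weights)
    rates = {_key(s): r for s, r in stratum_rates.items()}
    total = 0.0
    for stratum, w in weights.weights.items():
        if w == 0:
            continue
        if _key(stratum) not in rates:
            raise CoverageError(f"no rate for weighted stratum '{stratum}'")
        total += w * rates[_key(stratum)]
    return total


def percent_change(rate_start: float, rate_end: float) -> float:
    """100 x (end - start) / start, unrounded."""
    if rate_start <= 0:
        raise UndefinedChangeError(
            f"percent change undefined for starting rate {rate_start}"
        )
    return 100.0 * (rate_end - rate_start) / rate_start


def round_percent(p: float) -> int:
    """Nearest integer percent, ties away from zero (so -36.5 -> -37)."""
    return int(math.copysign(math.floor(abs(p) + 0.5), p))


def format_rate(r: float) -> str:
    """Reporting precision: one decimal, two when the rate is below 1."""
    return f"{r:.2f}" if abs(r) < 1 else f"{r:.1f}"


# ---------------------------------------------------------------------------
# Rate series over years


def _series_from_mask(
    table: MortalityTable,
    std: StandardPopulation,
    strata: Iterable[str] | None,
    row_mask: pd.Series,
) -> pd.Series:
    """Yearly age-adjusted rate of the deaths selected by ``row_mask``.

    Strata restrict the population at risk (None = all strata); the standard
    weights are renormalized within those strata.  Years come from the full
    table so cause-years with zero deaths contribute rate 0, not a gap.
    """
    df = table.df
    if strata is None:
        strata = table.age_strata
    strata = [s for s in table.age_strata if _key(s) in {_key(x) for x in strata}]
    weights = std.restricted(strata)
    pops = table.populations().set_index(["year", "age_group"])["population"]
    skeys = {_key(s): s for s in strata}

    sel = df.loc[row_mask & df["age_group"].map(_key).isin(skeys)]
    deaths = sel.groupby([sel["year"], sel["age_group"].map(_key)])["deaths"].sum()

    values = {}
    for year in table.years:
        stratum_rates = {}
        for skey, label in skeys.items():
            try:
                pop = pops.loc[(year, label)]
            except KeyError as exc:
                raise CoverageError(
                    f"no population for (year={year}, age_group={label})"
                ) from exc
            stratum_rates[skey] = crude_rate(float(deaths.get((year, skey), 0.0)), pop)
        values[year] = age_adjusted_rate(stratum_rates, weights)
    return pd.Series(values, name="rate").sort_index()


def _resolve_strata(
    table: MortalityTable,
    age_group: str | None,
    scheme: AgeGroupScheme | None,
) -> Iterable[str] | None:
    if age_group is None:
        return None
    if scheme is None:
        scheme = AgeGroupScheme.identity(table.age_strata)
    return scheme.strata_of(age_group)


def cause_rate_series(
    table: MortalityTable,
    std: StandardPopulation,
    intent: str,
    cause: str,
    age_group: str | None = None,
    scheme: AgeGroupScheme | None = None,
) -> pd.Series:
    """Age-adjusted rate of one (intent, cause) by year, optionally within a group."""
    df = table.df
    mask = (df["intent"].map(_key) == _key(intent)) & (df["cause"].map(_key) == _key(cause))
    return _series_from_mask(table, std, _resolve_strata(table, age_group, scheme), mask)


def all_injury_rate_series(
    table: MortalityTable,
    std: StandardPopulation,
    intent: str | None = None,
    age_group: str | None = None,
    scheme: AgeGroupScheme | None = None,
) -> pd.Series:
    """Age-adjusted all-cause injury rate by year (one intent or all)."""
    df = table.df
    if intent is None:
        mask = pd.Series(True, index=df.index)
    else:
        mask = df["intent"].map(_key) == _key(intent)
    return _series_from_mask(table, std, _resolve_strata(table, age_group, scheme), mask)


def unspecified_rate_series(
    table: MortalityTable,
    std: StandardPopulation,
    codemap: UnspecifiedCodeMap,
    intent: str | None = None,
    age_group: str | None = None,
    scheme: AgeGroupScheme | None = None,
) -> pd.Series:
    """Age-adjusted unspecified-injury rate by year (one intent or all intents)."""
    df = table.df
    mask = codemap.unspecified_mask(df)
    if intent is not None:
        mask &= df["intent"].map(_key) == _key(intent)
    return _series_from_mask(table, std, _resolve_strata(table, age_group, scheme), mask)


def write_rate_series_csv(series_by_label: Mapping[tuple[str, str], pd.Series], path) -> None:
    """Write rate series as a tidy ``group, cause, year, rate`` CSV."""
    rows = []
    for (group, cause), series in series_by_label.items():
        for year, rate in series.items():
            rows.append({"group": group, "cause": cause, "year": year, "rate": rate})
    pd.DataFrame(rows, columns=["group", "cause", "year", "rate"]).to_csv(path, index=False)
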