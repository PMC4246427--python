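"""Recording specificity: the unspecified proportion, its linear trend, and classification.

The proportion of unspecified deaths — unspecified-injury deaths divided by
all-injury deaths within an intent x age-group x year cell, x100 — is the
surrogate indicator of how specifically causes were recorded.  An ordinary
least-squares regression of the proportion (in percent) on calendar year tests
whether specificity changed; a significant negative slope means recording
*improved* (fewer residual codes), a significant positive slope means it
*worsened*.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import (
    DegenerateDesignError,
    InsufficientDataError,
    UndefinedProportionError,
)
from .io import (
    AgeGroupScheme,
    MortalityTable,
    UnspecifiedCodeMap,
    _key,
)

IMPROVED = "improved"
WORSENED = "worsened"
NO_CHANGE = "no_significant_change"


@dataclass(frozen=True)
class SpecificitySeries:
    """Yearly unspecified proportion (percent) for one intent x age group."""

    intent: str
    age_group: str
    by_year: pd.Series  # index: year, values: percent 0..100

    def __post_init__(self) -> None:
        object.__setattr__(self, "by_year", self.by_year.sort_index().astype(float))

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(int(y) for y in self.by_year.index)


@dataclass(frozen=True)
class TrendFit:
    """OLS fit of proportion (percent) on year.

    slope_b is in percentage points per year; the 95% CI uses the Student-t
    quantile with n-2 degrees of freedom.  adj_r2 may be negative for
    near-flat series.
    """

    slope_b: float
    se_b: float
    ci_low: float
    ci_high: float
    adj_r2: float
    p_value: float
    n: int
    intercept: float = float("nan")


def unspecified_proportion(
    table: MortalityTable,
    codemap: UnspecifiedCodeMap,
    intent: str,
    age_group: str,
    scheme: AgeGroupScheme | None = None,
) -> SpecificitySeries:
    """Percent of the cell's all-injury deaths recorded under an unspecified code."""
    if scheme is None:
        scheme = AgeGroupScheme.identity(table.age_strata)
    strata_keys = {_key(s) for s in scheme.strata_of(age_group)}
    df = table.df
    sel = df.loc[
        (df["intent"].map(_key) == _key(intent))
        & df["age_group"].map(_key).isin(strata_keys)
    ]
    unspec_mask = codemap.unspecified_mask(sel)
    total = sel.groupby("year")["deaths"].sum()
    unspec = sel.loc[unspec_mask].groupby("year")["deaths"].sum()
    values = {}
    for year in table.years:
        t = float(total.get(year, 0.0))
        if t <= 0:
            raise UndefinedProportionError(
                f"zero all-injury deaths for (intent={intent}, age_group={age_group}, "
                f"year={year})"
            )
        values[int(year)] = 100.0 * float(unspec.get(year, 0.0)) / t
    return SpecificitySeries(intent, age_group, pd.Series(values))


def t_confidence_interval(
    slope: float, se: float, n: int, alpha: float = 0.05
) -> tuple[float, float]:
    """Two-sided (1-alpha) CI for a regression slope: slope +/- t_{1-a/2, n-2} * se."""
    if n < 3:
        raise InsufficientDataError(f"need at least 3 points, got {n}")
    q = stats.t.ppf(1 - alpha / 2, df=n - 2)
    return slope - q * se, slope + q * se


def fit_linear_trend(series: SpecificitySeries | pd.Series) -> TrendFit:
    """OLS of the proportion (percent) on calendar year.

    The slope is invariant to recoding the year axis (only the intercept
    shifts).  A perfect linear series yields se 0, p 0 and adjusted R^2 of 1.
    """
    y = series.by_year if isinstance(series, SpecificitySeries) else series.sort_index()
    y = y.astype(float)
    if y.isna().any():
        raise InsufficientDataError("series has missing proportions")
    n = len(y)
    if n < 3:
        raise InsufficientDataError(f"need at least 3 years, got {n}")
    x = np.asarray(y.index, dtype=float)
    if np.ptp(x) == 0:
        raise DegenerateDesignError("year has zero variance")
    X = sm.add_constant(x)
    res = sm.OLS(np.asarray(y, dtype=float), X).fit()
    slope = float(res.params[1])
    se = float(res.bse[1])
    if res.ssr <= max(1e-24, 1e-16 * float(res.centered_tss)):
        # numerically perfect fit: the t statistic degenerates
        se = 0.0
        p = 0.0 if slope != 0 else 1.0
        ci_low = ci_high = slope
        adj_r2 = 1.0
    else:
        p = float(res.pvalues[1])
        ci_low, ci_high = t_confidence_interval(slope, se, n)
        adj_r2 = float(res.rsquared_adj)
    return TrendFit(
        slope_b=slope,
        se_b=se,
        ci_low=ci_low,
        ci_high=ci_high,
        adj_r2=adj_r2,
        p_value=p,
        n=n,
        intercept=float(res.params[0]),
    )


def classify_specificity_change(fit: TrendFit, alpha: float = 0.05) -> str:
    """Improved (significant decline), worsened (significant rise), or no change."""
    if fit.p_value < alpha:
        if fit.slope_b < 0:
            return IMPROVED
        if fit.slope_b > 0:
            return WORSENED
    return NO_CHANGE


def significance_stars(p: float) -> str:
    """Report formatting only: * for p<0.05, ** for p<0.01."""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def trend_report(
    table: MortalityTable,
    codemap: UnspecifiedCodeMap,
    intents: tuple[str, ...],
    age_groups: tuple[str, ...],
    scheme: AgeGroupScheme | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-(intent, age group) trend table: b, s_b, 95% CI, adjusted R^2, class."""
    rows = []
    for intent in intents:
        for group in age_groups:
            series = unspecified_proportion(table, codemap, intent, group, scheme)
            fit = fit_linear_trend(series)
            rows.append(
                {
                    "intent": intent,
                    "age_group": group,
                    "b": fit.slope_b,
                    "s_b": fit.se_b,
                    "ci_low": fit.ci_low,
                    "ci_high": fit.ci_high,
                    "adj_r2": fit.adj_r2,
                    "p": fit.p_value,
                    "n": fit.n,
                    "stars": significance_stars(fit.p_value),
                    "classification": classify_specificity_change(fit, alpha),
                    "mean_proportion": float(series.by_year.mean()),
                }
            )
    return pd.DataFrame(rows)
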