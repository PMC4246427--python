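"""Spearman rank correlation between unspecified and cause-specific rate series.

Within a group whose recording specificity drifted, causes that absorbed the
reclassified deaths show rate series that move opposite to the unspecified
series; Spearman's rank correlation measures that co-movement without assuming
linearity.  Correlations are computed on age-adjusted rate series by default.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    AlignmentError,
    ConfigurationError,
    InsufficientDataError,
    UndefinedCorrelationError,
)
from .io import AgeGroupScheme, MortalityTable, StandardPopulation, UnspecifiedCodeMap, _key
from . import rates

#: Major unintentional mechanisms screened against the unspecified series.
UNINTENTIONAL_CAUSES = (
    "falls",
    "MVT",
    "suffocation",
    "fire/burn",
    "natural/environmental",
    "poisoning",
    "drowning",
)

#: Common homicide mechanisms screened against the unspecified series.
HOMICIDE_MECHANISMS = ("firearm", "cut/pierce", "suffocation", "struck by or against")

#: Default screen: suicide is excluded (its unspecified proportion stays <0.7%).
DEFAULT_CAUSES_BY_INTENT: dict[str, tuple[str, ...]] = {
    "unintentional": UNINTENTIONAL_CAUSES,
    "homicide": HOMICIDE_MECHANISMS,
}


@dataclass(frozen=True)
class CorrelationResult:
    intent: str
    age_group: str
    cause: str
    r_s: float
    p_value: float
    n: int


def _spearman_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of midranks (average ranks for ties)."""
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise UndefinedCorrelationError("constant series has no rank correlation")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def spearman(
    x: pd.Series,
    y: pd.Series,
    method: str = "t",
) -> tuple[float, float, int]:
    """Spearman correlation of two year-indexed series.

    Returns ``(r_s, p_value, n)``.  ``method="t"`` uses the two-sided
    t approximation r_s * sqrt((n-2)/(1-r_s^2)) on n-2 df; ``method="exact"``
    enumerates all rank permutations (only sensible for n <= 8).  A perfect
    monotone relationship (r_s = +/-1) gets its analytic limit: p = 2/n! under
    the permutation null, 0.0 under the t approximation.
    """
    if list(x.index) != list(y.index):
        raise AlignmentError("series must share an identical year index")
    n = len(x)
    if n < 4:
        raise InsufficientDataError(f"need at least 4 paired years, got {n}")
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    r = _spearman_r(xv, yv)
    if method == "exact":
        if n > 8:
            raise ConfigurationError("exact permutation p-value limited to n <= 8")
        ry = stats.rankdata(yv, method="average")
        rx = stats.rankdata(xv, method="average")
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            rp = _spearman_r(rx, np.asarray(perm))
            if abs(rp) >= abs(r) - 1e-12:
                count += 1
            total += 1
        return r, count / total, n
    if method != "t":
        raise ConfigurationError(f"unknown p-value method '{method}'")
    if abs(r) >= 1.0 - 1e-15:
        return float(np.sign(r)), 0.0, n
    t = r * np.sqrt((n - 2) / (1 - r * r))
    p = 2 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p), n


def correlation_screen(
    table: MortalityTable,
    codemap: UnspecifiedCodeMap,
    std: StandardPopulation,
    groups: Sequence[tuple[str, str]],
    causes_by_intent: Mapping[str, Iterable[str]] | None = None,
    scheme: AgeGroupScheme | None = None,
) -> list[CorrelationResult]:
    """Correlate each group's unspecified rate series with its cause short-list.

    ``groups`` is a list of (intent, age_group) pairs; the intent's cause list
    comes from ``causes_by_intent`` (default: the unintentional and homicide
    short-lists; suicide has no list and is skipped by default configs).
    Requesting a cause absent from the table is a configuration error.
    """
    if causes_by_intent is None:
        causes_by_intent = DEFAULT_CAUSES_BY_INTENT
    known_causes = set(table.df["cause"].map(_key))
    results: list[CorrelationResult] = []
    for intent, age_group in groups:
        causes = causes_by_intent.get(_key(intent))
        if causes is None:
            causes = causes_by_intent.get(intent, ())
        x = rates.unspecified_rate_series(table, std, codemap, intent, age_group, scheme)
        for cause in causes:
            if _key(cause) not in known_causes:
                raise ConfigurationError(f"cause '{cause}' not present in the table")
            y = rates.cause_rate_series(table, std, intent, cause, age_group, scheme)
            r, p, n = spearman(x, y)
            results.append(CorrelationResult(intent, age_group, cause, r, p, n))
    return results


def correlation_report(results: Sequence[CorrelationResult]) -> pd.DataFrame:
    """Tidy ``intent, age_group, cause, r_s, p, n`` frame for CSV export."""
    return pd.DataFrame(
        [
            {
                "intent": r.intent,
                "age_group": r.age_group,
                "cause": r.cause,
                "r_s": r.r_s,
                "p": r.p_value,
                "n": r.n,
            }
            for r in results
        ],
        columns=["intent", "age_group", "cause", "r_s", "p", "n"],
    )
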