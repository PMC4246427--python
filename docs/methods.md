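# Methods

## The statistic and the adjustment

Injury deaths whose mechanism is not certified end up in residual ICD-10
categories and appear as a pooled "unspecified" cause within each intent
(manner of death). For an intent × age-group cell with all-injury deaths
`N_t` and unspecified deaths `U_t` in year `t`, the package's specificity
indicator is the unspecified proportion

    p_t = 100 · U_t / N_t        (percent).

`p_t` is a *surrogate* for recording quality: it measures how much mechanism
information reached the certificate, not whether the certified mechanisms are
correct. Drift in `p_t` is tested by ordinary least squares of `p_t` on
calendar year. The slope `b` is reported in percentage points per year with
its standard error, a 95% confidence interval using the Student-t quantile on
`n − 2` degrees of freedom, a two-sided p-value, and adjusted
`R² = 1 − (1 − R²)(n − 1)/(n − 2)` (which may be negative for near-flat
series — the implementation allows this). A significant negative slope is
classified `improved`, a significant positive slope `worsened`, otherwise
`no_significant_change`; α defaults to 0.05 and stars (\*, \*\*) mark
p < 0.05 and p < 0.01 in reports.

The adjustment assumes the *best-recorded year is attainable in every year*:
within each targeted group, the year with the lowest `p_t` (ties broken
toward the latest year) is the reference, and every other year's excess
unspecified deaths

    E_t = max(0, U_t − N_t · p_ref / 100)

are reallocated to the specified causes of the same cell in proportion to
their observed shares, i.e. each specified cause count is multiplied by
`f_t = 1 + E_t / (N_t − U_t)`. This proportionate rule embodies the model's
central assumption: masked deaths have the same cause mix as the specified
deaths of their cell. Under that assumption the adjusted counts are unbiased
up to the residual reference-level masking; when masking is cause-biased the
rule is biased too (the generator has a stress mode for exactly this, see
below). Consequences that hold by construction and are enforced by tests:
totals conserved exactly per group-year; ratios between specified causes
unchanged; the recomputed proportion equals `p_ref` in every adjusted year;
`f_t ≥ 1` with equality at the reference year.

Impact is summarized as the percent change
`100 · (r_2010 − r_1999)/r_1999` of directly age-standardized rates before
and after adjustment. Percent changes are always computed on unrounded rates
and only then rounded to the nearest integer (half away from zero); rates are
printed to one decimal, two when below 1 per 100,000.

## Rates and standardization

All rates are deaths per 100,000 persons. Direct standardization weights
stratum rates by a fixed standard population; weights are normalized on load,
so the result is invariant to their scale. The packaged default collapses the
U.S. 2000 standard million onto the four analysis age groups
(0–24: 0.3533, 25–44: 0.2982, 45–64: 0.2221, 65+: 0.1264). For a rate
*within* one age group the weights are renormalized over that group's strata;
when strata coincide with the groups (the default pipeline, which aggregates
strata first) this reduces to the crude group rate. Whether an upstream
source standardized to this or another standard is a configurable assumption
— pass any `StandardPopulation` — not something the package infers.

Redistribution operates on death counts and derives one factor per
(intent, age group, year) from group-level totals; the factor is applied to
the specified causes of every stratum in the group and each stratum's
unspecified count is scaled by the complementary group-level ratio. Because
the factor is constant across strata, scaling counts then standardizing is
identical to scaling the group's age-adjusted cause rates directly;
group-level totals are conserved exactly, per-stratum totals exactly when
strata equal groups. Cells with positive excess but zero specified deaths
cannot absorb their excess: they are flagged, a warning is logged, and the
excess stays unspecified rather than aborting the run.

## Association screen

Spearman's `r_s` is the Pearson correlation of midranks (average ranks on
ties); two-sided p-values use the `t = r_s·√((n−2)/(1−r_s²))` approximation
on `n − 2` df, with the analytic limit `p = 0` at `r_s = ±1`; an exact
permutation p-value is available for `n ≤ 8`. The screen correlates each
group's age-adjusted unspecified rate series with each cause in the intent's
short-list — seven unintentional mechanisms (falls, MVT, suffocation,
fire/burn, natural/environmental, poisoning, drowning) and four homicide
mechanisms (firearm, cut/pierce, suffocation, struck by or against). Suicide
carries no list by default: its unspecified share stays below 0.7% and the
adjustment would be noise. Crude-rate correlations are available by passing a
degenerate standard population.

Targets for redistribution default to the four groups where drift and share
are both large — unintentional 65+, homicide 0–24, 45–64 and 65+. An
`"auto"` mode reproduces the selection logic instead: mean `p_t` ≥ 5%, a
significant trend, and at least one significant correlation. The 5% floor is
this package's operationalization of "high proportion"; it is deliberately
conservative so that near-zero-share groups (e.g. young-adult unintentional
injuries, whose trend is statistically significant but practically
irrelevant) are not adjusted.

## The synthetic-data generator

`generate(config)` draws, per (year, stratum, intent, cause), a true count
`Poisson(population · rate/10⁵)` with `rate = baseline · trend^(year−y₀)`,
then thins it: each death is independently recorded as unspecified with the
cell's masking probability `m_t`. Masking moves labels, never deaths, so
per-intent totals are conserved exactly and `E[p_t] ≈ 100·m_t` regardless of
the cause mix — masking is cause-uniform by default, matching the assumption
the proportionate method itself makes. Per-cause masking multipliers can be
supplied to create a cause-biased stress scenario in which the method is
knowingly biased; this is a diagnostic mode, not a default. Populations are
constant over time; cohort dynamics, secular population growth,
under-reporting and misclassification of *specified* causes are outside the
model, so passing tests demonstrate correctness of the adjustment under its
own assumptions, not that real WISQARS data satisfy them.

The packaged default scenario (`paper_like_scenario`) emulates U.S.
1999–2010 injury mortality: twelve years, the four age groups (populations
1.03×10⁸, 8.2×10⁷, 7.9×10⁷, 3.9×10⁷), five intents, and linear masking ramps
— unintentional 65+ falling 0.189 → 0.109; homicide rising with age
(0–24: 0.05 → 0.08, 45–64: 0.11 → 0.18, 65+: 0.18 → 0.27); suicide constant
at 0.005; legal-intervention and undetermined intents small and flat. True
cause trajectories for the four redistributed groups are back-solved so that
the *observed* (masked) series reproduce published magnitudes — e.g. true
elderly falls start at 36.3/10⁵ growing 4.4%/year, which under the declining
masking shows up as a ~77% observed rise against a ~61% true rise; elderly
MVT declines 4.0%/year, observed as −30% against a true −37%. Cells outside
those groups carry plausible U.S.-scale values and are scenery. These
calibration constants are the scenario's definition and are not tuned per
run.

## Numerical and interface choices

- Counts are canonical; rates are derived. Redistributed counts are
  fractional (no integer rounding — rounding would break conservation).
- Labels (intent, cause, age group) are free strings, trimmed and matched
  case-insensitively; "unspecified" membership is data-driven via the code
  map, never hard-coded.
- A cause absent in some year contributes rate 0 for that year, not a gap;
  a year with zero all-injury deaths makes the proportion an explicit error.
- Missing years are an error, not interpolated; trend fits require ≥ 3
  years, correlations ≥ 4.
- Zero starting rates make percent change an explicit error object rather
  than ±∞.
- OLS is delegated to statsmodels; ranks to scipy. A numerically perfect
  linear fit (zero residual sum of squares relative to the total) is reported
  with se 0, p 0 and adjusted R² 1 instead of NaN.
- End-to-end runs are deterministic given the seed; artifacts are plain CSVs
  that re-parse under the package's own readers.

## Problem sizes

The replicated recovery studies use 200 replicates (test suite) and 100
replicates (acceptance script) at 10⁷ persons per stratum — large enough
that Poisson noise does not mask the adjustment's systematic error reduction,
small enough to iterate quickly. The single-run pipeline uses the full
U.S.-scale populations.

## Known limitations

- The reference-year rule assumes the best-recorded year's specificity was
  attainable throughout; if even the reference year is poorly recorded, the
  adjustment only removes *relative*, not absolute, masking bias.
- The proportionate rule is exactly as good as its cause-uniformity
  assumption; mechanisms that certifiers disproportionately leave unspecified
  (e.g. falls in the elderly) remain under-counted after adjustment.
- Published Spearman coefficients and regression tables from the original
  surveillance extract are not reproducible without that extract; the package
  validates direction and magnitude behaviour on synthetic data instead.
- No confidence intervals on rates or on the adjusted percent changes; the
  adjustment is deterministic given the table.
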