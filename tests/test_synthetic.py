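import math

import numpy as np
import pytest

from injspec import (
    AlignmentError,
    ConfigurationError,
    ScenarioConfig,
    UnspecifiedCodeMap,
    generate,
    paper_like_scenario,
    recovery_error,
    redistribute,
    unspecified_proportion,
)
from injspec.synthetic import constant_masking, linear_masking


def small_scenario(masking_p=0.2, pop=5e6, seed=0):
    """Two-group scenario small enough for exhaustive checks."""
    from dataclasses import replace

    cfg = paper_like_scenario()
    n = cfg.n_years
    masking = {key: constant_masking(masking_p, n) for key in cfg.masking}
    return replace(
        cfg,
        masking=masking,
        population={s: pop for s in cfg.population},
        seed=seed,
    )


class TestGenerate:
    def test_zero_masking_observed_equals_truth(self):
        from dataclasses import replace

        cfg = small_scenario(masking_p=0.0)
        ds = generate(cfg, seed=4)
        obs_spec = ds.observed.df[ds.observed.df["cause"] != "unspecified"]
        merged = obs_spec.merge(
            ds.truth.df,
            on=["year", "age_group", "intent", "cause"],
            suffixes=("_obs", "_truth"),
        )
        assert len(merged) == len(ds.truth.df)
        assert (merged["deaths_obs"] == merged["deaths_truth"]).all()
        unspec = ds.observed.df[ds.observed.df["cause"] == "unspecified"]
        assert (unspec["deaths"] == 0).all()

    def test_same_seed_reproduces_identical_dataset(self):
        cfg = paper_like_scenario()
        a = generate(cfg, seed=9)
        b = generate(cfg, seed=9)
        assert a.truth.equals(b.truth)
        assert a.observed.equals(b.observed)

    def test_different_seed_changes_counts_not_schema(self):
        cfg = paper_like_scenario()
        a = generate(cfg, seed=1)
        b = generate(cfg, seed=2)
        assert not a.observed.equals(b.observed)
        ka = a.observed.df[["year", "age_group", "intent", "cause"]]
        kb = b.observed.df[["year", "age_group", "intent", "cause"]]
        assert ka.equals(kb)

    def test_masking_conserves_per_intent_totals(self):
        ds = generate(paper_like_scenario(), seed=3)
        t = ds.truth.df.groupby(["year", "age_group", "intent"])["deaths"].sum()
        o = ds.observed.df.groupby(["year", "age_group", "intent"])["deaths"].sum()
        assert (t == o.loc[t.index]).all()

    def test_constant_masking_yields_matching_proportion(self):
        m = 0.2
        ds = generate(small_scenario(masking_p=m, pop=2e7), seed=6)
        s = unspecified_proportion(
            ds.observed, UnspecifiedCodeMap.default(), "unintentional", "65+"
        )
        n = (
            ds.truth.filter(intent="unintentional", age_groups=["65+"])
            .groupby("year")["deaths"].sum().min()
        )
        se = 100 * math.sqrt(m * (1 - m) / n)
        assert (s.by_year - 100 * m).abs().max() < 4 * se

    def test_cause_biased_masking_breaks_proportionate_recovery(self):
        # doubling one cause's masking violates the cause-uniformity assumption:
        # the adjustment hands the extra masked falls deaths to every cause by
        # share, so falls stay systematically under-counted after adjustment
        from dataclasses import replace

        cfg = small_scenario(masking_p=0.2, pop=5e7)
        biased = replace(cfg, masking_bias={("unintentional", "falls"): 2.0})
        ds = generate(biased, seed=13)
        result = redistribute(ds.observed, UnspecifiedCodeMap.default(),
                              [("unintentional", "65+")])
        adj = result.adjusted.filter(
            intent="unintentional", age_groups=["65+"]
        ).set_index(["year", "cause"])["deaths"]
        truth = ds.truth.filter(
            intent="unintentional", age_groups=["65+"]
        ).set_index(["year", "cause"])["deaths"]
        years = ds.truth.years
        deficit = [adj.loc[(y, "falls")] - truth.loc[(y, "falls")] for y in years]
        assert max(deficit) < 0  # every year under-counts falls

    def test_masking_bias_above_one_probability_rejected(self):
        from dataclasses import replace

        cfg = small_scenario(masking_p=0.6)
        biased = replace(cfg, masking_bias={("unintentional", "falls"): 2.0})
        with pytest.raises(ConfigurationError):
            generate(biased, seed=1)

    def test_invalid_masking_probability_rejected(self):
        from dataclasses import replace

        cfg = paper_like_scenario()
        bad = dict(cfg.masking)
        bad[("homicide", "65+")] = tuple([1.2] * cfg.n_years)
        with pytest.raises(ConfigurationError):
            replace(cfg, masking=bad)


class TestPaperLikeScenario:
    def test_elderly_unintentional_masking_ramp(self):
        cfg = paper_like_scenario()
        m = cfg.masking_for("unintentional", "65+")
        assert m[0] == pytest.approx(0.189)
        assert m[-1] == pytest.approx(0.109)

    def test_suicide_masking_stays_below_0_7_percent(self):
        cfg = paper_like_scenario()
        for group in ("0-24", "25-44", "45-64", "65+"):
            assert (cfg.masking_for("suicide", group) <= 0.007).all()

    def test_homicide_masking_rises_with_age_within_reported_ranges(self):
        cfg = paper_like_scenario()
        m45 = cfg.masking_for("homicide", "45-64")
        m65 = cfg.masking_for("homicide", "65+")
        assert (m45 >= 0.11).all() and (m45 <= 0.18).all()
        assert (m65 >= 0.18).all() and (m65 <= 0.27).all()
        assert (np.diff(m45) > 0).all() and (np.diff(m65) > 0).all()

    def test_masking_slope_helper_matches_linear_ramp(self):
        cfg = paper_like_scenario()
        assert cfg.masking_slope("unintentional", "65+") == pytest.approx(
            100 * (0.109 - 0.189) / 11
        )

    def test_true_fall_and_poisoning_rates_rise_while_mvt_falls(self):
        cfg = paper_like_scenario()
        y0, y1 = cfg.years
        assert cfg.true_rate("65+", "unintentional", "falls", y1) > cfg.true_rate(
            "65+", "unintentional", "falls", y0
        )
        assert cfg.true_rate("65+", "unintentional", "poisoning", y1) > cfg.true_rate(
            "65+", "unintentional", "poisoning", y0
        )
        assert cfg.true_rate("65+", "unintentional", "MVT", y1) < cfg.true_rate(
            "65+", "unintentional", "MVT", y0
        )


class TestScenarioFile:
    def test_yaml_overrides(self, tmp_path):
        path = tmp_path / "scenario.yaml"
        path.write_text(
            "seed: 5\n"
            "population:\n  '65+': 1000000\n"
            "masking:\n  homicide:\n    '65+': [0.1, 0.2]\n"
        )
        cfg = ScenarioConfig.from_file(path)
        assert cfg.seed == 5
        assert cfg.population["65+"] == 1e6
        m = cfg.masking_for("homicide", "65+")
        assert m[0] == pytest.approx(0.1) and m[-1] == pytest.approx(0.2)


class TestRecoveryError:
    def test_adjusted_equal_truth_gives_zero_error(self):
        ds = generate(small_scenario(masking_p=0.1), seed=5)
        report = recovery_error(ds, ds.truth)
        assert (report["mae_adjusted"] == 0).all()
        assert (report["mae_observed"] > 0).any()

    def test_zero_masking_pipeline_is_error_free(self):
        ds = generate(small_scenario(masking_p=0.0), seed=5)
        result = redistribute(ds.observed, UnspecifiedCodeMap.default())
        report = recovery_error(ds, result.adjusted)
        assert (report["mae_adjusted"] == 0).all()
        assert (report["mae_observed"] == 0).all()

    def test_misaligned_tables_raise(self):
        from dataclasses import replace

        ds = generate(small_scenario(), seed=5)
        cfg2 = replace(ds.config, years=(1999, 2005),
                       masking={k: v[:7] for k, v in ds.config.masking.items()})
        ds2 = generate(cfg2, seed=5)
        with pytest.raises(AlignmentError):
            recovery_error(ds, ds2.truth)

    def test_adjustment_beats_raw_observation_on_targeted_group(self):
        ds = generate(paper_like_scenario(), seed=12)
        result = redistribute(ds.observed, UnspecifiedCodeMap.default())
        report = recovery_error(ds, result.adjusted)
        sub = report[(report["intent"] == "unintentional") & (report["age_group"] == "65+")]
        assert sub["mae_adjusted"].mean() < sub["mae_observed"].mean()
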