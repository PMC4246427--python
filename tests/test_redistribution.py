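import numpy as np
import pandas as pd
import pytest

from injspec import (
    CoverageError,
    IntegrityError,
    StandardPopulation,
    UnspecifiedCodeMap,
    change_report,
    compute_excess,
    redistribute,
    select_reference_year,
    unspecified_proportion,
)
from conftest import make_table

GROUP = [("unintentional", "65+")]


def allocation_oracle(specified: dict, unspecified: float, ref_proportion: float):
    """Per-cause expected allocation, coded independently of the implementation.

    Each of the excess deaths lands on cause c with probability
    d_c / sum(d); the expected adjusted count is d_c + excess * d_c / sum(d).
    """
    total = sum(specified.values()) + unspecified
    excess = max(0.0, unspecified - total * ref_proportion / 100.0)
    share = sum(specified.values())
    return {c: d + excess * d / share for c, d in specified.items()}, unspecified - excess


class TestReferenceYear:
    def test_monotone_declining_series_selects_last_year(self):
        s = pd.Series(np.linspace(18.9, 10.9, 12), index=range(1999, 2011))
        assert select_reference_year(s) == 2010

    def test_single_year_series(self):
        assert select_reference_year(pd.Series({2005: 3.2})) == 2005

    def test_tie_broken_toward_latest_year(self):
        s = pd.Series({1999: 5.0, 2000: 4.0, 2001: 4.0, 2002: 6.0})
        assert select_reference_year(s) == 2001


class TestComputeExcess:
    def test_arithmetic(self):
        assert compute_excess(100, 20, 10.0) == pytest.approx(10.0)

    def test_zero_at_reference_level(self):
        assert compute_excess(100, 10, 10.0) == 0.0

    def test_published_65plus_cell(self):
        # all-injury total reconstructed from the printed rate and proportion
        total = 17.7 / 0.189
        assert compute_excess(total, 17.7, 10.9) == pytest.approx(7.492, abs=1e-3)

    def test_below_reference_is_floored_at_zero(self):
        assert compute_excess(100, 5, 10.0) == 0.0

    def test_unspecified_exceeding_total_is_integrity_error(self):
        with pytest.raises(IntegrityError):
            compute_excess(10, 20, 10.0)


class TestRedistribute:
    def test_toy_cell_factor_and_counts(self, toy_table, codemap):
        # 1999: specified {A:60, B:20}, unspecified 20, reference (2000) at 10%
        result = redistribute(toy_table, codemap, GROUP)
        assert result.reference_year[("unintentional", "65+")] == 2000
        assert result.factors[("unintentional", "65+", 1999)] == pytest.approx(1.125)
        cell = result.adjusted.filter(intent="unintentional", year=1999).set_index("cause")
        assert cell.loc["A", "deaths"] == pytest.approx(67.5)
        assert cell.loc["B", "deaths"] == pytest.approx(22.5)
        assert cell.loc["unspecified", "deaths"] == pytest.approx(10.0)

    def test_reference_year_cell_unchanged(self, toy_table, codemap):
        result = redistribute(toy_table, codemap, GROUP)
        before = toy_table.filter(year=2000).set_index("cause")["deaths"]
        after = result.adjusted.filter(year=2000).set_index("cause")["deaths"]
        assert (before == after).all()
        assert result.factors[("unintentional", "65+", 2000)] == 1.0
        assert result.excess[("unintentional", "65+", 2000)] == 0.0

    def test_non_targeted_groups_pass_through(self, codemap):
        t = make_table(
            [
                (1999, "65+", "unintentional", "A", 80, 1000),
                (1999, "65+", "unintentional", "unspecified", 20, 1000),
                (2000, "65+", "unintentional", "A", 95, 1000),
                (2000, "65+", "unintentional", "unspecified", 5, 1000),
                (1999, "65+", "homicide", "firearm", 50, 1000),
                (1999, "65+", "homicide", "unspecified", 50, 1000),
                (2000, "65+", "homicide", "firearm", 90, 1000),
                (2000, "65+", "homicide", "unspecified", 10, 1000),
            ]
        )
        result = redistribute(t, codemap, GROUP)
        hom_before = t.filter(intent="homicide")["deaths"].tolist()
        hom_after = result.adjusted.filter(intent="homicide")["deaths"].tolist()
        assert hom_before == hom_after

    def test_matches_expected_allocation_oracle(self, codemap):
        rng = np.random.default_rng(17)
        for _ in range(10):
            spec = {c: int(rng.integers(1, 50)) for c in "abcde"[: rng.integers(2, 6)]}
            unspec_ref = int(rng.integers(0, 5))
            unspec = int(rng.integers(unspec_ref + 1, unspec_ref + 40))
            rows = [(1999, "65+", "homicide", c, d, 1000) for c, d in spec.items()]
            rows.append((1999, "65+", "homicide", "unspecified", unspec, 1000))
            rows += [(2000, "65+", "homicide", c, d, 1000) for c, d in spec.items()]
            rows.append((2000, "65+", "homicide", "unspecified", unspec_ref, 1000))
            t = make_table(rows)
            result = redistribute(t, codemap, [("homicide", "65+")])
            ref_prop = 100 * unspec_ref / (sum(spec.values()) + unspec_ref)
            expected, expected_unspec = allocation_oracle(spec, unspec, ref_prop)
            cell = result.adjusted.filter(intent="homicide", year=1999).set_index("cause")
            for c, d in expected.items():
                assert cell.loc[c, "deaths"] == pytest.approx(d, rel=1e-9)
            assert cell.loc["unspecified", "deaths"] == pytest.approx(expected_unspec, abs=1e-9)

    def test_conservation_share_preservation_and_post_proportion(self, codemap):
        rng = np.random.default_rng(23)
        years = range(1999, 2005)
        rows = []
        for year in years:
            for cause in ("a", "b", "c"):
                rows.append((year, "65+", "unintentional", cause, rng.integers(5, 200), 10_000))
            rows.append((year, "65+", "unintentional", "unspecified", rng.integers(0, 80), 10_000))
        t = make_table(rows)
        result = redistribute(t, codemap, GROUP)
        ref_prop = unspecified_proportion(
            t, codemap, "unintentional", "65+"
        ).by_year.min()
        post = unspecified_proportion(result.adjusted, codemap, "unintentional", "65+")
        for year in years:
            before = t.filter(year=year)["deaths"].sum()
            after = result.adjusted.filter(year=year)["deaths"].sum()
            assert after == pytest.approx(before, rel=1e-12)  # conservation
            assert post.by_year.loc[year] == pytest.approx(ref_prop, abs=1e-9)
            b = t.filter(year=year).set_index("cause")["deaths"]
            a = result.adjusted.filter(year=year).set_index("cause")["deaths"]
            assert a["a"] * b["b"] == pytest.approx(a["b"] * b["a"], rel=1e-9)  # shares

    def test_factor_monotone_in_excess(self, codemap):
        def factor_for(unspec):
            rows = [
                (1999, "65+", "homicide", "x", 100, 1000),
                (1999, "65+", "homicide", "unspecified", unspec, 1000),
                (2000, "65+", "homicide", "x", 100, 1000),
                (2000, "65+", "homicide", "unspecified", 1, 1000),
            ]
            t = make_table(rows)
            r = redistribute(t, codemap, [("homicide", "65+")])
            return r.factors[("homicide", "65+", 1999)]

        factors = [factor_for(u) for u in (5, 10, 20, 40)]
        assert factors == sorted(factors)
        assert all(f >= 1 for f in factors)

    def test_unallocatable_excess_flags_and_retains(self, codemap):
        t = make_table(
            [
                (1999, "65+", "homicide", "unspecified", 30, 1000),
                (1999, "65+", "homicide", "firearm", 0, 1000),
                (2000, "65+", "homicide", "firearm", 90, 1000),
                (2000, "65+", "homicide", "unspecified", 10, 1000),
            ]
        )
        with pytest.warns(RuntimeWarning, match="unallocatable"):
            result = redistribute(t, codemap, [("homicide", "65+")])
        assert len(result.flags) == 1
        cell = result.adjusted.filter(year=1999).set_index("cause")
        assert cell.loc["unspecified", "deaths"] == 30  # excess retained


class TestChangeReport:
    def test_identical_tables_give_identical_columns(self, toy_table, codemap):
        std = StandardPopulation({"65+": 1.0})
        report = change_report(
            toy_table, toy_table, std, 1999, 2000,
            {"unintentional": ("A", "B")}, GROUP,
        )
        assert (report["rate_start_unadj"] == report["rate_start_adj"]).all()
        assert (report["pct_unadj"] == report["pct_adj"]).all()

    def test_adjusted_columns_reflect_redistribution(self, toy_table, codemap):
        std = StandardPopulation({"65+": 1.0})
        result = redistribute(toy_table, codemap, GROUP)
        report = change_report(
            toy_table, result.adjusted, std, 1999, 2000,
            {"unintentional": ("A",)}, GROUP,
        ).iloc[0]
        assert report["rate_start_unadj"] == pytest.approx(60.0)
        assert report["rate_start_adj"] == pytest.approx(67.5)
        assert report["pct_unadj"] == 17  # 60 -> 70
        assert report["pct_adj"] == 4  # 67.5 -> 70

    def test_missing_year_is_a_coverage_error(self, toy_table, codemap):
        std = StandardPopulation({"65+": 1.0})
        with pytest.raises(CoverageError):
            change_report(
                toy_table, toy_table, std, 1999, 2001,
                {"unintentional": ("A",)}, GROUP,
            )

    def test_missing_cause_is_a_coverage_error(self, toy_table, codemap):
        std = StandardPopulation({"65+": 1.0})
        with pytest.raises(CoverageError):
            change_report(
                toy_table, toy_table, std, 1999, 2000,
                {"unintentional": ("nonexistent",)}, GROUP,
            )
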