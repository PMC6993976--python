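"""Tests for regression-line comparison, two-way ANOVA, and Sidak post hoc."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from bbbpk import (
    compare_regression_lines,
    sidak_adjust,
    sidak_posthoc,
    two_way_anova,
)


def brute_force_line_f(groups):
    """Extra-sum-of-squares oracle assembled from explicit residual sums."""
    def rss(pairs):
        x = np.array([p[0] for p in pairs], float)
        y = np.array([p[1] for p in pairs], float)
        b, a = np.polyfit(x, y, 1)
        return float(np.sum((y - (a + b * x)) ** 2))

    k = len(groups)
    n = sum(len(g) for g in groups)
    rss_sep = sum(rss(g) for g in groups)
    # common slope, separate intercepts, by brute-force 1-D minimisation
    xs = [np.array([p[0] for p in g], float) for g in groups]
    ys = [np.array([p[1] for p in g], float) for g in groups]
    num = sum(np.sum((x - x.mean()) * (y - y.mean())) for x, y in zip(xs, ys))
    den = sum(np.sum((x - x.mean()) ** 2) for x in xs)
    b = num / den
    rss_cs = sum(
        np.sum((y - y.mean() - b * (x - x.mean())) ** 2) for x, y in zip(xs, ys)
    )
    f = ((rss_cs - rss_sep) / (k - 1)) / (rss_sep / (n - 2 * k))
    return float(f), (k - 1, n - 2 * k)


class TestCompareRegressionLines:
    def test_identical_groups_give_f_zero_p_one(self):
        pts = ([1, 2, 3, 4, 5], [2.0, 3.9, 6.1, 8.0, 10.2])
        res = compare_regression_lines({"a": pts, "b": pts})
        slope = res[0]
        assert slope.test == "slope_homogeneity"
        assert slope.F == pytest.approx(0.0, abs=1e-12)
        assert slope.p == pytest.approx(1.0, abs=1e-6)

    def test_matches_brute_force_extra_sum_of_squares(self):
        g1 = [(0, 1), (1, 3), (2, 4), (3, 7), (4, 8)]
        g2 = [(0, 2), (1, 2), (2, 5), (3, 5), (4, 9)]
        f_oracle, df_oracle = brute_force_line_f([g1, g2])
        res = compare_regression_lines(
            {
                "g1": ([p[0] for p in g1], [p[1] for p in g1]),
                "g2": ([p[0] for p in g2], [p[1] for p in g2]),
            }
        )[0]
        assert res.F == pytest.approx(f_oracle, rel=1e-9)
        assert res.df == df_oracle

    def test_two_groups_equals_two_slope_t_test_squared(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            x1, x2 = rng.uniform(0, 10, 8), rng.uniform(0, 10, 9)
            y1 = 1 + 0.5 * x1 + rng.normal(0, 1, 8)
            y2 = 2 + 0.8 * x2 + rng.normal(0, 1, 9)
            res = compare_regression_lines({"a": (x1, y1), "b": (x2, y2)})[0]
            # textbook two-slope t test with pooled residual variance
            f1, f2 = sps.linregress(x1, y1), sps.linregress(x2, y2)
            rss = (
                np.sum((y1 - f1.intercept - f1.slope * x1) ** 2)
                + np.sum((y2 - f2.intercept - f2.slope * x2) ** 2)
            )
            s2 = rss / (len(x1) + len(x2) - 4)
            se = math.sqrt(
                s2 / np.sum((x1 - x1.mean()) ** 2)
                + s2 / np.sum((x2 - x2.mean()) ** 2)
            )
            t = (f1.slope - f2.slope) / se
            assert res.F == pytest.approx(t**2, rel=1e-9)

    def test_four_group_comparison_supported(self):
        rng = np.random.default_rng(9)
        groups = {}
        for i in range(4):
            x = rng.uniform(0, 10, 10)
            groups[f"g{i}"] = (x, 1 + 0.5 * x + rng.normal(0, 0.5, 10))
        slope, elev = compare_regression_lines(groups)
        assert slope.df[0] == 3
        assert elev.df[0] == 3
        assert 0 <= slope.p <= 1 and 0 <= elev.p <= 1

    def test_elevation_premise_flag(self):
        x = np.arange(6, dtype=float)
        res = compare_regression_lines(
            {"flat": (x, 0 * x + 1.0), "steep": (x, 10 * x)}
        )
        slope, elev = res
        assert slope.p < 0.05
        assert not elev.premise_ok

    def test_degenerate_group_named_in_error(self):
        with pytest.raises(ValueError, match="bad"):
            compare_regression_lines(
                {"ok": ([1, 2, 3], [1, 2, 3]), "bad": ([2, 2, 2], [1, 2, 3])}
            )

    def test_type_one_error_rate_under_common_line(self):
        # two groups simulated from one line: rejection rate ~ alpha
        rng = np.random.default_rng(2024)
        reps, rejections = 2000, 0
        x = np.linspace(0, 10, 8)
        for _ in range(reps):
            y1 = 1 + 0.5 * x + rng.normal(0, 1, 8)
            y2 = 1 + 0.5 * x + rng.normal(0, 1, 8)
            res = compare_regression_lines({"a": (x, y1), "b": (x, y2)})[0]
            rejections += res.p < 0.05
        assert 0.035 <= rejections / reps <= 0.065


def brute_force_anova(df):
    """Direct balanced 2x2 sums-of-squares decomposition."""
    y = df["y"].to_numpy(float)
    grand = y.mean()
    ss_total = np.sum((y - grand) ** 2)
    a_levels, b_levels = sorted(df["A"].unique()), sorted(df["B"].unique())
    ss_a = sum(
        len(df[df.A == a]) * (df[df.A == a].y.mean() - grand) ** 2 for a in a_levels
    )
    ss_b = sum(
        len(df[df.B == b]) * (df[df.B == b].y.mean() - grand) ** 2 for b in b_levels
    )
    ss_cells = 0.0
    ss_resid = 0.0
    for a, b in itertools.product(a_levels, b_levels):
        cell = df[(df.A == a) & (df.B == b)].y
        ss_cells += len(cell) * (cell.mean() - grand) ** 2
        ss_resid += np.sum((cell - cell.mean()) ** 2)
    ss_ab = ss_cells - ss_a - ss_b
    return ss_a, ss_b, ss_ab, ss_resid, ss_total


class TestTwoWayAnova:
    def fixed_example(self):
        rows = []
        for a, b, vals in [
            (0, 0, (1, 3)), (0, 1, (2, 4)), (1, 0, (5, 7)), (1, 1, (6, 8)),
        ]:
            rows += [{"A": a, "B": b, "y": v} for v in vals]
        return pd.DataFrame(rows)

    def test_fixed_worked_example(self):
        res = two_way_anova(self.fixed_example(), "y", "A", "B")
        t = res.table
        assert t.loc["A", "SS"] == pytest.approx(32.0, rel=1e-12)
        assert t.loc["B", "SS"] == pytest.approx(2.0, rel=1e-12)
        assert t.loc["A:B", "SS"] == pytest.approx(0.0, abs=1e-9)
        assert t.loc["residual", "SS"] == pytest.approx(8.0, rel=1e-12)
        assert t.loc["A", "F"] == pytest.approx(16.0, rel=1e-9)
        assert t.loc["B", "F"] == pytest.approx(1.0, rel=1e-9)
        assert t.loc["A:B", "F"] == pytest.approx(0.0, abs=1e-9)

    def test_matches_brute_force_on_random_balanced_designs(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            reps = rng.integers(2, 5)
            rows = [
                {"A": a, "B": b, "y": rng.normal()}
                for a in (0, 1) for b in (0, 1) for _ in range(reps)
            ]
            df = pd.DataFrame(rows)
            res = two_way_anova(df, "y", "A", "B").table
            ss_a, ss_b, ss_ab, ss_resid, ss_total = brute_force_anova(df)
            assert res.loc["A", "SS"] == pytest.approx(ss_a, rel=1e-9, abs=1e-12)
            assert res.loc["B", "SS"] == pytest.approx(ss_b, rel=1e-9, abs=1e-12)
            assert res.loc["A:B", "SS"] == pytest.approx(ss_ab, rel=1e-9, abs=1e-12)
            assert res.loc["residual", "SS"] == pytest.approx(ss_resid, rel=1e-9)
            # decomposition conserves total SS
            assert res["SS"].sum() == pytest.approx(ss_total, rel=1e-9)

    def test_order_invariance(self):
        df = self.fixed_example()
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        t1 = two_way_anova(df, "y", "A", "B").table
        t2 = two_way_anova(shuffled, "y", "A", "B").table
        pd.testing.assert_frame_equal(t1, t2)

    def test_constant_response_degenerate(self):
        df = self.fixed_example()
        df["y"] = 5.0
        res = two_way_anova(df, "y", "A", "B")
        assert res.degenerate
        assert math.isnan(res.table.loc["A", "F"])

    def test_empty_cell_rejected(self):
        df = self.fixed_example()
        df = df[~((df.A == 1) & (df.B == 1))]
        with pytest.raises(ValueError, match="empty cell"):
            two_way_anova(df, "y", "A", "B")

    def test_unbalanced_rejected(self):
        df = pd.concat(
            [self.fixed_example(), pd.DataFrame([{"A": 0, "B": 0, "y": 9.0}])],
            ignore_index=True,
        )
        with pytest.raises(ValueError, match="unbalanced"):
            two_way_anova(df, "y", "A", "B")


class TestSidak:
    def test_single_comparison_unchanged(self):
        assert sidak_adjust(0.04, 1) == pytest.approx(0.04)

    def test_two_comparisons_closed_form(self):
        assert sidak_adjust(0.05, 2) == pytest.approx(1 - 0.95**2)

    @given(
        st.floats(min_value=0.0, max_value=1.0),
        st.floats(min_value=0.0, max_value=1.0),
        st.integers(min_value=1, max_value=20),
        st.integers(min_value=1, max_value=20),
    )
    @settings(max_examples=200, deadline=None)
    def test_adjustment_monotone_in_p_and_m(self, p1, p2, m1, m2):
        lo_p, hi_p = sorted((p1, p2))
        lo_m, hi_m = sorted((m1, m2))
        assert sidak_adjust(lo_p, m1) <= sidak_adjust(hi_p, m1)
        assert sidak_adjust(p1, lo_m) <= sidak_adjust(p1, hi_m)

    def test_posthoc_uses_residual_ms(self):
        rows = []
        rng = np.random.default_rng(3)
        for a in (0, 1):
            for b in (0, 1):
                rows += [{"A": a, "B": b, "y": float(rng.normal(a * 2))}
                         for _ in range(5)]
        df = pd.DataFrame(rows)
        out = sidak_posthoc(
            df, "y", "A", "B", comparisons=[((0, 0), (1, 0)), ((0, 1), (1, 1))]
        )
        assert len(out) == 2
        assert (out.p_sidak >= out.p - 1e-15).all()
        anova = two_way_anova(df, "y", "A", "B")
        assert (out.df == anova.residual_df).all()

    def test_zero_residual_ms_rejected(self):
        rows = [
            {"A": a, "B": b, "y": float(a + b)}
            for a in (0, 1) for b in (0, 1) for _ in range(2)
        ]
        with pytest.raises(ValueError, match="residual"):
            sidak_posthoc(pd.DataFrame(rows), "y", "A", "B",
                          comparisons=[((0, 0), (1, 0))])

    def test_familywise_error_controlled_under_null(self):
        # 2x2 balanced null: probability of any Sidak-adjusted rejection
        # stays at or below the nominal level (plus Monte-Carlo slack)
        rng = np.random.default_rng(77)
        reps, fw = 800, 0
        comparisons = [((0, 0), (0, 1)), ((1, 0), (1, 1))]
        for _ in range(reps):
            rows = [
                {"A": a, "B": b, "y": float(rng.normal())}
                for a in (0, 1) for b in (0, 1) for _ in range(5)
            ]
            out = sidak_posthoc(pd.DataFrame(rows), "y", "A", "B", comparisons)
            fw += (out.p_sidak < 0.05).any()
        assert fw / reps <= 0.05 + 2.5 * math.sqrt(0.05 * 0.95 / reps)
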