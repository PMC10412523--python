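"""Inferential layer: ANOVAs, paired t, post-hocs, calibration."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

import cbdrive as cb


class TestAnovaOneway:
    def test_identical_groups_f_zero(self):
        res = cb.anova_oneway([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert res.statistic == pytest.approx(0.0)
        assert res.effect_size == pytest.approx(0.0)

    def test_hand_computed_sums_of_squares(self):
        res = cb.anova_oneway([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        assert res.statistic == pytest.approx(13.5)
        assert (res.df1, res.df2) == (1, 4)
        assert res.effect_size == pytest.approx(13.5 / 17.5)

    def test_matches_scipy(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(m, 1, size=12) for m in (0, 0.5, 1.2)]
        res = cb.anova_oneway(groups)
        f, p = sps.f_oneway(*groups)
        assert res.statistic == pytest.approx(f)
        assert res.p == pytest.approx(p)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            cb.anova_oneway([[1.0], [2.0, 3.0]])


class TestAnovaFactorial:
    def test_additive_means_zero_interaction(self):
        a_eff = {"a0": 0.0, "a1": 2.0}
        b_eff = {"b0": 0.0, "b1": 5.0}
        vals, fa, fb = [], [], []
        for ai in a_eff:
            for bj in b_eff:
                for v in (-1.0, 0.0, 1.0):
                    vals.append(a_eff[ai] + b_eff[bj] + v)
                    fa.append(ai)
                    fb.append(bj)
        res = cb.anova_factorial(vals, fa, fb)
        assert res["interaction"].statistic == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_2x2(self):
        # cells (n=2): a0b0={1,3}, a0b1={5,7}, a1b0={2,4}, a1b1={10,12}
        vals = [1, 3, 5, 7, 2, 4, 10, 12]
        fa = ["a0"] * 4 + ["a1"] * 4
        fb = ["b0", "b0", "b1", "b1"] * 2
        res = cb.anova_factorial(vals, fa, fb)
        # hand SS: grand=5.5; A means 4, 7 -> SS_A=2*2*(1.5^2+1.5^2)=18;
        # B means 2.5, 8.5 -> SS_B=4*(3^2+3^2)=72; cell means 2,6,3,11 ->
        # interaction residuals +-1 -> SS_AB=2*4=8; within-cell SS_err=8, df=4
        assert res["factor_a"].statistic == pytest.approx(18 / 2)
        assert res["factor_b"].statistic == pytest.approx(72 / 2)
        assert res["interaction"].statistic == pytest.approx(8 / 2)
        assert res["factor_a"].effect_size == pytest.approx(18 / 26)

    def test_matches_statsmodels_on_balanced_design(self):
        import pandas as pd
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        rng = np.random.default_rng(11)
        rows = []
        for ai in ("a0", "a1", "a2"):
            for bj in ("b0", "b1", "b2"):
                for v in rng.normal(hash(ai) % 3 + (hash(bj) % 5) * 0.5, 1.0, size=6):
                    rows.append({"y": v, "A": ai, "B": bj})
        df = pd.DataFrame(rows)
        mine = cb.anova_factorial(df["y"], df["A"], df["B"])
        tab = sm.stats.anova_lm(ols("y ~ C(A) * C(B)", data=df).fit(), typ=2)
        assert mine["factor_a"].statistic == pytest.approx(tab.loc["C(A)", "F"])
        assert mine["factor_b"].statistic == pytest.approx(tab.loc["C(B)", "F"])
        assert mine["interaction"].statistic == pytest.approx(tab.loc["C(A):C(B)", "F"])
        assert mine["factor_a"].p == pytest.approx(tab.loc["C(A)", "PR(>F)"])

    def test_label_permutation_leaves_error_ss_invariant(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=24)
        fa = np.repeat(["x", "y"], 12)
        fb = np.tile(np.repeat(["u", "v"], 6), 2)
        res1 = cb.anova_factorial(vals, fa, fb)
        res2 = cb.anova_factorial(vals, fb, fa)  # swap factor roles
        assert res1["interaction"].statistic == pytest.approx(res2["interaction"].statistic)
        assert res1["factor_a"].statistic == pytest.approx(res2["factor_b"].statistic)

    def test_empty_cell_rejected(self):
        with pytest.raises(ValueError):
            cb.anova_factorial([1.0, 2.0, 3.0, 4.0], ["a", "a", "b", "b"], ["u", "v", "u", "u"])


class TestPairedT:
    def test_equal_samples(self):
        res = cb.paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.effect_size == 0.0

    def test_symmetric_differences_cancel(self):
        res = cb.paired_t([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.effect_size == pytest.approx(0.0)

    def test_constant_nonzero_difference_rejected(self):
        with pytest.raises(ValueError):
            cb.paired_t([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])

    def test_matches_scipy_and_cohens_d(self):
        rng = np.random.default_rng(8)
        a = rng.normal(1.0, 1.0, 30)
        b = rng.normal(0.5, 1.0, 30)
        res = cb.paired_t(a, b)
        t, p = sps.ttest_rel(a, b)
        assert res.statistic == pytest.approx(t)
        assert res.p == pytest.approx(p)
        d = a - b
        assert res.effect_size == pytest.approx(d.mean() / d.std(ddof=1))


class TestPosthoc:
    def test_identical_groups_adjusted_p_one(self):
        g = [1.0, 2.0, 3.0, 4.0]
        for method in ("tukey_hsd", "bonferroni"):
            for rec in cb.posthoc([g, g, g], method):
                assert rec["p_adj"] == pytest.approx(1.0, abs=1e-9)

    def test_bonferroni_definition(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(m, 1, 10) for m in (0, 0.3, 2.0)]
        recs = cb.posthoc(groups, "bonferroni")
        for rec in recs:
            i, j = rec["i"], rec["j"]
            _, raw = sps.ttest_ind(groups[i], groups[j])
            assert rec["p_adj"] == pytest.approx(min(1.0, raw * 3))
            assert rec["p_adj"] >= raw

    def test_tukey_matches_studentised_range_brute_force(self):
        """Independent q-statistic computation on a small 3-group toy."""
        groups = [
            np.array([1.0, 2.0, 1.5, 2.5, 2.0]),
            np.array([4.0, 5.0, 4.5, 5.5, 5.0]),
            np.array([9.0, 8.0, 8.5, 9.5, 7.5]),
        ]
        recs = {(r["i"], r["j"]): r["p_adj"] for r in cb.posthoc(groups, "tukey_hsd")}
        k = 3
        n = 5
        df_err = k * (n - 1)
        ms_err = np.mean([g.var(ddof=1) for g in groups])
        for (i, j), p_adj in recs.items():
            q = abs(groups[i].mean() - groups[j].mean()) / np.sqrt(ms_err / n)
            p_ref = sps.studentized_range.sf(q, k, df_err)
            assert p_adj == pytest.approx(p_ref, rel=1e-4, abs=1e-9)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            cb.posthoc([[1.0, 2.0], [3.0, 4.0]], "holm")


class TestScaleInvariance:
    @pytest.mark.parametrize("k", [0.1, 3.0, 1000.0])
    def test_statistics_unchanged_under_scaling(self, k):
        rng = np.random.default_rng(4)
        groups = [rng.normal(m, 1, 10) for m in (0, 0.4, 1.0)]
        base = cb.anova_oneway(groups)
        scaled = cb.anova_oneway([k * g for g in groups])
        assert scaled.statistic == pytest.approx(base.statistic)
        assert scaled.p == pytest.approx(base.p)
        assert scaled.effect_size == pytest.approx(base.effect_size)
        a, b = rng.normal(0.5, 1, 15), rng.normal(0, 1, 15)
        bt = cb.paired_t(a, b)
        st = cb.paired_t(k * a, k * b)
        assert st.statistic == pytest.approx(bt.statistic)
        assert st.effect_size == pytest.approx(bt.effect_size)


class TestTypeICalibration:
    def test_null_rejection_rates_near_nominal(self):
        """Empirical type-I error in [3.5%, 6.5%] at nominal 5% for the
        one-way ANOVA, balanced factorial ANOVA and paired t."""
        rng = np.random.default_rng(12345)
        n_reps = 1000
        rej = {"oneway": 0, "factorial": 0, "paired": 0}
        fa = np.repeat(["a0", "a1", "a2"], 12)
        fb = np.tile(np.repeat(["b0", "b1", "b2"], 4), 3)
        for _ in range(n_reps):
            groups = rng.normal(size=(3, 15))
            if cb.anova_oneway(list(groups)).p < 0.05:
                rej["oneway"] += 1
            vals = rng.normal(size=36)
            if cb.anova_factorial(vals, fa, fb)["factor_a"].p < 0.05:
                rej["factorial"] += 1
            a, b = rng.normal(size=20), rng.normal(size=20)
            if cb.paired_t(a, b).p < 0.05:
                rej["paired"] += 1
        for name, count in rej.items():
            assert 0.035 <= count / n_reps <= 0.065, (name, count / n_reps)
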