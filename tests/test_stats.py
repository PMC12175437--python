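"""Statistics chain: hand oracles for ANOVA/Tukey/chi-squared/ICC, a
closed-form check for logistic regression, brute-force AUC concordance,
and the averaging/sensitivity helpers."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from hfpefcmr.stats import (
    average_across_visits,
    chi_squared,
    cicchetti_band,
    cohort_summary,
    compare_groups,
    fit_logistic,
    icc2,
    one_way_anova,
    pearson_corr,
    pooled_mean,
    roc_analysis,
    sensitivity_excluding_arrhythmia,
    tukey_hsd,
)


class TestAnova:
    def test_hand_sum_of_squares_oracle(self):
        groups = [np.array([1.0, 2.0, 3.0]), np.array([2.0, 3.0, 4.0]),
                  np.array([3.0, 4.0, 5.0])]
        # hand decomposition: group means 2,3,4; grand mean 3
        # SSB = 3*(1+0+1) = 6 on 2 df; SSW = 3*2 = 6 on 6 df -> F = 3
        f, p = one_way_anova(groups)
        assert f == pytest.approx(3.0)
        assert p == pytest.approx(1.0 - sps.f.cdf(3.0, 2, 6))

    def test_equal_means_give_f_zero_p_one(self):
        g = [np.array([1.0, 2.0, 3.0]), np.array([3.0, 2.0, 1.0])]
        f, p = one_way_anova(g)
        assert f == 0.0 and p == 1.0

    def test_zero_within_variance_unequal_means(self):
        f, p = one_way_anova([np.array([1.0, 1.0]), np.array([2.0, 2.0])])
        assert np.isinf(f) and p == 0.0

    def test_two_groups_f_equals_squared_pooled_t(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.7, 1, 9)
        f, p_f = one_way_anova([a, b])
        t, p_t = sps.ttest_ind(a, b)
        assert f == pytest.approx(t**2, rel=1e-10)
        assert p_f == pytest.approx(p_t, rel=1e-10)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            one_way_anova([np.array([1.0, 2.0])])
        with pytest.raises(ValueError):
            one_way_anova([np.array([1.0]), np.array([2.0, 3.0])])


class TestTukey:
    def test_identical_groups_p_near_one(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        p = tukey_hsd([a, a.copy(), a + 5.0], ["x", "y", "z"])
        assert p[("x", "y")] > 0.99

    def test_constructed_q_at_critical_value_gives_p_05(self):
        # groups with pattern mean_i + (-d,-d,0,d,d): MSW = d^2 on 12 df;
        # a pair separated by q_crit * d / sqrt(5) sits exactly at the 5%
        # studentized-range critical value for k=3
        d = 1.0
        e = np.array([-d, -d, 0.0, d, d])
        q_crit = sps.studentized_range.ppf(0.95, 3, 12)
        delta = q_crit * d / np.sqrt(5)
        groups = [e + 0.0, e + delta, e + 2 * delta]
        p = tukey_hsd(groups, ["a", "b", "c"])
        assert p[("a", "b")] == pytest.approx(0.05, abs=1e-6)
        assert p[("b", "c")] == pytest.approx(0.05, abs=1e-6)

    def test_largest_gap_has_smallest_p(self, rng):
        g = [rng.normal(m, 1.0, 8) for m in (0.0, 1.0, 3.0)]
        p = tukey_hsd(g, ["lo", "mid", "hi"])
        assert p[("lo", "hi")] <= min(p[("lo", "mid")], p[("mid", "hi")])


class TestChiSquared:
    def test_table_proportional_to_margins_gives_zero(self):
        stat, p = chi_squared(np.array([[10, 20], [30, 60]]))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_2x2_diagonal(self):
        stat, _ = chi_squared(np.array([[10, 0], [0, 10]]))
        assert stat == pytest.approx(20.0)

    def test_study_sex_by_group_counts(self):
        # female counts 2/1/5 within groups of 6/16/13
        table = np.array([[2, 1, 5], [4, 15, 8]])
        _, p = chi_squared(table)
        assert p == pytest.approx(0.097, abs=5e-4)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_squared(np.array([[0, 0], [3, 4]]))


class TestPearson:
    def test_exact_linear_relation(self):
        x = np.arange(10.0)
        r, p = pearson_corr(x, 2.0 * x)
        assert r == pytest.approx(1.0)

    def test_five_point_hand_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        r, _ = pearson_corr(x, y)
        hand = np.sum((x - 3.0) * (y - 3.2)) / np.sqrt(
            np.sum((x - 3.0) ** 2) * np.sum((y - 3.2) ** 2))
        assert r == pytest.approx(hand, rel=1e-12)

    def test_independent_large_n_near_zero(self, rng):
        r, _ = pearson_corr(rng.normal(size=10_000), rng.normal(size=10_000))
        assert abs(r) < 0.05

    def test_log_transform_and_guards(self, rng):
        x = rng.lognormal(0, 0.5, 50)
        y = 2.0 * np.log(x) + rng.normal(0, 0.1, 50)
        r_log, _ = pearson_corr(x, y, log_x=True)
        r_raw, _ = pearson_corr(x, y)
        assert r_log > r_raw
        with pytest.raises(ValueError, match="positive"):
            pearson_corr(np.array([-1.0, 1.0, 2.0]), np.ones(3), log_x=True)
        with pytest.raises(ValueError, match="variance"):
            pearson_corr(np.ones(5), np.arange(5.0))


class TestLogistic:
    def test_null_predictor_or_near_one(self, rng):
        y = rng.integers(0, 2, 20_000).astype(float)
        x = rng.normal(size=20_000)
        res = fit_logistic(y, x)
        assert res.odds_ratio == pytest.approx(1.0, abs=0.05)
        assert res.ci_low <= res.odds_ratio <= res.ci_high

    def test_discriminant_analysis_identity_large_n(self, rng):
        # equal-variance Gaussian classes: logistic slope -> dmu / sigma^2
        n, dmu, sigma = 100_000, 1.0, 2.0
        y = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        x = np.r_[rng.normal(0.0, sigma, n // 2), rng.normal(dmu, sigma, n // 2)]
        res = fit_logistic(y, x)
        assert res.coef == pytest.approx(dmu / sigma**2, rel=0.02)

    def test_adjusted_model_reports_covariates(self, rng):
        n = 500
        y = rng.integers(0, 2, n).astype(float)
        x = rng.normal(size=n) + y
        cov = pd.DataFrame({"age": rng.normal(64, 8, n),
                            "sex": rng.integers(0, 2, n),
                            "bmi": rng.normal(30, 4, n)})
        res = fit_logistic(y, x, covariates=cov)
        assert res.adjusted and res.covariates == ["age", "sex", "bmi"]

    def test_complete_separation_flagged_not_inflated(self):
        y = np.r_[np.zeros(10), np.ones(10)]
        x = np.r_[np.arange(10.0), np.arange(100.0, 110.0)]
        with pytest.warns(UserWarning, match="separation"):
            res = fit_logistic(y, x)
        assert res.separated

    def test_outcome_validation(self):
        with pytest.raises(ValueError, match="binary"):
            fit_logistic(np.array([0.0, 1.0, 2.0]), np.arange(3.0))
        with pytest.raises(ValueError, match="both classes"):
            fit_logistic(np.zeros(5), np.arange(5.0))


class TestROC:
    def test_perfect_separation(self):
        res = roc_analysis(np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0]),
                           np.array([0, 0, 0, 1, 1, 1]))
        assert res.auc == 1.0
        assert res.sensitivity == 1.0 and res.specificity == 1.0
        assert 3.0 < res.threshold < 10.0
        assert res.accuracy == 1.0 and res.ppv == 1.0 and res.npv == 1.0

    def test_four_point_toy(self):
        res = roc_analysis(np.array([1.0, 2.0, 3.0, 4.0]),
                           np.array([0, 0, 1, 1]))
        assert res.auc == 1.0
        assert 2.0 < res.threshold < 3.0

    def test_brute_force_concordance_oracle(self):
        # one inversion: AUC = concordant pairs (+ half ties) / all pairs
        x = np.array([1.0, 2.0, 6.0, 4.0, 5.0, 3.0])
        y = np.array([0, 0, 0, 1, 1, 1])
        pos, neg = x[y == 1], x[y == 0]
        pairs = [(1.0 if a > b else 0.5 if a == b else 0.0)
                 for a in pos for b in neg]
        res = roc_analysis(x, y)
        assert res.auc == pytest.approx(np.mean(pairs))

    def test_cross_check_against_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        x = rng.normal(size=200) + np.r_[np.zeros(120), np.ones(80)]
        y = np.r_[np.zeros(120), np.ones(80)]
        assert roc_analysis(x, y).auc == pytest.approx(roc_auc_score(y, x),
                                                       abs=1e-12)

    @given(shift=st.floats(-3.0, 3.0), scale=st.floats(0.1, 10.0))
    def test_auc_invariant_under_monotone_transform(self, shift, scale):
        rng = np.random.default_rng(5)
        x = rng.normal(size=60)
        y = (rng.random(60) < 0.4).astype(float)
        if y.min() == y.max():
            return
        base = roc_analysis(x, y).auc
        assert roc_analysis(np.exp(scale * x + shift), y).auc == pytest.approx(
            base, abs=1e-12)

    def test_constant_marker_degenerate(self):
        with pytest.warns(UserWarning, match="constant"):
            res = roc_analysis(np.ones(10), np.r_[np.zeros(5), np.ones(5)])
        assert res.auc == 0.5


class TestICC:
    def test_exact_agreement_is_excellent(self):
        a = np.array([10.0, 12.0, 15.0, 9.0, 14.0])
        res = icc2(a, a.copy())
        assert res.icc2 == pytest.approx(1.0)
        assert res.cicchetti_band == "excellent"

    def test_hand_mean_squares_oracle_4x2(self):
        # closed-form ICC(2,1) from the two-way ANOVA decomposition
        day1 = np.array([9.0, 10.0, 12.0, 15.0])
        day8 = np.array([10.0, 11.0, 13.0, 14.0])
        n, k = 4, 2
        mat = np.c_[day1, day8]
        grand = mat.mean()
        msr = k * np.sum((mat.mean(axis=1) - grand) ** 2) / (n - 1)
        msc = n * np.sum((mat.mean(axis=0) - grand) ** 2) / (k - 1)
        sst = np.sum((mat - grand) ** 2)
        mse = (sst - (n - 1) * msr - (k - 1) * msc) / ((n - 1) * (k - 1))
        hand = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        res = icc2(day1, day8)
        assert res.icc2 == pytest.approx(hand, rel=1e-9)

    def test_visit_shift_penalizes_absolute_agreement(self):
        import pingouin as pg

        rng = np.random.default_rng(8)
        day1 = rng.normal(10.0, 3.0, 40)
        day8 = day1 + 2.0 + rng.normal(0.0, 0.3, 40)
        res = icc2(day1, day8)
        long = pd.DataFrame({
            "s": np.tile(np.arange(40), 2),
            "r": np.repeat(["a", "b"], 40),
            "v": np.r_[day1, day8]})
        tab = pg.intraclass_corr(long, "s", "r", "v").set_index("Type")
        consistency = float(tab.loc["ICC(C,1)" if "ICC(C,1)" in tab.index
                                    else "ICC3", "ICC"])
        assert res.icc2 < consistency

    def test_bands_and_guards(self):
        assert cicchetti_band(0.2) == "poor"
        assert cicchetti_band(0.5) == "fair"
        assert cicchetti_band(0.7) == "good"
        assert cicchetti_band(0.9) == "excellent"
        with pytest.raises(ValueError, match="zero total variance"):
            icc2(np.ones(5), np.ones(5))
        with pytest.raises(ValueError, match="n >= 3"):
            icc2(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


class TestAveragingAndSensitivity:
    def test_visit_averaging(self):
        df = pd.DataFrame({
            "subject_id": ["a", "a", "b"],
            "visit_day": [1, 8, 1],
            "group": ["t2dm", "t2dm", "t2dm"],
            "mpr": [10.0, 20.0, 3.0],
        })
        out = average_across_visits(df)
        assert out.loc[out.subject_id == "a", "mpr"].iloc[0] == 15.0
        assert out.loc[out.subject_id == "b", "mpr"].iloc[0] == 3.0  # carried

    def test_missing_day8_value_carries_day1(self):
        df = pd.DataFrame({
            "subject_id": ["a", "a"], "visit_day": [1, 8],
            "group": ["t2dm"] * 2, "mpr": [2.5, np.nan]})
        assert average_across_visits(df).mpr.iloc[0] == 2.5

    def test_sensitivity_subset_and_group_guard(self):
        df = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(6)],
            "group": ["obese_control"] * 2 + ["t2dm"] * 2 + ["hfpef_t2dm"] * 2,
            "arrhythmia_history": [0, 0, 0, 0, 1, 0],
            "mpr": [3.6, 3.7, 3.0, 3.1, 2.2, 2.3],
        })
        res = sensitivity_excluding_arrhythmia(df, lambda d: len(d))
        assert res.n_excluded == 1 and res.n_remaining == 5 and res.result == 5
        df.loc[df.group == "hfpef_t2dm", "arrhythmia_history"] = 1
        with pytest.raises(ValueError, match="hfpef_t2dm"):
            sensitivity_excluding_arrhythmia(df, lambda d: len(d))

    def test_no_flagged_subjects_identity(self):
        df = pd.DataFrame({
            "subject_id": ["a", "b", "c", "d"],
            "group": ["t2dm", "t2dm", "hfpef_t2dm", "hfpef_t2dm"],
            "arrhythmia_history": [0, 0, 0, 0],
            "mpr": [3.0, 3.1, 2.2, 2.3],
        })
        res = sensitivity_excluding_arrhythmia(df, lambda d: d.mpr.mean())
        assert res.n_excluded == 0
        assert res.result == pytest.approx(df.mpr.mean())


class TestCohortSummary:
    def test_weighted_overall_equals_pooled_mean(self, rng):
        df = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(35)],
            "group": ["obese_control"] * 6 + ["t2dm"] * 16 + ["hfpef_t2dm"] * 13,
            "bmi": np.r_[rng.normal(27.7, 1.3, 6), rng.normal(30.6, 3.1, 16),
                         rng.normal(32.3, 4.7, 13)],
            "sex": rng.integers(0, 2, 35),
        })
        out = cohort_summary(df, ["bmi"], ["sex"],
                             group_order=["obese_control", "t2dm", "hfpef_t2dm"])
        row = out[out.variable == "bmi"].iloc[0]
        expected = pooled_mean(
            [row[f"{g}_mean"] for g in ("obese_control", "t2dm", "hfpef_t2dm")],
            [6, 16, 13])
        assert row.overall_mean == pytest.approx(expected, rel=1e-12)
        sex_row = out[out.variable == "sex"].iloc[0]
        assert sex_row.overall_count == int((df.sex == 1).sum())

    def test_compare_groups_structure(self, rng):
        vals = {g: rng.normal(m, 1.0, n) for g, m, n in
                [("obese_control", 0.0, 6), ("t2dm", 0.5, 16), ("hfpef_t2dm", 2.0, 13)]}
        cmp_res = compare_groups(vals, "demo")
        assert cmp_res.ns == [6, 16, 13]
        assert len(cmp_res.tukey_p) == 3
        assert 0.0 <= cmp_res.anova_p <= 1.0
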