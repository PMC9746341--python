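"""Group tests, trend contrast, covariate adjustment, ICC, correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from hippomrs.stats import (
    CollinearityError,
    UndefinedTestError,
    chi_square_2x2,
    glm_adjusted_difference,
    icc_test_retest,
    pearson_diff_correlation,
    response_classification,
    response_group,
    t_test_from_summary,
    trend_anova,
)


class TestResponseClassification:
    @pytest.mark.parametrize(
        "w0, wn, category",
        [
            (20.0, 10.0, "complete responder"),   # r = 0.5 exactly, inclusive
            (24.0, 20.0, "non-responder"),        # r = 1/6
            (24.0, 15.0, "partial responder"),    # r = 0.375
            (24.0, 18.0, "partial responder"),    # r = 0.25 boundary
            (20.0, 25.0, "non-responder"),        # worsened
        ],
    )
    def test_categories(self, w0, wn, category):
        assert response_classification(w0, wn) == category

    def test_final_group_split(self):
        assert response_group(20.0, 10.0) == "n-RD"  # r = 0.5 inclusive
        assert response_group(20.0, 10.5) == "RD"

    def test_zero_baseline_undefined(self):
        with pytest.raises(UndefinedTestError):
            response_classification(0.0, 5.0)


class TestTTestFromSummary:
    def test_matches_raw_data_pooled_t(self):
        """Constructive check: a dataset built to match the summary gives the
        same pooled t through scipy's raw-data routine."""
        rng = np.random.default_rng(0)
        x = rng.normal(10, 3, 26)
        y = rng.normal(8, 4, 41)
        res = t_test_from_summary(
            x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y)
        )
        ref = sps.ttest_ind(x, y, equal_var=True)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-12)
        assert res.df == 65

    def test_equal_means_give_zero(self):
        res = t_test_from_summary(5.0, 1.0, 10, 5.0, 2.0, 12)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_zero_variance_unequal_means_flagged_infinite(self):
        res = t_test_from_summary(5.0, 0.0, 10, 4.0, 0.0, 12)
        assert np.isinf(res.statistic)
        assert res.p_value == 0.0

    def test_small_groups_rejected(self):
        with pytest.raises(UndefinedTestError):
            t_test_from_summary(1.0, 1.0, 1, 2.0, 1.0, 5)


class TestChiSquare:
    def test_proportional_rows_give_zero(self):
        res = chi_square_2x2(10, 20, 5, 10)
        assert res.statistic == pytest.approx(0.0)
        assert res.df == 1

    def test_matches_scipy_without_correction(self):
        res = chi_square_2x2(12, 7, 9, 14)
        ref = sps.chi2_contingency([[12, 7], [9, 14]], correction=False)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-12)

    @given(
        a=st.integers(1, 40), b=st.integers(1, 40),
        c=st.integers(1, 40), d=st.integers(1, 40),
    )
    @settings(max_examples=50, deadline=None)
    def test_invariant_under_simultaneous_row_column_swap(self, a, b, c, d):
        res1 = chi_square_2x2(a, b, c, d)
        res2 = chi_square_2x2(d, c, b, a)
        assert res1.statistic == pytest.approx(res2.statistic, rel=1e-12)

    def test_zero_margin_undefined(self):
        with pytest.raises(UndefinedTestError):
            chi_square_2x2(0, 0, 5, 10)


class TestTrendAnova:
    @staticmethod
    def make_records(week_means, n_per_week=20, sd=1.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for w, mu in enumerate(week_means):
            for _ in range(n_per_week):
                rows.append({"week": w, "m": rng.normal(mu, sd)})
        return pd.DataFrame(rows)

    def test_strict_linear_trend_detected(self):
        df = self.make_records([0, 1, 2, 3, 4, 5, 6], sd=1e-9)
        res = trend_anova(df, "m")
        assert res.p_value < 1e-6

    def test_null_p_values_uniform(self):
        """Flat means: p for trend is uniform over seeds (KS check)."""
        pvals = [
            trend_anova(self.make_records([2, 2, 2, 2], n_per_week=8, seed=s), "m").p_value
            for s in range(300)
        ]
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_constant_data_p_one(self):
        df = self.make_records([3, 3, 3], sd=0.0)
        res = trend_anova(df, "m")
        assert res.p_value == 1.0

    def test_too_few_weeks_rejected(self):
        df = self.make_records([1, 2])
        with pytest.raises(UndefinedTestError):
            trend_anova(df, "m")


class TestGlmAdjustedDifference:
    @staticmethod
    def make_data(n=80, confound_through_age=False, seed=0):
        rng = np.random.default_rng(seed)
        group = np.repeat(["A", "B"], n // 2)
        age = rng.normal(30, 8, n)
        if confound_through_age:
            age = age + np.where(group == "B", 6.0, 0.0)
            y = 0.3 * age + rng.normal(0, 1, n)  # group effect only via age
        else:
            y = np.where(group == "B", 1.0, 0.0) + rng.normal(0, 1, n)
        return pd.DataFrame(
            {
                "y": y, "group": group, "age": age,
                "gender": rng.integers(0, 2, n).astype(float),
                "age_onset": rng.normal(24, 4, n),
                "duration": rng.normal(7, 3, n),
            }
        )

    def test_independent_covariates_leave_p_similar(self):
        stats_unadj, stats_adj = [], []
        for seed in range(40):
            df = self.make_data(seed=seed)
            res = glm_adjusted_difference(df, "y")
            a = df[df["group"] == "A"]["y"]
            b = df[df["group"] == "B"]["y"]
            raw = sps.ttest_ind(b, a, equal_var=True)
            stats_unadj.append(raw.statistic)
            stats_adj.append(res.statistic)
        assert np.corrcoef(stats_unadj, stats_adj)[0, 1] > 0.95
        assert abs(np.mean(stats_adj) - np.mean(stats_unadj)) < 0.5

    def test_confound_through_age_removed(self):
        stats_adj = [
            glm_adjusted_difference(
                self.make_data(confound_through_age=True, seed=s), "y"
            ).statistic
            for s in range(40)
        ]
        # group adds nothing beyond age: t statistics centred on zero
        assert abs(np.mean(stats_adj)) < 0.5

    def test_zero_variance_covariate_named(self):
        df = self.make_data()
        df["duration"] = 7.0
        with pytest.raises(CollinearityError, match="duration"):
            glm_adjusted_difference(df, "y")


class TestIcc:
    def test_identical_sessions_give_one(self):
        x = np.array([3.0, 5.0, 9.0, 2.0, 7.0])
        assert icc_test_retest(x, x) == pytest.approx(1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(1)
        icc = icc_test_retest(rng.normal(size=200), rng.normal(size=200))
        assert abs(icc) < 0.1

    def test_variance_components_expectation(self):
        """sigma_subject^2 = 3 sigma_error^2 -> ICC -> 0.75 at large n."""
        rng = np.random.default_rng(2)
        n = 4000
        subject = rng.normal(0, np.sqrt(3.0), n)
        icc = icc_test_retest(
            subject + rng.normal(0, 1.0, n), subject + rng.normal(0, 1.0, n)
        )
        assert icc == pytest.approx(0.75, abs=0.03)

    def test_matches_pingouin_icc3(self):
        """Cross-check the ANOVA decomposition against pingouin's ICC3."""
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        subj = rng.normal(0, 2, 25)
        w0 = subj + rng.normal(0, 1, 25)
        w1 = subj + rng.normal(0, 1, 25)
        ours = icc_test_retest(w0, w1)
        long = pd.DataFrame(
            {
                "subject": np.tile(np.arange(25), 2),
                "session": np.repeat([0, 1], 25),
                "score": np.concatenate([w0, w1]),
            }
        )
        ref = pingouin.intraclass_corr(
            long, targets="subject", raters="session", ratings="score"
        )
        consistency_single = ref["Type"].isin(["ICC3", "ICC(C,1)"])
        icc3 = ref.loc[consistency_single, "ICC"].iloc[0]
        assert ours == pytest.approx(icc3, abs=1e-6)

    def test_zero_between_subject_variance_warns(self):
        # all subjects identical within each session: no subject effect
        with pytest.warns(UserWarning):
            icc = icc_test_retest([1.0, 1.0, 1.0, 1.0], [2.0, 2.0, 2.0, 2.0])
        assert icc == 0.0

    def test_needs_three_subjects(self):
        with pytest.raises(UndefinedTestError):
            icc_test_retest([1.0, 2.0], [1.0, 2.0])


class TestPearson:
    def test_perfect_negative(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r, p = pearson_diff_correlation(x, -2 * x)
        assert r == pytest.approx(-1.0)

    def test_four_point_hand_case(self):
        """(0,0),(1,2),(2,1),(3,3): Sxy = 4, Sxx = Syy = 5 -> r = 0.8."""
        r, p = pearson_diff_correlation([0, 1, 2, 3], [0, 2, 1, 3])
        assert r == pytest.approx(0.8, rel=1e-12)
        assert p == pytest.approx(0.2, rel=1e-9)

    def test_null_type_i_error_calibrated(self):
        rng = np.random.default_rng(4)
        rejections = sum(
            pearson_diff_correlation(rng.normal(size=50), rng.normal(size=50))[1] < 0.05
            for _ in range(600)
        )
        assert 0.02 <= rejections / 600 <= 0.08

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedTestError):
            pearson_diff_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
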