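"""Exclusions, staging, nonparametric tests and regression models."""

import itertools

import numpy as np
import pandas as pd
import pytest

import emphyhet.stats as st
from emphyhet import (
    apply_exclusions,
    fit_adjusted_linear,
    fit_logistic_gold,
    fit_piecewise_univariate,
    gold_stage,
    left_right_sign_test,
    proportion_positive_test,
    summarize_cohort,
)


def subject(**kw):
    base = dict(
        subject_id="S0", copd=1, age=65.0, male=1, pack_years=50.0,
        fev1_pre_l=2.0, fev1_post_l=2.05, fev1_pct_pred=70.0,
        fev1_fvc_pct=60.0, rv_tlc_pct=43.0, dlco_pct_pred=60.0,
        cb="no", laa_pct=5.0, hi_pct=20.0, hi_left_pct=20.0,
        hi_right_pct=20.0, gold_stage="II",
    )
    base.update(kw)
    return base


class TestExclusions:
    def test_bronchodilator_response_both_thresholds(self):
        # 25% and 250 ml: both conditions met -> excluded
        df = pd.DataFrame([subject(fev1_pre_l=1.00, fev1_post_l=1.25)])
        kept, log = apply_exclusions(df)
        assert len(kept) == 0
        assert log["bronchodilator_response"] == 1

    def test_percent_without_volume_is_retained(self):
        # 15% but only 150 ml: the "and" rule keeps the subject
        df = pd.DataFrame([subject(fev1_pre_l=1.00, fev1_post_l=1.15)])
        kept, log = apply_exclusions(df)
        assert len(kept) == 1
        assert log["retained"] == 1

    def test_cb_yes_and_missing_both_excluded(self):
        df = pd.DataFrame([
            subject(cb="yes"), subject(cb=""), subject(cb=None), subject(cb="no"),
        ])
        kept, log = apply_exclusions(df)
        assert len(kept) == 1
        assert log["chronic_bronchitis_or_unknown"] == 3

    def test_missing_spirometry_logged(self):
        df = pd.DataFrame([subject(fev1_pre_l=np.nan)])
        kept, log = apply_exclusions(df)
        assert len(kept) == 0
        assert log["missing_spirometry"] == 1

    def test_disposition_counts_conserve_input(self):
        rows = [
            subject(fev1_pre_l=1.0, fev1_post_l=1.3),
            subject(cb="yes"),
            subject(),
            subject(copd=0, fev1_pre_l=1.0, fev1_post_l=1.3),  # BR rule is COPD-only
        ]
        kept, log = apply_exclusions(pd.DataFrame(rows))
        assert log["input"] == 4
        assert (log["bronchodilator_response"] + log["chronic_bronchitis_or_unknown"]
                + log["missing_spirometry"] + log["retained"]) == 4
        assert len(kept) == 2


class TestGoldStage:
    @pytest.mark.parametrize(
        "fev1, ratio, stage",
        [
            (98, 0.77, "none"),
            (85, 0.61, "I"),
            (71, 0.61, "II"),
            (80, 0.61, "I"),    # boundary: >= 80 is stage I
            (50, 0.61, "II"),
            (49, 0.61, "III"),
            (30, 0.40, "III"),
            (29, 0.40, "IV"),
            (71, 61.0, "II"),   # percent form accepted
            (98, 0.70, "none"),  # fixed-ratio boundary
        ],
    )
    def test_standard_cutoffs(self, fev1, ratio, stage):
        assert gold_stage(fev1, ratio) == stage

    def test_non_finite_raises(self):
        with pytest.raises(ValueError):
            gold_stage(np.nan, 0.6)


class TestSummaries:
    def test_frequency_display(self):
        df = pd.DataFrame([subject(male=1)] * 104 + [subject(male=0)] * 56)
        t = summarize_cohort(df)
        row = t[(t.variable == "male") & (t.level == "1")].iloc[0]
        assert row["display"] == "104(65%)"

    def test_single_subject_iqr_collapses(self):
        t = summarize_cohort(pd.DataFrame([subject(age=64.0)]))
        row = t[t.variable == "age"].iloc[0]
        assert (row["median"], row["q1"], row["q3"]) == (64.0, 64.0, 64.0)

    def test_empty_cohort_raises(self):
        with pytest.raises(ValueError):
            summarize_cohort(pd.DataFrame(columns=["age"]))


class TestProportionTest:
    def test_closed_form_129_of_160(self):
        hi = np.r_[np.ones(129), -np.ones(31)]
        res = proportion_positive_test(hi)
        assert res.statistic == pytest.approx(60.025)  # (129-80)^2/80 + (31-80)^2/80
        assert res.p_value < 1e-10

    def test_exact_null(self):
        hi = np.r_[np.ones(80), -np.ones(80)]
        res = proportion_positive_test(hi)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_161_of_190_significant(self):
        hi = np.r_[np.ones(161), -np.ones(29)]
        assert proportion_positive_test(hi).p_value < 0.05

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            proportion_positive_test(np.array([]))


def sign_test_enumeration(diffs):
    """Exact two-sided sign-test p by enumerating all 2^n sign patterns."""
    nz = [d for d in diffs if d != 0]
    n = len(nz)
    k = sum(d > 0 for d in nz)
    obs = abs(k - n / 2)
    hits = sum(
        abs(sum(signs) - n / 2) >= obs - 1e-12
        for signs in itertools.product((0, 1), repeat=n)
    )
    return hits / 2**n


class TestSignTest:
    def test_all_positive_closed_form(self):
        res = left_right_sign_test(np.arange(1, 11) + 1.0, np.arange(1, 11) * 1.0)
        assert res.p_value == pytest.approx(2 * 0.5**10)

    def test_balanced_is_one(self):
        left = np.r_[np.ones(5), np.zeros(5)]
        right = np.r_[np.zeros(5), np.ones(5)]
        assert left_right_sign_test(left, right).p_value == pytest.approx(1.0)

    def test_all_zero_warns_p_one(self):
        with pytest.warns(UserWarning):
            res = left_right_sign_test(np.ones(6), np.ones(6))
        assert res.p_value == 1.0

    @pytest.mark.parametrize("seed", range(4))
    def test_agrees_with_enumeration_small_n(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        diffs = rng.normal(0.3, 1.0, n)
        diffs[diffs == 0] = 0.1
        res = left_right_sign_test(diffs, np.zeros(n))
        assert res.p_value == pytest.approx(sign_test_enumeration(diffs), abs=1e-12)


def rank_sum_enumeration(x, y):
    """Exact two-sided rank-sum p by enumerating all group assignments."""
    pooled = np.concatenate([x, y])
    n = len(x)
    ranks = pd.Series(pooled).rank().to_numpy()
    stats = []
    for idx in itertools.combinations(range(len(pooled)), n):
        r = ranks[list(idx)].sum()
        stats.append(r - n * (n + 1) / 2)  # Mann-Whitney U of the "x" group
    stats = np.asarray(stats)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    p_le = (stats <= u_obs + 1e-12).mean()
    p_ge = (stats >= u_obs - 1e-12).mean()
    return min(1.0, 2 * min(p_le, p_ge))


class TestWilcoxon:
    @pytest.mark.parametrize("seed", range(4))
    def test_agrees_with_enumeration_small_n(self, seed):
        rng = np.random.default_rng(100 + seed)
        x = rng.normal(0, 1, int(rng.integers(3, 5)))
        y = rng.normal(0.8, 1, int(rng.integers(3, 5)))
        res = st.wilcoxon_rank_sum(x, y)
        assert res.detail["method"] == "exact"
        assert res.p_value == pytest.approx(rank_sum_enumeration(x, y), abs=1e-12)

    def test_large_shift_is_significant(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 30)
        y = rng.normal(5, 1, 30)
        assert st.wilcoxon_rank_sum(x, y).p_value < 1e-3

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            st.wilcoxon_rank_sum(np.array([]), np.array([1.0]))


class TestChiSquare2x2:
    def test_matches_closed_form(self):
        a, b, c, d = 18.0, 13.0, 101.0, 28.0
        table = np.array([[a, b], [c, d]])
        n = a + b + c + d
        closed = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        res = st.chi2_2x2(table)
        assert res.statistic == pytest.approx(closed, rel=1e-12)

    def test_yates_flag_changes_p(self):
        table = np.array([[18, 13], [101, 28]])
        assert st.chi2_2x2(table, correction=True).p_value > st.chi2_2x2(table).p_value


class TestCompareGroups:
    def _cohort(self, n_low=30, n_up=30, shift=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n_low):
            rows.append(subject(hi_pct=-10.0, fev1_pct_pred=rng.normal(60, 10),
                                gold_stage="III"))
        for i in range(n_up):
            rows.append(subject(hi_pct=10.0, fev1_pct_pred=rng.normal(60 + shift, 10),
                                gold_stage="II"))
        return pd.DataFrame(rows)

    def test_large_shift_detected(self):
        comp = st.compare_groups(self._cohort(shift=20.0), variables=("fev1_pct_pred",))
        fev = next(c for c in comp if c.variable == "fev1_pct_pred")
        assert fev.p_value < 1e-3

    def test_gold_dichotomy_counts(self):
        comp = st.compare_groups(self._cohort(), variables=())
        gold = next(c for c in comp if c.variable == "gold_iii_iv")
        assert gold.group_stats["HI<=0"]["gold_iii_iv"] == 30
        assert gold.group_stats["HI>0"]["gold_iii_iv"] == 0

    def test_empty_group_skipped_with_warning(self):
        df = self._cohort(n_low=0)
        with pytest.warns(UserWarning):
            comp = st.compare_groups(df, variables=("fev1_pct_pred",))
        assert np.isnan(comp[0].p_value)


class TestPiecewise:
    def test_noise_free_v_shape_recovered_exactly(self):
        hi = np.linspace(-50, 50, 21)
        y = 5.0 + np.where(hi > 0, 1.0 * hi, -2.0 * hi)  # slope +1 right, -2 left
        df = pd.DataFrame({"hi_pct": hi, "y": y})
        fit = fit_piecewise_univariate(df, "y")
        assert fit["hi_pos"]["estimate"] == pytest.approx(1.0, abs=1e-10)
        assert fit["hi_neg"]["estimate"] == pytest.approx(-2.0, abs=1e-10)

    def test_equal_slopes_reduce_to_simple_regression(self):
        rng = np.random.default_rng(3)
        hi = rng.uniform(-40, 40, 80)
        y = 2.0 + 0.5 * hi + rng.normal(0, 1, 80)
        df = pd.DataFrame({"hi_pct": hi, "y": y})
        constrained = fit_piecewise_univariate(df, "y", constrain_equal_slopes=True)
        slope, intercept = np.polyfit(hi, y, 1)
        assert constrained["hi"]["estimate"] == pytest.approx(slope, rel=1e-10)
        assert constrained["const"]["estimate"] == pytest.approx(intercept, rel=1e-10)

    def test_one_sided_design_raises(self):
        df = pd.DataFrame({"hi_pct": np.linspace(1, 50, 20),
                           "y": np.linspace(1, 50, 20)})
        with pytest.raises(np.linalg.LinAlgError):
            fit_piecewise_univariate(df, "y")

    def test_few_per_side_flagged(self):
        hi = np.r_[np.linspace(1, 50, 18), [-5.0, -10.0]]
        df = pd.DataFrame({"hi_pct": hi, "y": hi * 2.0})
        fit = fit_piecewise_univariate(df, "y")
        assert fit.warnings


class TestAdjustedLinear:
    def _design_fixture(self):
        # 10-row complete-case fixture with both HI signs
        return pd.DataFrame({
            "fev1_pct_pred": [55, 70, 62, 81, 44, 90, 66, 58, 73, 49],
            "hi_pct": [10, -20, 35, 5, -40, 60, 15, -5, 25, -15],
            "laa_pct": [8, 12, 3, 1, 20, 0.5, 6, 9, 4, 14],
            "age": [60, 65, 70, 55, 72, 61, 67, 63, 69, 58],
            "male": [1, 0, 1, 1, 0, 1, 0, 1, 0, 1],
            "pack_years": [40, 55, 30, 20, 80, 15, 50, 45, 35, 60],
        })

    def test_matches_normal_equations_oracle(self):
        df = self._design_fixture()
        fit = fit_adjusted_linear(df, "fev1_pct_pred")
        hi = df["hi_pct"].to_numpy(dtype=float)
        X = np.column_stack([
            np.ones(len(df)), df["laa_pct"], np.maximum(hi, 0), np.minimum(hi, 0),
            df["age"], df["male"], df["pack_years"],
        ])
        beta = np.linalg.solve(X.T @ X, X.T @ df["fev1_pct_pred"].to_numpy(dtype=float))
        assert np.allclose(fit.table["estimate"].to_numpy(), beta, atol=1e-9)

    def test_constant_shift_moves_only_intercept(self):
        df = self._design_fixture()
        f0 = fit_adjusted_linear(df, "fev1_pct_pred")
        df2 = df.assign(fev1_pct_pred=df["fev1_pct_pred"] + 17.0)
        f1 = fit_adjusted_linear(df2, "fev1_pct_pred")
        assert f1["const"]["estimate"] == pytest.approx(f0["const"]["estimate"] + 17.0)
        for term in ("laa_pct", "hi_pos", "hi_neg", "age", "male", "pack_years"):
            assert f1[term]["estimate"] == pytest.approx(f0[term]["estimate"], abs=1e-9)

    def test_complete_case_n_reported(self):
        df = self._design_fixture()
        df.loc[0, "pack_years"] = np.nan
        fit = fit_adjusted_linear(df, "fev1_pct_pred")
        assert fit.n == 9

    def test_too_few_cases_raises(self):
        with pytest.raises(ValueError):
            fit_adjusted_linear(self._design_fixture().head(6), "fev1_pct_pred")


class TestLogisticGold:
    def _cohort(self, n=300, seed=0, null=True):
        rng = np.random.default_rng(seed)
        hi = rng.uniform(-30, 60, n)
        df = pd.DataFrame({
            "hi_pct": hi,
            "laa_pct": rng.uniform(0, 20, n),
            "age": rng.normal(65, 5, n),
            "male": rng.integers(0, 2, n),
            "pack_years": rng.uniform(20, 80, n),
        })
        p = 0.5 if null else 1 / (1 + np.exp(-(-2.0 + 0.2 * df["laa_pct"])))
        severe = rng.random(n) < p
        df["gold_stage"] = np.where(severe, "III", "II")
        df["copd"] = 1
        return df

    def test_null_covariates_give_or_near_one(self):
        fit = fit_logistic_gold(self._cohort(seed=4))
        for term in ("laa_pct", "hi_pos", "hi_neg", "age", "male"):
            row = fit[term]
            assert row["ci_low"] <= 1.0 <= row["ci_high"]

    def test_or_ci_brackets_estimate(self):
        fit = fit_logistic_gold(self._cohort(seed=5, null=False))
        t = fit.table
        assert ((t["ci_low"] <= t["estimate"]) & (t["estimate"] <= t["ci_high"])).all()

    def test_constant_outcome_raises_separation(self):
        df = self._cohort(seed=6)
        df["gold_stage"] = "II"
        with pytest.raises(st.SeparationError):
            fit_logistic_gold(df)

    def test_perfect_separation_reported(self):
        df = self._cohort(n=60, seed=7)
        df["gold_stage"] = np.where(df["hi_pct"] > 10, "III", "II")
        with pytest.raises(st.SeparationError):
            fit_logistic_gold(df)
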