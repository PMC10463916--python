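import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from sidermap.stats import (
    conover_posthoc,
    cooks_distances,
    friedman_kendall,
    influence_filter,
    lme_compare,
    rm_anova_tukey,
    skillings_mack,
)


def brute_friedman_chi2(arr):
    """Direct rank-formula evaluation with tie correction."""
    n, k = arr.shape
    ranks = np.array([sps.rankdata(row) for row in arr])
    R = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * np.sum((R - n * (k + 1) / 2) ** 2)
    ties = sum(float(np.sum(c**3 - c)) for row in arr for c in [np.unique(row, return_counts=True)[1]])
    return chi2 / (1 - ties / (n * k * (k**2 - 1)))


class TestFriedmanKendall:
    def test_perfect_concordance_gives_w_one(self):
        arr = np.tile([1.0, 2.0, 3.0], (4, 1)) + np.arange(4)[:, None] * 10
        res = friedman_kendall(arr)
        assert res.kendall_w == pytest.approx(1.0)
        assert res.df == 2

    def test_constant_blocks_give_zero(self):
        arr = np.tile([5.0, 5.0, 5.0, 5.0], (6, 1))
        res = friedman_kendall(arr)
        assert res.chi2 == 0.0 and res.kendall_w == 0.0

    def test_random_design_matches_rank_formula_and_scipy(self):
        rng = np.random.default_rng(0)
        arr = rng.normal(size=(6, 4))
        res = friedman_kendall(arr)
        assert res.chi2 == pytest.approx(brute_friedman_chi2(arr))
        scipy_chi2, scipy_p = sps.friedmanchisquare(*arr.T)
        assert res.chi2 == pytest.approx(scipy_chi2)
        assert res.p == pytest.approx(scipy_p)

    def test_w_identity_holds_under_ties(self):
        rng = np.random.default_rng(1)
        arr = rng.integers(0, 4, size=(8, 5)).astype(float)
        res = friedman_kendall(arr)
        assert res.kendall_w == pytest.approx(res.chi2 / (8 * 4))
        assert 0.0 <= res.kendall_w <= 1.0

    def test_missing_cells_are_routed_to_skillings_mack(self):
        arr = np.ones((4, 3))
        arr[0, 0] = np.nan
        with pytest.raises(ValueError, match="skillings_mack"):
            friedman_kendall(arr)


def longhand_skillings_mack(arr):
    """Independent quadratic-form evaluation from the definition."""
    n, k = arr.shape
    A = np.zeros(k)
    cov = np.zeros((k, k))
    for row in arr:
        obs = np.isfinite(row)
        s = obs.sum()
        if s < 2:
            continue
        r = sps.rankdata(row[obs])
        full = np.zeros(k)
        full[obs] = np.sqrt(12.0 / (s + 1)) * (r - (s + 1) / 2.0)
        A += full
        for j in range(k):
            for l in range(k):
                if obs[j] and obs[l]:
                    cov[j, l] += (s - 1) if j == l else -1
    return float(A @ np.linalg.pinv(cov) @ A)


class TestSkillingsMack:
    def test_reduces_to_friedman_on_complete_tiefree_designs(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            arr = rng.normal(size=(7, 4))
            assert skillings_mack(arr).statistic == pytest.approx(
                friedman_kendall(arr).chi2, abs=1e-8
            )

    def test_constant_design_gives_zero(self):
        assert skillings_mack(np.ones((5, 3))).statistic == pytest.approx(0.0)

    def test_single_missing_cell_matches_longhand_quadratic_form(self):
        rng = np.random.default_rng(3)
        arr = rng.normal(size=(6, 4))
        arr[2, 1] = np.nan
        res = skillings_mack(arr)
        assert res.statistic == pytest.approx(longhand_skillings_mack(arr))
        assert res.df == 3

    def test_unobserved_treatment_dropped_with_warning(self):
        rng = np.random.default_rng(4)
        arr = rng.normal(size=(5, 4))
        arr[:, 2] = np.nan
        with pytest.warns(UserWarning, match="dropped"):
            res = skillings_mack(arr)
        assert res.df == 2 and res.dropped_treatments == (2,)


class TestConoverPosthoc:
    def test_identical_treatments_yield_no_rejections(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=(6, 1))
        arr = np.tile(base, (1, 4))
        table = conover_posthoc(arr)
        assert (table["p_adjusted"] >= table["p_raw"] - 1e-12).all()
        assert (table["p_adjusted"] > 0.99).all()

    def test_dominant_treatment_has_smallest_pvalues(self):
        rng = np.random.default_rng(6)
        arr = rng.normal(size=(8, 4))
        arr[:, 2] += 50.0
        table = conover_posthoc(arr, labels=list("abcd"))
        involving_c = table[(table.treatment_a == "c") | (table.treatment_b == "c")]
        others = table[(table.treatment_a != "c") & (table.treatment_b != "c")]
        assert involving_c["p_adjusted"].max() < others["p_adjusted"].min()

    def test_bh_adjustment_equals_stepup_bruteforce(self):
        rng = np.random.default_rng(7)
        arr = rng.normal(size=(7, 5))
        arr[:, 0] += 2.0
        table = conover_posthoc(arr)
        raw = table["p_raw"].to_numpy()
        m = len(raw)
        order = np.argsort(raw)
        stepup = np.empty(m)
        prev = 1.0
        for rank_from_top in range(m - 1, -1, -1):
            i = order[rank_from_top]
            val = min(prev, raw[i] * m / (rank_from_top + 1))
            stepup[i] = val
            prev = val
        assert table["p_adjusted"].to_numpy() == pytest.approx(stepup)

    def test_incomplete_design_rejected(self):
        arr = np.ones((4, 3))
        arr[1, 2] = np.nan
        with pytest.raises(ValueError, match="complete"):
            conover_posthoc(arr)


class TestRMAnovaTukey:
    def test_identical_conditions_are_null(self):
        rng = np.random.default_rng(8)
        arr = np.tile(rng.normal(size=(6, 1)), (1, 4))
        res = rm_anova_tukey(arr)
        assert res.F == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_shifted_condition_dominates(self):
        rng = np.random.default_rng(9)
        arr = rng.normal(size=(8, 4))
        arr[:, 1] += 10 * arr.std()
        res = rm_anova_tukey(arr, labels=list("wxyz"))
        assert res.p < 1e-3
        inv = res.tukey[(res.tukey.condition_a == "x") | (res.tukey.condition_b == "x")]
        rest = res.tukey[(res.tukey.condition_a != "x") & (res.tukey.condition_b != "x")]
        assert inv["p_adjusted"].max() < rest["p_adjusted"].min()

    def test_f_matches_partitioned_sums_of_squares_and_pingouin(self):
        rng = np.random.default_rng(10)
        arr = rng.normal(size=(7, 3)) + np.array([0.0, 0.5, 1.0])
        res = rm_anova_tukey(arr)
        import pingouin as pg

        df = pd.DataFrame(
            {
                "y": arr.ravel(),
                "cond": np.tile(np.arange(3), 7),
                "subj": np.repeat(np.arange(7), 3),
            }
        )
        aov = pg.rm_anova(dv="y", within="cond", subject="subj", data=df)
        assert res.F == pytest.approx(float(aov["F"].iloc[0]))
        assert res.p == pytest.approx(float(aov["p_unc"].iloc[0]))

    def test_fewer_than_three_subjects_rejected(self):
        with pytest.raises(ValueError, match="three"):
            rm_anova_tukey(np.ones((2, 4)))


def make_cohort_table(rng, slope=0.0, n_cases=19, noise=30.0, subj_sd=50.0):
    rows = []
    for i in range(n_cases):
        age = rng.integers(64, 89)
        sex = "M" if rng.uniform() < 0.7 else "F"
        u = rng.normal(0, subj_sd)
        for r in ("frontal", "temporal", "parietal", "occipital"):
            iron = rng.gamma(4.0, 50.0)
            gfap = 150.0 + slope * iron + u + rng.normal(0, noise)
            rows.append((f"c{i:02d}", r, iron, gfap, age, sex))
    return pd.DataFrame(
        rows, columns=["case_id", "region", "iron_density", "gfap_density", "age", "sex"]
    )


class TestMixedModels:
    def test_exact_linear_response_recovers_slope(self):
        rng = np.random.default_rng(11)
        df = make_cohort_table(rng, slope=0.0, noise=1.0, subj_sd=0.0)
        df["gfap_density"] = 5.0 + 0.25 * df["iron_density"]
        res = lme_compare(df, "gfap_density", filter_influence=False)
        assert res.iron_slope == pytest.approx(0.25, rel=1e-4)

    def test_planted_slope_detected_and_full_model_preferred(self):
        rng = np.random.default_rng(12)
        hits = 0
        for _ in range(10):
            df = make_cohort_table(rng, slope=0.8)
            res = lme_compare(df, "gfap_density", filter_influence=False)
            if res.lrt_p < 0.05 and res.aic_full < res.aic_null:
                hits += 1
        assert hits >= 9

    def test_loglikelihood_nondecreasing_with_added_fixed_effect(self):
        rng = np.random.default_rng(13)
        df = make_cohort_table(rng, slope=0.0)
        res = lme_compare(df, "gfap_density", filter_influence=False)
        assert res.loglik_full >= res.loglik_null - 1e-6
        assert res.lrt_df == 1

    def test_interval_brackets_estimate(self):
        rng = np.random.default_rng(14)
        df = make_cohort_table(rng, slope=0.5)
        res = lme_compare(df, "gfap_density", filter_influence=False)
        lo, hi = res.iron_slope_ci
        assert lo < res.iron_slope < hi
        assert 0.0 <= res.marginal_r2 <= res.conditional_r2 <= 1.0


class TestInfluenceFilter:
    def test_planted_outlier_subject_is_removed(self):
        rng = np.random.default_rng(15)
        df = make_cohort_table(rng, slope=0.3)
        df.loc[df.case_id == "c04", "gfap_density"] *= 20.0
        filtered, removed, dist = influence_filter(df, "gfap_density")
        assert "c04" in removed
        assert dist["c04"] > 4.0 / 19

    def test_homogeneous_cohort_keeps_most_subjects(self):
        rng = np.random.default_rng(16)
        df = make_cohort_table(rng, slope=0.0, noise=20.0, subj_sd=10.0)
        _, removed, _ = influence_filter(df, "gfap_density")
        assert len(removed) <= 2

    def test_threshold_is_four_over_n(self):
        rng = np.random.default_rng(17)
        df = make_cohort_table(rng, n_cases=20)
        _, removed, dist = influence_filter(df, "gfap_density")
        for subj, d in dist.items():
            assert (subj in removed) == (d > 0.2)
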