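"""Distribution tests, effect sizes, Monte-Carlo intervals, Bayes factor."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sst

import speechsync as ss


# ---------------------------------------------------------------------------
# brute-force oracles

def brute_ks_one_sample(x):
    """O(n^2)-spirit sup over all empirical jump points vs Phi."""
    x = np.sort(x)
    n = len(x)
    d = 0.0
    for i, xi in enumerate(x):
        cdf = sst.norm.cdf(xi)
        d = max(d, abs((i + 1) / n - cdf), abs(i / n - cdf))
    return d


def brute_ks_two_sample(x, y):
    pts = np.concatenate([x, y])
    d = 0.0
    for p in pts:
        d = max(d, abs(np.mean(x <= p) - np.mean(y <= p)))
    return d


def brute_fisher_p(table):
    """Two-sided Fisher p by hypergeometric enumeration."""
    a, b = table[0]
    c, d = table[1]
    row1, col1, n = a + b, a + c, a + b + c + d
    rv = sst.hypergeom(n, row1, col1)
    p_obs = rv.pmf(a)
    ks = np.arange(max(0, col1 - (n - row1)), min(row1, col1) + 1)
    pmfs = rv.pmf(ks)
    return float(pmfs[pmfs <= p_obs * (1 + 1e-9)].sum())


def brute_mwu_exact_p(x, y):
    """Exact two-sided p by enumerating group assignments, with U counted
    by direct pairwise comparison (independent of rank computation)."""
    def u_of(a, b):
        u = 0.0
        for ai in a:
            for bj in b:
                u += 1.0 if ai > bj else (0.5 if ai == bj else 0.0)
        return u

    pooled = np.concatenate([x, y])
    n1 = len(x)
    center = n1 * len(y) / 2.0
    dev = abs(u_of(x, y) - center)
    total = extreme = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        sel = np.zeros(len(pooled), dtype=bool)
        sel[list(idx)] = True
        total += 1
        if abs(u_of(pooled[sel], pooled[~sel]) - center) >= dev - 1e-12:
            extreme += 1
    return extreme / total


# ---------------------------------------------------------------------------

class TestKS:
    def test_single_point_at_zero(self):
        res = ss.ks_one_sample([0.0])
        assert res.d_stat == pytest.approx(0.5)

    def test_large_normal_sample_small_d(self):
        rng = np.random.default_rng(0)
        res = ss.ks_one_sample(rng.standard_normal(5000))
        assert res.d_stat < 0.03
        assert res.p_value > 0.01

    @pytest.mark.parametrize("seed", range(10))
    def test_one_sample_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2), rng.integers(5, 80))
        assert ss.ks_one_sample(x).d_stat == pytest.approx(brute_ks_one_sample(x),
                                                           abs=1e-12)

    def test_two_sample_identical_and_disjoint(self):
        x = np.array([1.0, 2.0, 3.0])
        assert ss.ks_two_sample(x, x).d_stat == 0.0
        assert ss.ks_two_sample([1.0, 2.0], [3.0, 4.0]).d_stat == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_two_sample_matches_brute_force(self, seed):
        rng = np.random.default_rng(100 + seed)
        x = rng.normal(0, 1, rng.integers(4, 60))
        y = rng.normal(0.3, 1.2, rng.integers(4, 60))
        assert ss.ks_two_sample(x, y).d_stat == pytest.approx(
            brute_ks_two_sample(x, y), abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ss.ks_one_sample([])
        with pytest.raises(ValueError):
            ss.ks_two_sample([], [1.0])

    def test_lilliefors_variant_standardizes(self):
        rng = np.random.default_rng(1)
        x = rng.normal(50.0, 5.0, 200)  # far from N(0,1) raw
        raw = ss.ks_one_sample(x)
        lill = ss.ks_one_sample(x, standardize=True)
        assert raw.d_stat > 0.9
        assert lill.d_stat < 0.1


class TestMonteCarloCI:
    def test_percentile_definition(self):
        n_sim = 1000
        lo, hi = ss.mc_confidence_interval(lambda rng: rng.standard_normal(),
                                           n_sim=n_sim, level=0.95, seed=0)
        rng = np.random.default_rng(0)
        vals = np.sort([rng.standard_normal() for _ in range(n_sim)])
        assert np.sum(vals < lo) == math.floor(0.025 * n_sim)
        assert np.sum(vals > hi) == math.floor(0.025 * n_sim)

    def test_constant_statistic_zero_width(self):
        lo, hi = ss.mc_confidence_interval(lambda rng: 1.7, n_sim=500, seed=0)
        assert lo == hi == 1.7

    def test_seed_reproducible_and_widens_with_level(self):
        a = ss.mc_confidence_interval(lambda r: r.standard_normal(), 2000, 0.95, 7)
        b = ss.mc_confidence_interval(lambda r: r.standard_normal(), 2000, 0.95, 7)
        assert a == b
        wide = ss.mc_confidence_interval(lambda r: r.standard_normal(), 2000, 0.99, 7)
        assert wide[0] <= a[0] and wide[1] >= a[1]

    def test_small_n_sim_warns(self):
        with pytest.warns(UserWarning):
            ss.mc_confidence_interval(lambda r: 0.0, n_sim=50, seed=0)


class TestMannWhitney:
    def test_disjoint_groups_exact(self):
        res = ss.mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.u_stat == 0.0
        assert res.p_value == pytest.approx(0.1)
        assert res.rank_biserial_r == pytest.approx(1.0)
        assert res.method == "exact_enumeration"

    def test_identical_groups_zero_effect(self):
        res = ss.mann_whitney([1.0, 2.0, 5.0], [1.0, 2.0, 5.0])
        assert res.rank_biserial_r == pytest.approx(0.0)

    def test_exact_matches_permutation_oracle(self):
        rng = np.random.default_rng(5)
        for n1 in range(2, 6):
            for n2 in range(2, 6):
                x = np.round(rng.normal(0, 1, n1), 1)  # rounding creates ties
                y = np.round(rng.normal(0.5, 1, n2), 1)
                assert ss.mann_whitney(x, y).p_value == pytest.approx(
                    brute_mwu_exact_p(x, y), abs=1e-12)

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(2)
        res = ss.mann_whitney(rng.normal(0, 1, 30), rng.normal(0, 1, 30))
        assert res.method == "normal_approx_tie_corrected"
        assert 0.0 <= res.p_value <= 1.0

    def test_type_one_error_calibrated(self):
        """Rejection rate at alpha=.05 under the null stays near nominal."""
        rng = np.random.default_rng(99)
        rejections = 0
        n_rep = 2000
        for _ in range(n_rep):
            x = rng.standard_normal(20)
            y = rng.standard_normal(20)
            if ss.mann_whitney(x, y).p_value < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_rep <= 0.07

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            ss.mann_whitney([], [1.0])


class TestFisher:
    def test_balanced_table_is_null(self):
        res = ss.fisher_exact([[1, 1], [1, 1]])
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_perfect_association(self):
        res = ss.fisher_exact([[5, 0], [0, 5]])
        assert res.p_value == pytest.approx(2 / 252)

    @pytest.mark.parametrize("seed", range(10))
    def test_p_matches_hypergeometric_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.integers(1, 25, size=(2, 2))
        assert ss.fisher_exact(t).p_value == pytest.approx(brute_fisher_p(t),
                                                           abs=1e-10)

    def test_zero_cell_warns_and_degenerates(self):
        with pytest.warns(UserWarning, match="zero cell"):
            res = ss.fisher_exact([[5, 0], [3, 4]])
        assert res.odds_ratio == math.inf

    def test_sex_group_orientation(self):
        """OR reads as male-vs-female odds of being a high synchronizer."""
        labels = ["high"] * 25 + ["low"] * 36
        sexes = ["male"] * 14 + ["female"] * 11 + ["male"] * 5 + ["female"] * 31
        res = ss.fisher_exact(ss.sex_group_table(labels, sexes))
        assert res.odds_ratio == pytest.approx(14 * 31 / (11 * 5))


class TestSpearman:
    def test_monotone_pairs(self):
        x = np.arange(10.0)
        assert ss.spearman(x, np.exp(x)).rho == pytest.approx(1.0)
        assert ss.spearman(x, -x).rho == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_pearson_on_ranks(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 60))
        x = np.round(rng.normal(size=n), 1)
        y = np.round(0.5 * x + rng.normal(size=n), 1)
        expected = np.corrcoef(sst.rankdata(x), sst.rankdata(y))[0, 1]
        assert ss.spearman(x, y).rho == pytest.approx(expected, abs=1e-12)

    def test_ci_contains_point_estimate(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=50)
        res = ss.spearman(x, x + rng.normal(size=50))
        assert res.ci[0] <= res.rho <= res.ci[1]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ss.spearman([1, 2, 3], [1, 2])


class TestBayesFactor:
    def test_null_data_favors_null(self):
        rng = np.random.default_rng(0)
        count = 0
        for _ in range(20):
            bf = ss.bayes_factor_ttest(rng.standard_normal(100),
                                       rng.standard_normal(100))
            count += bf.bf01 > 1.0
        assert count >= 18  # evidence for the null in nearly every replicate

    def test_separated_samples_favor_alternative(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(50)
        y = rng.standard_normal(50) + 3.0
        assert ss.bayes_factor_ttest(x, y).bf01 < 0.1

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        x, y = rng.standard_normal(40), rng.standard_normal(45) + 0.3
        assert ss.bayes_factor_ttest(x, y).bf01 == pytest.approx(
            ss.bayes_factor_ttest(y, x).bf01, rel=1e-9)

    def test_matches_reference_jzs(self):
        """Cross-check against pingouin's closed-form JZS Bayes factor."""
        import pingouin as pg
        rng = np.random.default_rng(7)
        x = rng.normal(0.0, 1.0, 60)
        y = rng.normal(0.4, 1.0, 60)
        mine = ss.bayes_factor_ttest(x, y)
        t_pooled = sst.ttest_ind(x, y).statistic
        ref_bf10 = float(pg.bayesfactor_ttest(t_pooled, 60, 60))
        assert 1.0 / mine.bf01 == pytest.approx(ref_bf10, rel=0.05)

    def test_posterior_summaries_reasonable(self):
        rng = np.random.default_rng(3)
        bf = ss.bayes_factor_ttest(rng.standard_normal(80),
                                   rng.standard_normal(80) - 0.5)
        assert bf.credible_interval[0] < bf.posterior_mean < bf.credible_interval[1]
        assert bf.posterior_mean > 0  # x tends larger


class TestBattery:
    def make_cohort(self, seed, n=200, rho=0.2):
        df = ss.simulate_cohort(ss.CohortSimSpec(n=n, seed=seed, music_plv_rho=rho))
        df["label"] = df["plv_true_group"]
        return df

    def test_null_covariates_show_no_effects(self):
        """With no group differences injected, rank-biserial effects stay small."""
        max_r = 0.0
        for seed in range(20):
            df = ss.simulate_cohort(ss.CohortSimSpec(
                n=200, seed=seed, music_plv_rho=0.0,
                sex_probs_by_group={"low": 0.5, "high": 0.5}))
            df["label"] = df["plv_true_group"]
            # erase group-dependent age structure for the null check
            rng = np.random.default_rng(seed)
            df["age"] = np.clip(np.round(rng.normal(25, 5, len(df))), 19, 70)
            rep = ss.run_group_comparisons(df)
            for key in ("mwu_age", "mwu_edu_years"):
                max_r = max(max_r, abs(rep["combined"][key].rank_biserial_r))
        assert max_r < 0.2

    def test_copula_correlation_recovered(self):
        df = ss.simulate_cohort(ss.CohortSimSpec(n=500, seed=12, music_plv_rho=0.3))
        res = ss.spearman(df["plv"], df["music_years"])
        assert res.rho == pytest.approx(0.3, abs=0.1)

    def test_full_report_structure(self):
        df1 = self.make_cohort(seed=1)
        df2 = self.make_cohort(seed=2)
        df2["cohort"] = "swedish"
        both = __import__("pandas").concat([df1, df2], ignore_index=True)
        rep = ss.run_group_comparisons(both)
        assert set(rep["per_cohort"]) == {"english", "swedish"}
        assert "ks_two_sample" in rep["between_cohorts"]
        assert rep["between_cohorts"]["bayes_factor"].bf01 > 0
        assert set(rep["combined"]["ks_by_sex"]) == {"female", "male"}

    def test_missing_column_recorded_not_fatal(self):
        df = self.make_cohort(seed=3).drop(columns=["age"])
        rep = ss.run_group_comparisons(df)
        assert any("mwu_age" in k for k in rep["errors"])
        assert "mwu_edu_years" in rep["combined"]

    def test_empty_cohort_rejected(self):
        import pandas as pd
        with pytest.raises(ValueError):
            ss.run_group_comparisons(pd.DataFrame(columns=["plv"]))
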