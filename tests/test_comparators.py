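"""Comparator tests: TATES, Tippett, FC, MANOVA, MultiPhen, SUMSCORE."""

import warnings

import numpy as np
import pytest
from scipy import stats

from afcomb import comparators as cmp
from afcomb.core import (null_reference_from_pvalues, partial_log_sums,
                         permutation_draws, rank_transfer)
from afcomb.scenarios import ScenarioConfig, generate_scenario_batch
from afcomb.univariate import univariate_pvalues
from conftest import manual_draws


class TestEffectiveNumber:
    def test_identity_gives_K(self):
        assert cmp.effective_number(np.eye(7)) == pytest.approx(7.0)

    def test_all_ones_gives_one(self):
        assert cmp.effective_number(np.ones((5, 5))) == pytest.approx(1.0)

    def test_profile_bounds_and_monotone(self):
        rng = np.random.default_rng(0)
        A = rng.standard_normal((30, 9))
        R = np.corrcoef(A, rowvar=False)
        prof = cmp.effective_number_profile(R, np.arange(9))
        ks = np.arange(1, 10)
        assert np.all(prof >= 1.0 - 1e-9) and np.all(prof <= ks + 1e-9)
        assert np.all(np.diff(prof) >= -1e-9)
        assert prof[-1] == pytest.approx(cmp.effective_number(R))


class TestTates:
    def test_independence_is_simes_form(self):
        """With R = I, p_TATES = min_j (K/j) p_(j)."""
        p = np.array([0.01, 0.5])
        assert cmp.tates(p, np.eye(2)) == pytest.approx(min(0.02, 0.5))
        p = np.array([0.3, 0.04, 0.9, 0.11])
        ordered = np.sort(p)
        expected = np.min(4 * ordered / np.arange(1, 5))
        assert cmp.tates(p, np.eye(4)) == pytest.approx(expected)

    def test_single_phenotype_identity(self):
        assert cmp.tates(np.array([0.23]), np.eye(1)) == pytest.approx(0.23)

    def test_perfect_correlation_returns_min_p(self):
        p = np.array([0.07, 0.3, 0.6])
        assert cmp.tates(p, np.ones((3, 3))) == pytest.approx(0.07)

    def test_never_exceeds_me_times_minp(self):
        rng = np.random.default_rng(1)
        A = rng.standard_normal((50, 6))
        R = np.corrcoef(A, rowvar=False)
        p = rng.uniform(size=6)
        out = cmp.tates(p, R)
        assert out <= min(1.0, cmp.effective_number(R) * p.min()) + 1e-12

    def test_non_psd_rejected(self):
        R = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError):
            cmp.tates(np.array([0.1, 0.2]), R)


class TestPermutationComparators:
    def test_tippett_sidak_limit_under_independence(self):
        """The permutation p of min-p converges to 1 - (1 - p_min)^K when
        phenotypes are independent."""
        rng = np.random.default_rng(2)
        n, K, B = 2000, 5, 4000
        x = rng.binomial(2, 0.3, n).astype(float)
        Y = rng.standard_normal((n, K))
        d = permutation_draws(Y, x, B, rng=rng)
        p_min = d.p_obs.min()
        sidak = 1 - (1 - p_min) ** K
        got = cmp.tippett_test(draws=d)
        assert got == pytest.approx(sidak, abs=4 * np.sqrt(sidak / B) + 0.01)

    def test_fc_chi2_limit_under_independence(self):
        """Fisher statistic -2 sum(ln p) is chi2 with 2K df under
        independence; the permutation p matches its upper tail."""
        assert cmp.fisher_statistic([0.05, 0.05]) == pytest.approx(
            -4 * np.log(0.05), abs=1e-9)
        assert cmp.fisher_statistic([0.05, 0.05]) == pytest.approx(11.983, abs=1e-3)
        rng = np.random.default_rng(3)
        n, K, B = 2000, 4, 4000
        x = rng.binomial(2, 0.3, n).astype(float)
        Y = rng.standard_normal((n, K))
        d = permutation_draws(Y, x, B, rng=rng)
        chi2_tail = stats.chi2.sf(cmp.fisher_statistic(d.p_obs), 2 * K)
        got = cmp.fc_test(draws=d)
        assert got == pytest.approx(chi2_tail,
                                    abs=4 * np.sqrt(chi2_tail / B) + 0.01)

    def test_degenerate_pvalues(self):
        assert cmp.tippett_statistic([1.0, 1.0]) == 1.0
        assert cmp.fisher_statistic([1.0, 1.0, 1.0]) == 0.0

    def test_fc_statistic_equals_minus_two_TK(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=8)
        assert cmp.fisher_statistic(p) == pytest.approx(
            -2 * partial_log_sums(p)[-1])

    def test_reductions_to_transferred_T1_and_TK(self, small_dataset):
        """On shared shuffles, Tippett's permutation p equals the
        rank-transferred p of T_1 and FC's equals that of T_K, exactly."""
        Y, x = small_dataset
        d = permutation_draws(Y, x, 500, rng=5)
        ref = null_reference_from_pvalues(d.null_P)
        perk = rank_transfer(partial_log_sums(d.p_obs), ref)
        assert cmp.tippett_test(draws=d) == perk[0]
        assert cmp.fc_test(draws=d) == perk[-1]

    def test_sumscore_symmetric_in_phenotype_order(self, small_dataset):
        Y, x = small_dataset
        d = manual_draws(Y, x, 50, seed=6)
        perm = np.random.default_rng(7).permutation(Y.shape[1])
        d2 = type(d)(n=d.n, r_obs=d.r_obs[perm], null_r=d.null_r[:, perm])
        assert cmp.sumscore_test(draws=d) == cmp.sumscore_test(draws=d2)

    def test_sumscore_k1_two_sided_permutation_p(self):
        rng = np.random.default_rng(8)
        n, B = 80, 300
        x = rng.binomial(2, 0.3, n).astype(float)
        Y = (0.2 * x + rng.standard_normal(n))[:, None]
        d = manual_draws(Y, x, B, seed=9)
        obs = abs(d.scores_obs.sum())
        expected = (1 + np.sum(np.abs(d.null_scores.sum(1)) >= obs)) / (B + 1)
        assert cmp.sumscore_test(draws=d) == expected

    def test_sumscore_sign_cancellation(self):
        """Aligned effects across phenotypes give more power than effects
        with half the signs flipped."""
        rng = np.random.default_rng(10)
        n, K, B, reps, beta = 300, 4, 200, 300, 0.25
        rej_same = rej_flip = 0
        for _ in range(reps):
            x = rng.binomial(2, 0.3, n).astype(float)
            E = rng.standard_normal((n, K))
            Y_same = E + beta * x[:, None]
            signs = np.array([1.0, 1.0, -1.0, -1.0])
            Y_flip = E + beta * x[:, None] * signs
            d1 = permutation_draws(Y_same, x, B, rng=rng)
            d2 = permutation_draws(Y_flip, x, B, rng=rng)
            rej_same += cmp.sumscore_test(draws=d1) <= 0.05
            rej_flip += cmp.sumscore_test(draws=d2) <= 0.05
        assert rej_same > rej_flip + 3 * np.sqrt(reps * 0.25)


class TestManova:
    def test_k1_equals_univariate_f_test(self):
        """At K=1, Lambda = 1/(1 + t^2/(n-2)) and the exact-F version of the
        test reproduces the univariate regression p-value."""
        rng = np.random.default_rng(11)
        n = 200
        x = rng.binomial(2, 0.3, n).astype(float)
        y = 0.2 * x + rng.standard_normal(n)
        lam = cmp.wilks_lambda(y[:, None], x)
        r = np.corrcoef(y, x)[0, 1]
        t2 = r**2 * (n - 2) / (1 - r**2)
        assert lam == pytest.approx(1 / (1 + t2 / (n - 2)), rel=1e-10)
        p_uni = univariate_pvalues(y[:, None], x)[0]
        assert cmp.manova_wilks(y[:, None], x, stat="rao") == pytest.approx(
            p_uni, rel=1e-9)
        # chi-square variants agree asymptotically
        assert cmp.manova_wilks(y[:, None], x) == pytest.approx(p_uni, abs=0.01)
        assert cmp.manova_wilks(y[:, None], x, stat="plain") == pytest.approx(
            p_uni, abs=0.01)

    def test_null_uniformity(self):
        rng = np.random.default_rng(12)
        n, K = 150, 5
        pv = []
        for _ in range(1500):
            x = rng.binomial(2, 0.3, n).astype(float)
            pv.append(cmp.manova_wilks(rng.standard_normal((n, K)), x))
        assert stats.kstest(pv, "uniform").pvalue > 0.01

    def test_duplicated_column_raises(self):
        rng = np.random.default_rng(13)
        Y = rng.standard_normal((60, 2))
        Y = np.column_stack([Y, Y[:, 0]])
        with pytest.raises(np.linalg.LinAlgError):
            cmp.manova_wilks(Y, rng.binomial(2, 0.3, 60).astype(float))


class TestMultiphen:
    def test_loglik_matches_statsmodels(self):
        """The fast proportional-odds fit agrees with statsmodels'
        OrderedModel maximum likelihood."""
        from statsmodels.miscmodels.ordinal_model import OrderedModel
        rng = np.random.default_rng(14)
        n, K = 400, 6
        Y = rng.standard_normal((n, K))
        x = rng.binomial(2, 0.3, n)
        Y[:, 0] += 0.15 * x
        Yc = Y - Y.mean(0)
        _, codes = np.unique(x, return_inverse=True)
        res = cmp._fit_prop_odds(Yc, codes, 3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sm_llf = OrderedModel(x, Yc, distr="logit").fit(
                method="bfgs", disp=0).llf
        assert -res.fun == pytest.approx(sm_llf, abs=1e-5)

    def test_null_uniformity(self):
        rng = np.random.default_rng(15)
        n, K = 250, 4
        pv = []
        for _ in range(1200):
            x = rng.binomial(2, 0.3, n).astype(float)
            pv.append(cmp.multiphen(rng.standard_normal((n, K)), x))
        assert stats.kstest(pv, "uniform").pvalue > 0.01

    def test_k1_calibration_tracks_linear_regression(self):
        """Both tests of the same independence null reject at similar rates;
        their p-values correlate strongly at large n."""
        rng = np.random.default_rng(16)
        n = 3000
        p_lin, p_ord = [], []
        for _ in range(200):
            x = rng.binomial(2, 0.3, n).astype(float)
            y = rng.standard_normal((n, 1))
            p_lin.append(univariate_pvalues(y, x)[0])
            p_ord.append(cmp.multiphen(y, x))
        p_lin, p_ord = np.array(p_lin), np.array(p_ord)
        assert np.corrcoef(p_lin, p_ord)[0, 1] > 0.85
        assert abs((p_ord <= 0.1).mean() - (p_lin <= 0.1).mean()) < 0.08

    def test_power_monotone_in_effect_size(self):
        """Average p-value decreases as the genetic effect grows."""
        rng = np.random.default_rng(17)
        n, K, reps = 400, 4, 120
        means = []
        for beta in (0.0, 0.2, 0.4):
            pv = []
            for _ in range(reps):
                x = rng.binomial(2, 0.3, n).astype(float)
                Y = rng.standard_normal((n, K))
                Y[:, 0] += beta * x
                pv.append(cmp.multiphen(Y, x))
            means.append(np.mean(pv))
        assert means[0] > means[1] > means[2]

    def test_two_genotype_classes_fall_back_to_logistic(self):
        rng = np.random.default_rng(18)
        n = 200
        x = rng.binomial(1, 0.3, n).astype(float)  # no homozygous-alt class
        Y = rng.standard_normal((n, 3))
        with pytest.warns(RuntimeWarning, match="binary"):
            p = cmp.multiphen(Y, x)
        assert 0.0 < p <= 1.0

    def test_monomorphic_raises(self):
        rng = np.random.default_rng(19)
        with pytest.raises(ValueError):
            cmp.multiphen(rng.standard_normal((50, 2)), np.zeros(50))


def test_permutation_methods_bit_reproducible(small_dataset):
    Y, x = small_dataset
    a = cmp.tippett_test(Y, x, B=100, rng=20)
    b = cmp.tippett_test(Y, x, B=100, rng=20)
    assert a == b
    assert cmp.sumscore_test(Y, x, B=100, rng=21) == \
        cmp.sumscore_test(Y, x, B=100, rng=21)
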