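"""Robust statistics, Freedman-Lane permutation, max-stat FWER, BH FDR."""

import itertools

import numpy as np
import pytest
from scipy import stats

import megasite as ms
from megasite.errors import ConfigurationError, DataError, EstimationError


def two_sample_design(groups):
    g = np.asarray(groups, dtype=float)
    M = np.column_stack([np.ones(len(g)), g - 0.5])
    return M, np.array([0.0, 1.0])


class TestRobustStatistic:
    def test_single_group_equals_hand_computed_pooled_t(self):
        # printed 8-value toy set, group A = (1, 3, 2, 5), B = (0.5, 2.5, 1.5, 4)
        y = np.array([1.0, 3.0, 2.0, 5.0, 0.5, 2.5, 1.5, 4.0])
        g = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        # hand computation: means 2.75 / 2.125, pooled var
        ma, mb = 2.75, 2.125
        ssa = (1 - ma) ** 2 + (3 - ma) ** 2 + (2 - ma) ** 2 + (5 - ma) ** 2
        ssb = (0.5 - mb) ** 2 + (2.5 - mb) ** 2 + (1.5 - mb) ** 2 + (4 - mb) ** 2
        sp2 = (ssa + ssb) / 6
        t_hand = (ma - mb) / np.sqrt(sp2 * (1 / 4 + 1 / 4))
        M, C = two_sample_design(g)
        assert ms.robust_statistic(y, M, C) == pytest.approx(t_hand, abs=1e-10)
        assert t_hand == pytest.approx(
            stats.ttest_ind(y[g == 1], y[g == 0]).statistic
        )

    def test_two_groups_matches_scipy_welch(self):
        rng = np.random.default_rng(0)
        y = np.concatenate([rng.normal(0, 1, 12), rng.normal(0.5, 3, 18)])
        g = np.repeat([0, 1], [12, 18])
        M, C = two_sample_design(g)
        v = ms.robust_statistic(y, M, C, variance_groups=g)
        welch = stats.ttest_ind(y[g == 1], y[g == 0], equal_var=False).statistic
        assert v == pytest.approx(welch, abs=1e-10)

    def test_equal_sizes_equal_variances_reduce_to_pooled_t(self):
        y = np.array([1.0, 2.0, 3.0, 4.0, 2.0, 3.0, 4.0, 5.0])
        g = np.repeat([0, 1], 4)  # equal n and equal sample variances
        M, C = two_sample_design(g)
        v = ms.robust_statistic(y, M, C, variance_groups=g)
        t = ms.robust_statistic(y, M, C)
        assert v == pytest.approx(t, abs=1e-12)

    def test_single_group_multicolumn_contrast_equals_classical_f(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        n = 40
        X = rng.normal(size=(n, 2))
        y = 0.4 * X[:, 0] + rng.normal(size=n)
        M = np.column_stack([np.ones(n), X])
        C = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        G = ms.robust_statistic(y, M, C)
        f_sm = float(sm.OLS(y, M).fit().f_test("x1 = 0, x2 = 0").fvalue)
        assert G == pytest.approx(f_sm, abs=1e-8)

    def test_zero_residual_dof_group_rejected(self):
        # a singleton site with its own intercept column is fitted exactly,
        # leaving that variance group no residual degrees of freedom
        y = np.arange(5, dtype=float)
        site = np.array([0, 0, 0, 0, 1])
        M = np.column_stack([(site == 0).astype(float),
                             (site == 1).astype(float)])
        C = np.array([1.0, -1.0])
        with pytest.raises(EstimationError):
            ms.robust_statistic(y, M, C, variance_groups=site)


class TestPermutationTest:
    def test_p_never_below_one_over_nperm_plus_one(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=20) + np.repeat([0, 5], 10)  # huge effect
        M, C = two_sample_design(np.repeat([0, 1], 10))
        scheme = ms.PermutationScheme(n_perm=99, seed=0)
        res = ms.permutation_test(y, M, C, scheme)
        assert res.p_unc[0] >= 1 / 100 - 1e-12
        assert res.p_unc[0] <= 3 / 100  # huge effect: only ties can exceed it

    def test_exhaustive_two_blocks_matches_brute_force(self):
        # 8 subjects, 2 blocks of 4: all 4!*4! = 576 rearrangements
        y = np.array([0.8, 2.1, -0.3, 1.4, 3.0, 1.1, 2.6, 0.2])
        g = np.array([0, 0, 1, 1, 0, 0, 1, 1])
        blocks = np.repeat(["a", "b"], 4)
        M, C = two_sample_design(g)
        scheme = ms.PermutationScheme(n_perm=1, blocks=blocks, exhaustive=True)
        res = ms.permutation_test(y, M, C, scheme)
        assert res.exhaustive and res.null.shape[0] == 576

        # independent oracle: permute y within blocks, pooled t via scipy
        t_obs = abs(stats.ttest_ind(y[g == 1], y[g == 0]).statistic)
        count = 0
        for pa in itertools.permutations(range(4)):
            for pb in itertools.permutations(range(4, 8)):
                yp = y[np.array(pa + pb)]
                t = abs(stats.ttest_ind(yp[g == 1], yp[g == 0]).statistic)
                count += t >= t_obs - 1e-12
        assert res.p_unc[0] == pytest.approx(count / 576, abs=1e-12)

    def test_null_rejection_rate_is_calibrated(self):
        # exactness: ~5% rejections at alpha=0.05 under the null
        rej = tot = 0
        M, C = two_sample_design(np.tile([0, 1], 15))
        blocks = np.repeat(["a", "b"], 15)
        for rep in range(100):
            rng = np.random.default_rng(100 + rep)
            Y = rng.normal(size=(30, 5))
            scheme = ms.PermutationScheme(n_perm=250, blocks=blocks, seed=rep)
            res = ms.permutation_test(Y, M, C, scheme)
            rej += (res.p_unc < 0.05).sum()
            tot += 5
        assert 0.03 <= rej / tot <= 0.07

    def test_block_relabeling_leaves_pvalues_unchanged(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=16)
        M, C = two_sample_design(np.tile([0, 1], 8))
        a = ms.PermutationScheme(n_perm=200, seed=1,
                                 blocks=np.repeat(["x", "y"], 8))
        b = ms.PermutationScheme(n_perm=200, seed=1,
                                 blocks=np.repeat(["y", "x"], 8))
        pa = ms.permutation_test(y, M, C, a).p_unc
        pb = ms.permutation_test(y, M, C, b).p_unc
        assert np.array_equal(pa, pb)

    def test_element_order_invariance(self):
        rng = np.random.default_rng(4)
        Y = rng.normal(size=(24, 6))
        M, C = two_sample_design(np.tile([0, 1], 12))
        scheme = ms.PermutationScheme(n_perm=100, seed=2)
        res = ms.permutation_test(Y, M, C, scheme)
        perm = np.array([3, 1, 5, 0, 2, 4])
        res_p = ms.permutation_test(Y[:, perm], M, C, scheme)
        assert np.allclose(res_p.stat, res.stat[perm])
        assert np.allclose(res_p.p_unc, res.p_unc[perm])

    def test_seeded_stream_reproducible(self):
        rng = np.random.default_rng(5)
        Y = rng.normal(size=(20, 3))
        M, C = two_sample_design(np.tile([0, 1], 10))
        scheme = ms.PermutationScheme(n_perm=100, seed=7)
        a = ms.permutation_test(Y, M, C, scheme)
        b = ms.permutation_test(Y, M, C, scheme)
        assert np.array_equal(a.null, b.null)

    def test_invalid_configurations_rejected(self):
        with pytest.raises(ConfigurationError):
            ms.PermutationScheme(n_perm=0)
        y = np.zeros(6)
        M, C = two_sample_design(np.tile([0, 1], 3))
        scheme = ms.PermutationScheme(n_perm=10, blocks=np.array(["a"] * 5))
        with pytest.raises(DataError):
            ms.permutation_test(y, M, C, scheme)


class TestFwerMaxstat:
    def test_single_element_single_family_equals_uncorrected(self):
        rng = np.random.default_rng(6)
        y = rng.normal(size=20)
        M, C = two_sample_design(np.tile([0, 1], 10))
        res = ms.permutation_test(y, M, C, ms.PermutationScheme(n_perm=200,
                                                                seed=0))
        assert ms.fwer_maxstat([res])[0][0] == res.p_unc[0]

    def test_duplicated_element_does_not_change_correction(self):
        rng = np.random.default_rng(7)
        Y = rng.normal(size=(20, 4))
        Ydup = np.column_stack([Y, Y[:, 0]])
        M, C = two_sample_design(np.tile([0, 1], 10))
        scheme = ms.PermutationScheme(n_perm=150, seed=1)
        p1 = ms.fwer_maxstat([ms.permutation_test(Y, M, C, scheme)])[0]
        p2 = ms.fwer_maxstat([ms.permutation_test(Ydup, M, C, scheme)])[0]
        assert np.allclose(p1, p2[:4])

    def test_fwer_dominates_uncorrected(self):
        rng = np.random.default_rng(8)
        Y = rng.normal(size=(30, 8))
        M, C = two_sample_design(np.tile([0, 1], 15))
        res = ms.permutation_test(Y, M, C, ms.PermutationScheme(n_perm=100,
                                                                seed=2))
        assert (ms.fwer_maxstat([res])[0] >= res.p_unc - 1e-12).all()

    def test_less_conservative_than_bonferroni_on_correlated_elements(self):
        # shared signal across elements: max-stat exploits the dependence
        rng = np.random.default_rng(9)
        n, V = 40, 20
        shared = rng.normal(size=(n, 1))
        g = np.tile([0, 1], n // 2)
        Y = shared + 0.1 * rng.normal(size=(n, V)) + 0.9 * g[:, None]
        M, C = two_sample_design(g)
        res = ms.permutation_test(Y, M, C, ms.PermutationScheme(n_perm=500,
                                                                seed=3))
        p_max = ms.fwer_maxstat([res])[0]
        p_bonf = np.minimum(res.p_unc * V, 1.0)
        assert (p_max <= p_bonf + 1e-12).all()
        assert p_max.mean() < p_bonf.mean()

    def test_mismatched_schedules_rejected(self):
        rng = np.random.default_rng(10)
        Y = rng.normal(size=(20, 2))
        M, C = two_sample_design(np.tile([0, 1], 10))
        a = ms.permutation_test(Y, M, C, ms.PermutationScheme(n_perm=50, seed=0))
        b = ms.permutation_test(Y, M, C, ms.PermutationScheme(n_perm=50, seed=9))
        with pytest.raises(ConfigurationError):
            ms.fwer_maxstat([a, b])
        # separate pooling does not require a shared schedule
        out = ms.fwer_maxstat([a, b], pool="separate")
        assert len(out) == 2


class TestFdrBH:
    def test_equal_pvalues_unchanged(self):
        assert np.allclose(ms.fdr_bh([0.2, 0.2, 0.2]), 0.2)

    def test_hand_applied_step_up(self):
        # min over k of p_(k) * m / k with monotone enforcement
        adjusted = ms.fdr_bh([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adjusted, [0.04, 0.04, 0.04, 0.04])

    def test_single_pvalue_identity(self):
        assert ms.fdr_bh([0.17])[0] == pytest.approx(0.17)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(DataError):
            ms.fdr_bh([0.1, 0.0])
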