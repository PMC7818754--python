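"""Library-size normalization, the two-part hurdle test, Wilcoxon
alternative, BH adjustment and recall/precision scoring."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy import sparse, stats

from scbench import de


def _adata(X):
    X = np.asarray(X)
    return ad.AnnData(
        X=sparse.csr_matrix(X.astype(float)),
        obs=pd.DataFrame(index=[f"c{i}" for i in range(X.shape[0])]),
        var=pd.DataFrame(index=[f"g{i}" for i in range(X.shape[1])]),
    )


def _norm_np(M):
    tot = M.sum(axis=1, keepdims=True)
    return np.log2(M / tot * 1e4 + 1)


class TestNormalize:
    def test_formula_spot_check(self):
        adata = _adata([[10, 9990]])
        out = de.normalize(adata).X.toarray()
        assert out[0, 0] == pytest.approx(np.log2(10 / 10_000 * 1e4 + 1))

    def test_zeros_preserved(self):
        adata = _adata([[0, 5, 0, 5]])
        out = de.normalize(adata).X.toarray()
        assert out[0, 0] == 0 and out[0, 2] == 0

    def test_scale_invariance_per_cell(self):
        a = de.normalize(_adata([[3, 7, 0]])).X.toarray()
        b = de.normalize(_adata([[6, 14, 0]])).X.toarray()
        np.testing.assert_allclose(a, b)

    def test_zero_total_cell_dropped_with_warning(self):
        adata = _adata([[1, 2], [0, 0]])
        with pytest.warns(RuntimeWarning, match="zero-total"):
            out = de.normalize(adata)
        assert out.n_obs == 1


class TestHurdleTest:
    def test_identical_groups_give_p_one(self):
        A = np.tile([[0.0, 2.0, 3.0]], (5, 1))
        p = de.hurdle_test(A, A.copy())
        np.testing.assert_allclose(p, 1.0)

    def test_all_zero_gene_gives_p_one(self):
        rng = np.random.default_rng(0)
        A = np.column_stack([np.zeros(10), rng.random(10)])
        B = np.column_stack([np.zeros(10), rng.random(10)])
        p = de.hurdle_test(A, B)
        assert p[0] == 1.0

    def test_strong_separation_is_significant(self):
        A = np.zeros((199, 1))
        B = np.zeros((199, 1))
        A[:179, 0] = 3.0  # detected in 90%
        B[:20, 0] = 3.0  # detected in 10%
        p = de.hurdle_test(np.hstack([A, A]), np.hstack([B, B]))
        assert (p < 1e-4).all()

    def test_agrees_with_permutation_null_oracle(self):
        """A moderate-effect gene's chi-square p matches the label-permutation
        distribution of the same statistic within Monte-Carlo error."""
        rng = np.random.default_rng(1)
        nA = nB = 60
        a = np.where(rng.random(nA) < 0.55, rng.normal(2.2, 1.0, nA), 0.0)
        b = np.where(rng.random(nB) < 0.40, rng.normal(1.9, 1.0, nB), 0.0)
        a, b = np.abs(a), np.abs(b)
        p_obs = de.hurdle_test(
            np.column_stack([a, a]), np.column_stack([b, b])
        )[0]
        pooled = np.concatenate([a, b])
        n_shuffle = 4000
        stat_obs = stats.chi2.isf(p_obs, 2)
        hits = 0
        for _ in range(n_shuffle):
            perm = rng.permutation(pooled)
            pp = de.hurdle_test(
                np.column_stack([perm[:nA]] * 2),
                np.column_stack([perm[nA:]] * 2),
            )[0]
            if stats.chi2.isf(pp, 2) >= stat_obs:
                hits += 1
        p_perm = (hits + 1) / (n_shuffle + 1)
        mc_err = 3 * np.sqrt(p_perm * (1 - p_perm) / n_shuffle)
        assert abs(p_obs - p_perm) < max(mc_err, 0.02)

    def test_null_pvalues_near_uniform(self):
        rng = np.random.default_rng(2)
        lam = rng.lognormal(0, 1, 2000)
        A = _norm_np(rng.poisson(np.tile(lam, (199, 1))))
        B = _norm_np(rng.poisson(np.tile(lam, (199, 1))))
        p = de.hurdle_test(A, B)
        assert stats.kstest(p, "uniform").statistic < 0.05

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            de.hurdle_test(np.ones((1, 3)), np.ones((5, 3)))


class TestWilcoxonTest:
    def test_constant_groups_give_p_one(self):
        A = np.full((10, 2), 3.0)
        p = de.wilcoxon_test(A, A.copy())
        np.testing.assert_allclose(p, 1.0)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(3)
        A, B = rng.random((15, 4)), rng.random((12, 4))
        np.testing.assert_allclose(
            de.wilcoxon_test(A, B), de.wilcoxon_test(B, A)
        )

    def test_matches_exact_enumeration_at_small_n(self):
        # moderate shift (p ~ 1e-2), where the tie-corrected normal
        # approximation tracks the exact null enumeration closely
        rng = np.random.default_rng(3)
        A = rng.uniform(0, 1, (20, 1)) + 0.25
        B = rng.uniform(0, 1, (20, 1))
        p_asym = de.wilcoxon_test(A, B)[0]
        p_exact = stats.mannwhitneyu(
            A[:, 0], B[:, 0], alternative="two-sided", method="exact"
        ).pvalue
        assert p_asym == pytest.approx(p_exact, rel=0.2)

    def test_disjoint_supports_far_in_tail(self):
        rng = np.random.default_rng(14)
        A = rng.uniform(10, 11, (20, 1))
        B = rng.uniform(0, 1, (20, 1))
        assert de.wilcoxon_test(A, B)[0] < 1e-6


class TestBH:
    def test_closed_form_example(self):
        np.testing.assert_allclose(
            de.bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_p_unchanged(self):
        assert de.bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(5)
        p = rng.random(500)
        assert (de.bh_fdr(p) >= p - 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            de.bh_fdr([0.5, 1.2])


class TestSubsampleAndTest:
    def test_seeded_determinism(self):
        rng = np.random.default_rng(6)
        A = _norm_np(rng.poisson(3.0, (60, 100)) * 1.0)
        B = _norm_np(rng.poisson(3.0, (60, 100)) * 1.0)
        r1 = de.subsample_and_test(A, B, n=40, reps=3, seed=7)
        r2 = de.subsample_and_test(A, B, n=40, reps=3, seed=7)
        assert r1.counts == r2.counts

    def test_null_counts_near_zero(self):
        rng = np.random.default_rng(8)
        lam = rng.lognormal(0, 1, 400)
        A = _norm_np(rng.poisson(np.tile(lam, (80, 1))) * 1.0)
        B = _norm_np(rng.poisson(np.tile(lam, (80, 1))) * 1.0)
        out = de.subsample_and_test(A, B, n=60, reps=3, seed=9)
        assert out.mean_nde <= 1.0

    def test_small_group_capped_with_warning(self):
        rng = np.random.default_rng(10)
        A = rng.random((20, 10))
        B = rng.random((20, 10))
        with pytest.warns(RuntimeWarning, match="subsampling"):
            out = de.subsample_and_test(A, B, n=199, reps=2, seed=0)
        assert out.mean_nde >= 0

    def test_power_grows_with_sample_size(self):
        """Testing more cells finds at least as many DE genes as a small
        subsample on data with genuine differences."""
        rng = np.random.default_rng(11)
        lamA = rng.lognormal(0, 1, 300)
        lamB = lamA * np.where(rng.random(300) < 0.3, 3.0, 1.0)
        A = _norm_np(rng.poisson(np.tile(lamA, (250, 1))) * 1.0)
        B = _norm_np(rng.poisson(np.tile(lamB, (250, 1))) * 1.0)
        small = de.subsample_and_test(A, B, n=50, reps=3, seed=12)
        big = de.subsample_and_test(A, B, n=250, reps=1, seed=12)
        assert big.mean_nde > small.mean_nde


class TestBulkTruthAndScore:
    def test_confusion_matrix_formulas(self):
        genes = [f"g{i}" for i in range(60)]
        bulkA = pd.Series(100.0, index=genes)
        bulkB = pd.Series(100.0, index=genes)
        bulkB.iloc[:50] = 10.0  # 50 bulk-true genes
        sig = genes[:30] + genes[50:60]  # 30 TP, 10 FP, 20 FN
        score = de.bulk_truth_and_score(bulkA, bulkB, sig, genes)
        assert (score.tp, score.fp, score.fn) == (30, 10, 20)
        assert score.recall == pytest.approx(0.6)
        assert score.precision == pytest.approx(0.75)
        assert score.tp + score.fn == 50

    def test_empty_significant_set(self):
        genes = ["g1", "g2"]
        score = de.bulk_truth_and_score(
            pd.Series([100, 1.0], index=genes),
            pd.Series([1.0, 1.0], index=genes),
            [],
            genes,
        )
        assert score.recall == 0.0
        assert np.isnan(score.precision)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            de.bulk_truth_and_score(pd.Series(dtype=float),
                                    pd.Series(dtype=float), [], [])
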