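"""Differential expression with a two-part hurdle test, scored against bulk.

Counts are library-size normalized to log2(count / cell_total * 1e4 + 1).
The hurdle test combines a binomial likelihood-ratio test on detection
frequency with a Gaussian likelihood-ratio test on the mean of detected
values; the summed statistic is referred to a chi-square whose degrees of
freedom equal the number of estimable parts.  Genes at BH-adjusted
FDR < 1e-4 are declared differentially expressed and compared with a
1.5-fold bulk RNA-seq change as ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse, stats
from statsmodels.stats.multitest import multipletests

FDR_THRESHOLD = 1e-4


def normalize(adata: ad.AnnData, scale: float = 1e4) -> ad.AnnData:
    """log2(count / cell_total * scale + 1); zero-total cells are dropped."""
    totals = np.asarray(adata.X.sum(axis=1)).ravel()
    keep = totals > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} zero-total cells before "
            "normalization",
            RuntimeWarning,
        )
    out = adata[keep].copy()
    X = sparse.csr_matrix(out.X, dtype=float)
    inv = scale / totals[keep]
    X = sparse.diags(inv) @ X
    X.data = np.log2(X.data + 1.0)
    out.X = X.tocsr()
    return out


def _dense(norm) -> np.ndarray:
    if isinstance(norm, ad.AnnData):
        norm = norm.X
    if sparse.issparse(norm):
        return norm.toarray()
    return np.asarray(norm, dtype=float)


def _binomial_lrt(dA, nA, dB, nB):
    """2*(loglik of group-specific detection rates - pooled rate).

    xlogy handles the 0*log(0) = 0 limits cleanly.
    """
    from scipy.special import xlogy

    def _ll(k, m):
        p = k / m
        return xlogy(k, p) + xlogy(m - k, 1.0 - p)

    d, n = dA + dB, nA + nB
    lr = 2.0 * (_ll(dA, nA) + _ll(dB, nB) - _ll(d, n))
    return np.maximum(lr, 0.0)


def _gaussian_lrt(sA, qA, dA, sB, qB, dB):
    """MLE-variance Gaussian LRT on the means of detected values.

    sX/qX are sums and sums of squares of the detected (positive) values of
    each group, dX the detection counts.
    """
    d = dA + dB
    with np.errstate(divide="ignore", invalid="ignore"):
        sse_within = (qA - sA**2 / np.maximum(dA, 1)) + (
            qB - sB**2 / np.maximum(dB, 1)
        )
        sse_pooled = (qA + qB) - (sA + sB) ** 2 / np.maximum(d, 1)
        lr = d * (np.log(np.maximum(sse_pooled, 1e-300)) -
                  np.log(np.maximum(sse_within, 1e-300)))
    return np.maximum(lr, 0.0)


def hurdle_test(normA, normB) -> np.ndarray:
    """Two-part hurdle p-value per gene between two groups of cells.

    ``normA``/``normB`` are cells x genes matrices of normalized expression
    (zeros = undetected).  The detection part is estimable when the pooled
    detection frequency is strictly between 0 and 1; the continuous part
    when both groups have detected values, at least three in total, with
    positive within-group variance.  A gene with no estimable part (e.g.
    all-zero in both groups) gets p = 1.
    """
    A, B = _dense(normA), _dense(normB)
    nA, nB = A.shape[0], B.shape[0]
    if nA < 2 or nB < 2:
        raise ValueError("each group needs at least 2 cells")
    dA, dB = (A > 0).sum(axis=0).astype(float), (B > 0).sum(axis=0).astype(float)
    d, n = dA + dB, float(nA + nB)

    est1 = (d > 0) & (d < n)
    lr1 = np.where(est1, _binomial_lrt(dA, nA, dB, nB), 0.0)

    sA, sB = A.sum(axis=0), B.sum(axis=0)
    qA, qB = (A**2).sum(axis=0), (B**2).sum(axis=0)
    sse_within = (qA - np.divide(sA**2, np.maximum(dA, 1))) + (
        qB - np.divide(sB**2, np.maximum(dB, 1))
    )
    est2 = (dA >= 1) & (dB >= 1) & (d >= 3) & (sse_within > 1e-12)
    lr2 = np.where(est2, _gaussian_lrt(sA, qA, dA, sB, qB, dB), 0.0)

    stat = lr1 + lr2
    df = est1.astype(int) + est2.astype(int)
    p = np.ones_like(stat)
    has_df = df > 0
    p[has_df] = stats.chi2.sf(stat[has_df], df[has_df])
    return p


def wilcoxon_test(normA, normB) -> np.ndarray:
    """Wilcoxon rank-sum p-value per gene (tie-corrected normal
    approximation); all-tie genes get p = 1."""
    A, B = _dense(normA), _dense(normB)
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise ValueError("each group needs at least 2 cells")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.mannwhitneyu(
            A, B, axis=0, alternative="two-sided", method="asymptotic"
        )
        p = np.asarray(res.pvalue, dtype=float)
    combined = np.vstack([A, B])
    p[np.ptp(combined, axis=0) == 0] = 1.0
    return np.clip(np.nan_to_num(p, nan=1.0), 0.0, 1.0)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_table(
    normA, normB, genes, test: str = "hurdle", alpha: float = FDR_THRESHOLD
) -> pd.DataFrame:
    """Run a DE test and assemble the per-gene result table."""
    tests = {"hurdle": hurdle_test, "wilcoxon": wilcoxon_test}
    if test not in tests:
        raise ValueError(f"unknown test {test!r}; choose from {sorted(tests)}")
    p = tests[test](normA, normB)
    fdr = bh_fdr(p)
    A, B = _dense(normA), _dense(normB)
    delta = A.mean(axis=0) - B.mean(axis=0)
    return pd.DataFrame(
        {
            "gene": np.asarray(genes),
            "log_fc": delta,
            "p": p,
            "fdr": fdr,
            "significant": fdr < alpha,
        }
    )


@dataclass
class SubsampleResult:
    counts: list[int]
    mean_nde: float
    ci_low: float
    ci_high: float


def subsample_and_test(
    normA,
    normB,
    n: int = 199,
    reps: int = 10,
    seed: int = 0,
    test: str = "hurdle",
    alpha: float = FDR_THRESHOLD,
) -> SubsampleResult:
    """Repeatedly subsample ``n`` cells per group, test, and count DE genes.

    Reports the mean significant-gene count over ``reps`` repetitions with a
    Student-t 95% confidence interval.  Groups smaller than ``n`` cap the
    subsample with a warning.
    """
    A, B = _dense(normA), _dense(normB)
    n_eff = min(n, A.shape[0], B.shape[0])
    if n_eff < n:
        warnings.warn(
            f"groups smaller than n={n}; subsampling {n_eff} cells", RuntimeWarning
        )
    rng = np.random.default_rng(seed)
    counts = []
    for _ in range(reps):
        ia = rng.choice(A.shape[0], size=n_eff, replace=False)
        ib = rng.choice(B.shape[0], size=n_eff, replace=False)
        p = (hurdle_test if test == "hurdle" else wilcoxon_test)(A[ia], B[ib])
        counts.append(int((bh_fdr(p) < alpha).sum()))
    mean = float(np.mean(counts))
    if reps > 1 and np.std(counts, ddof=1) > 0:
        half = float(
            stats.t.ppf(0.975, reps - 1) * np.std(counts, ddof=1) / np.sqrt(reps)
        )
    else:
        half = 0.0
    return SubsampleResult(
        counts=counts, mean_nde=mean, ci_low=mean - half, ci_high=mean + half
    )


@dataclass
class PRScore:
    tp: int
    fp: int
    fn: int
    recall: float
    precision: float


def bulk_truth_and_score(
    bulkA, bulkB, sc_significant, genes, fc_threshold: float = 1.5
) -> PRScore:
    """Recall/precision of a single-cell DE gene set against bulk truth.

    A gene is bulk-true when (FPKM_A + 1)/(FPKM_B + 1) exceeds
    ``fc_threshold`` in either direction.  Precision is NaN when no gene was
    called.
    """
    genes = pd.Index(genes)
    if len(genes) == 0:
        raise ValueError("empty gene universe")
    a = np.asarray(pd.Series(bulkA).reindex(genes), dtype=float)
    b = np.asarray(pd.Series(bulkB).reindex(genes), dtype=float)
    ratio = (a + 1.0) / (b + 1.0)
    truth = (ratio > fc_threshold) | (ratio < 1.0 / fc_threshold)
    sig = genes.isin(pd.Index(sc_significant))
    tp = int((sig & truth).sum())
    fp = int((sig & ~truth).sum())
    fn = int((~sig & truth).sum())
    recall = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    precision = tp / (tp + fp) if (tp + fp) > 0 else float("nan")
    return PRScore(tp=tp, fp=fp, fn=fn, recall=recall, precision=precision)
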