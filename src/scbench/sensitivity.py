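"""Detection statistics, gene-accumulation curves, and dropout/GD50 models.

The dropout rate of a gene — the fraction of cells in which it records zero
counts — is modeled as a function of its bulk expression level x (FPKM) by
f(x) = a * exp(-b * x), fit with nonlinear least squares.  GD50, the bulk
expression at which the fitted curve crosses a detection probability of 0.5,
follows in closed form as ln(2a)/b (defined only when a > 0.5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import optimize, sparse

from .io import TYPE_SPECIES


def detection_stats(
    adata: ad.AnnData, reads_per_cid: np.ndarray | None = None
) -> pd.DataFrame:
    """Per-cell nUMI, nGene, mitochondrial fraction and read-derived ratios.

    ``reads_per_cid`` (same order as ``adata.obs_names``) enables reads/UMI
    and reads/gene; without it those columns are NaN.  All-zero cells report
    NaN ratios and mito fraction.
    """
    X = sparse.csr_matrix(adata.X)
    n_umi = np.asarray(X.sum(axis=1)).ravel()
    n_gene = X.getnnz(axis=1)
    mito_mask = adata.var["mito"].to_numpy()
    mito = np.asarray(X[:, mito_mask].sum(axis=1)).ravel()
    with np.errstate(divide="ignore", invalid="ignore"):
        mito_frac = np.where(n_umi > 0, mito / np.maximum(n_umi, 1), np.nan)
    out = pd.DataFrame(
        {"n_umi": n_umi, "n_gene": n_gene, "mito_frac": mito_frac},
        index=adata.obs_names,
    )
    if reads_per_cid is not None:
        reads = np.asarray(reads_per_cid, dtype=float)
        out["reads"] = reads
        with np.errstate(divide="ignore", invalid="ignore"):
            out["reads_per_umi"] = np.where(n_umi > 0, reads / n_umi, np.nan)
            out["reads_per_gene"] = np.where(n_gene > 0, reads / n_gene, np.nan)
    else:
        out["reads"] = np.nan
        out["reads_per_umi"] = np.nan
        out["reads_per_gene"] = np.nan
    return out


def mito_filter(stats: pd.DataFrame, threshold: float) -> pd.Index:
    """Cells retained at a mitochondrial-fraction threshold (< threshold)."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    keep = stats["mito_frac"] < threshold
    return stats.index[keep.fillna(False)]


def gene_accumulation(
    adata: ad.AnnData,
    sizes=range(1, 51),
    iterations: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean genes detected in pools of 1..n cells sampled without replacement.

    For each pool size, cells are drawn ``iterations`` times, counts summed,
    and genes with a nonzero sum counted; sizes beyond the pool are capped
    with a warning.
    """
    X = sparse.csr_matrix(adata.X)
    n = X.shape[0]
    sizes = list(sizes)
    if max(sizes) > n:
        warnings.warn(
            f"pool of {n} cells smaller than requested size {max(sizes)}; capping",
            RuntimeWarning,
        )
        sizes = sorted({min(s, n) for s in sizes})
    max_size = max(sizes)
    rng = np.random.default_rng(seed)
    # nested pools: each iteration permutes the cells once and grows the pool
    # by prefixes, so detected gene sets are supersets as the pool grows
    per_iter = np.empty((iterations, len(sizes)), dtype=float)
    for it in range(iterations):
        perm = rng.permutation(n)[:max_size]
        prefix = (X[perm].toarray().cumsum(axis=0) > 0).sum(axis=1)
        per_iter[it] = [prefix[s - 1] for s in sizes]
    return pd.DataFrame(
        {
            "pool_size": sizes,
            "mean_genes": per_iter.mean(axis=0),
            "sd_genes": (
                per_iter.std(axis=0, ddof=1) if iterations > 1
                else np.zeros(len(sizes))
            ),
        }
    )


@dataclass
class DropoutModel:
    a: float
    b: float
    gd50: float  # NaN when undefined (a <= 0.5 or failed fit)
    residual: float
    converged: bool

    @staticmethod
    def gd50_from(a: float, b: float) -> float:
        if a > 0.5 and b > 0:
            return float(np.log(2.0 * a) / b)
        return float("nan")


def dropout_fractions(adata: ad.AnnData, genes) -> pd.Series:
    """Fraction of cells with zero counts, per gene."""
    X = sparse.csc_matrix(adata[:, genes].X)
    detected = X.getnnz(axis=0)
    return pd.Series(1.0 - detected / adata.n_obs, index=pd.Index(genes))


def fit_dropout(x, dropout, a_max: float = 1.5) -> DropoutModel:
    """Nonlinear least-squares fit of the exponential dropout curve.

    Initialized at a=1, b=ln(2)/median(x); a is bounded to (0, ``a_max``]
    since it plays the role of a probability amplitude.
    """
    x = np.asarray(x, dtype=float)
    dropout = np.asarray(dropout, dtype=float)
    mask = x > 0
    if mask.sum() < 50:
        raise ValueError("need >= 50 genes with positive expression to fit")
    if ((dropout < 0) | (dropout > 1)).any():
        raise ValueError("dropout fractions must lie in [0, 1]")
    x, dropout = x[mask], dropout[mask]
    p0 = (1.0, np.log(2.0) / np.median(x))
    try:
        popt, _ = optimize.curve_fit(
            lambda t, a, b: a * np.exp(-b * t),
            x,
            dropout,
            p0=p0,
            bounds=([1e-12, 1e-12], [a_max, np.inf]),
            maxfev=10_000,
        )
        a, b = float(popt[0]), float(popt[1])
        resid = float(np.sqrt(np.mean((a * np.exp(-b * x) - dropout) ** 2)))
        return DropoutModel(
            a=a, b=b, gd50=DropoutModel.gd50_from(a, b), residual=resid,
            converged=True,
        )
    except RuntimeError:
        return DropoutModel(
            a=float("nan"), b=float("nan"), gd50=float("nan"),
            residual=float("nan"), converged=False,
        )


def umi_quantile_bins(n_umi: np.ndarray, n_bins: int = 6) -> np.ndarray:
    """Equal-occupancy bins by rank of per-cell UMI counts (0 = lowest)."""
    order = np.argsort(np.argsort(n_umi, kind="stable"), kind="stable")
    return (order * n_bins) // len(n_umi)


def binned_dropout(
    adata: ad.AnnData,
    labels: pd.Series,
    bulk: pd.DataFrame,
    n_bins: int = 6,
    cells_per_fit: int = 50,
    iterations: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Dropout models per UMI-quantile bin and cell type.

    Cells are split into ``n_bins`` equal-occupancy bins by nUMI.  For every
    (bin, type) with at least ``cells_per_fit`` cells, ``iterations`` random
    subsets of ``cells_per_fit`` cells are fit and the resulting GD50 and
    (a, b) are averaged separately; insufficient combinations are skipped.
    """
    labels = labels.reindex(adata.obs_names)
    n_umi = np.asarray(adata.X.sum(axis=1)).ravel()
    bins = umi_quantile_bins(n_umi, n_bins)
    rng = np.random.default_rng(seed)
    rows = []
    for b in range(n_bins):
        for ct in labels.dropna().unique():
            if ct not in TYPE_SPECIES:
                continue
            sel = np.where((bins == b) & (labels == ct).to_numpy())[0]
            if len(sel) < cells_per_fit:
                continue
            sp = TYPE_SPECIES[ct]
            genes = bulk.index[
                (bulk[ct] > 0)
                & (adata.var["species"].reindex(bulk.index) == sp).to_numpy()
            ]
            genes = genes.intersection(adata.var_names)
            x = bulk.loc[genes, ct].to_numpy(float)
            gd50s, a_s, b_s = [], [], []
            for _ in range(iterations):
                take = rng.choice(sel, size=cells_per_fit, replace=False)
                frac = dropout_fractions(adata[take], genes).to_numpy()
                model = fit_dropout(x, frac)
                if model.converged:
                    a_s.append(model.a)
                    b_s.append(model.b)
                    gd50s.append(model.gd50)
            if not a_s:
                continue
            rows.append(
                {
                    "bin": b,
                    "cell_type": ct,
                    "n_cells": len(sel),
                    "mean_a": float(np.mean(a_s)),
                    "mean_b": float(np.mean(b_s)),
                    "mean_gd50": float(np.nanmean(gd50s)),
                }
            )
    return pd.DataFrame(rows)
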