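"""Concordance of single-cell and pseudo-bulk profiles with bulk signatures.

Per-cell concordance is the Pearson correlation of ln(count+1) against
ln(FPKM+1) over the marker panel; pseudo-bulk concordance sums counts over
random pools of 1..50 cells of one type and correlates against the type's
bulk signature over all genes of its species, averaged over iterations.
"""

from __future__ import annotations

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse, stats

from .classify import MarkerPanel, correlation_vectors
from .io import TYPE_SPECIES


def per_cell_concordance(
    adata: ad.AnnData, bulk: pd.DataFrame, panel: MarkerPanel
) -> pd.DataFrame:
    """Pearson r of every cell against each bulk type over the marker panel.

    Values are returned unmasked; a reporting layer may hide r <= 0.2 for
    display without dropping them from the data.
    """
    return correlation_vectors(adata, bulk, panel.genes)


def pseudobulk_concordance(
    adata: ad.AnnData,
    labels: pd.Series,
    bulk: pd.DataFrame,
    sizes=range(1, 51),
    iterations: int = 50,
    seed: int = 0,
    log_scale: bool = True,
) -> pd.DataFrame:
    """Mean Pearson r of pooled profiles to bulk, per cell type and pool size.

    Pools are drawn without replacement from the cells labeled with each
    type; counts are summed and correlated (on ln(x+1) by default) with the
    type's bulk FPKM over all genes of the type's species.
    """
    labels = labels.reindex(adata.obs_names)
    rng = np.random.default_rng(seed)
    rows = []
    for ct in [c for c in labels.dropna().unique() if c in TYPE_SPECIES]:
        sp = TYPE_SPECIES[ct]
        gene_mask = (adata.var["species"] == sp).to_numpy()
        genes = adata.var_names[gene_mask]
        y = bulk.loc[genes, ct].to_numpy(float)
        if np.ptp(y) == 0:
            raise ValueError(f"constant bulk vector for {ct}; correlation undefined")
        ly = np.log1p(y) if log_scale else y
        cells = np.where((labels == ct).to_numpy())[0]
        X = sparse.csr_matrix(adata.X)[:, gene_mask]
        ct_sizes = [min(s, len(cells)) for s in sizes]
        for size in sorted(set(ct_sizes)):
            rs = []
            for _ in range(iterations):
                take = rng.choice(cells, size=size, replace=False)
                pooled = np.asarray(X[take].sum(axis=0)).ravel()
                lx = np.log1p(pooled) if log_scale else pooled
                if np.ptp(lx) == 0:
                    rs.append(np.nan)
                else:
                    rs.append(stats.pearsonr(lx, ly).statistic)
            rows.append(
                {
                    "cell_type": ct,
                    "pool_size": size,
                    "mean_r": float(np.nanmean(rs)),
                    "sd_r": float(np.nanstd(rs, ddof=1)) if iterations > 1 else 0.0,
                }
            )
    return pd.DataFrame(rows)
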