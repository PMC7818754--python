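"""Sequencing-depth normalization via the modal depth of cell-containing CIDs.

Per-library depth is summarized by the depth of the highest-mRNA cell
population: a Gaussian kernel density estimate of log10 per-CID totals
(normal-reference bandwidth), whose significant mode at the largest depth is
taken as the library's modal depth d_i.  Libraries are equalized by
scaling factors s_i = min_j(d_j) / d_i, realized as binomial count thinning.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats


def normal_reference_bandwidth(x: np.ndarray) -> float:
    """Normal-reference ("rule of thumb") KDE bandwidth,
    1.06 * min(sd, IQR/1.349) * n^(-1/5)."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    return 1.06 * spread * len(x) ** (-0.2)


def first_significant_mode(
    totals: np.ndarray,
    significance_frac: float = 0.05,
    grid_size: int = 2048,
) -> float:
    """Modal sequencing depth of the cell population with the highest mRNA
    content.

    A Gaussian KDE with normal-reference bandwidth is fit to log10 totals and
    evaluated on a dense grid; among local maxima whose density reaches at
    least ``significance_frac`` of the global maximum, the mode at the
    largest depth is returned, back-transformed to read units.
    """
    totals = np.asarray(totals, dtype=float)
    if len(totals) < 10:
        raise ValueError("need at least 10 totals to estimate a depth mode")
    if (totals <= 0).any():
        raise ValueError("totals must be positive")
    logt = np.log10(totals)
    if np.ptp(logt) == 0:  # degenerate: a point mass is its own mode
        return float(totals[0])
    bw = normal_reference_bandwidth(logt)
    kde = stats.gaussian_kde(logt, bw_method=bw / logt.std(ddof=1))
    grid = np.linspace(logt.min() - 3 * bw, logt.max() + 3 * bw, grid_size)
    dens = kde(grid)
    interior = np.arange(1, grid_size - 1)
    is_max = (dens[interior] >= dens[interior - 1]) & (
        dens[interior] > dens[interior + 1]
    )
    peaks = interior[is_max]
    if len(peaks) == 0:
        peaks = np.array([int(np.argmax(dens))])
    significant = peaks[dens[peaks] >= significance_frac * dens.max()]
    return float(10 ** grid[significant.max()])


@dataclass
class ScalingPlan:
    """Per-library modal depths and the factors equalizing them."""

    table: pd.DataFrame  # columns: library, d, s

    @property
    def target_depth(self) -> float:
        return float(self.table["d"].min())


def scaling_factors(modal_depths, libraries=None) -> ScalingPlan:
    """s_i = min_j(d_j) / d_i; the shallowest library keeps s = 1."""
    d = np.asarray(modal_depths, dtype=float)
    if (d <= 0).any():
        raise ValueError("modal depths must be positive")
    if libraries is None:
        libraries = [f"lib{i}" for i in range(len(d))]
    s = d.min() / d
    return ScalingPlan(pd.DataFrame({"library": list(libraries), "d": d, "s": s}))


def downsample_counts(adata: ad.AnnData, s: float, seed: int = 0) -> ad.AnnData:
    """Thin counts by binomial sampling with retention probability ``s``.

    Statistically equivalent, at the count level, to downsampling reads of an
    end-counting library by the same factor.  ``s = 1`` returns an identical
    copy.
    """
    if not 0.0 < s <= 1.0:
        raise ValueError(f"scaling factor must be in (0, 1], got {s}")
    out = adata.copy()
    if s == 1.0:
        return out
    rng = np.random.default_rng(seed)
    X = out.X.tocsr() if not isinstance(out.X, np.ndarray) else None
    if X is None:
        out.X = rng.binomial(adata.X.astype(np.int64), s)
    else:
        X.data = rng.binomial(X.data.astype(np.int64), s)
        X.eliminate_zeros()
        out.X = X
    return out
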