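"""Cross-species cell-type classification and multiplet-rate estimation.

Cells are assigned to one of the four mixture cell types by Pearson
correlation of ln(count+1) against ln(FPKM+1) bulk signatures over a marker
panel, thresholded by mutually exclusive per-type rules.  Cross-species
multiplets are detected by the 10th-percentile rule and converted to a total
multiplet rate with the adjustment factor

    lambda = 2 * n_h * n_m / (n_h + n_m - n_hm)^2,

which accounts for undetectable same-species multiplets and unequal species
proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

from .io import CELL_TYPES, TYPE_SPECIES

UNCLASSIFIED = "unclassified"


def _contrast_of(species: str) -> tuple[str, str]:
    return ("EL4", "IVA12") if species == "mouse" else ("Jurkat", "TALL104")


@dataclass
class MarkerPanel:
    """Genes passing the FPKM and ln-fold-change filters, per species."""

    table: pd.DataFrame  # index: gene; columns: species, contrast, ln_fc

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    def __post_init__(self) -> None:
        for sp in ("human", "mouse"):
            if not (self.table["species"] == sp).any():
                raise ValueError(f"marker panel empty for species {sp!r}")


@dataclass
class RuleSet:
    """Per-type correlation thresholds: one lower bound on the own-type
    correlation, upper bounds on the other three.  ``standard`` matches the
    droplet-method rules, ``relaxed`` the low-CID (ICELL8-style) variant."""

    variant: str
    own_min: dict[str, float]
    other_max: dict[str, dict[str, float]]

    @classmethod
    def standard(cls) -> "RuleSet":
        return cls(
            variant="standard",
            own_min={"EL4": 0.60, "IVA12": 0.60, "Jurkat": 0.40, "TALL104": 0.40},
            other_max=_other_max_common(),
        )

    @classmethod
    def relaxed(cls) -> "RuleSet":
        return cls(
            variant="relaxed",
            own_min={"EL4": 0.40, "IVA12": 0.40, "Jurkat": 0.35, "TALL104": 0.25},
            other_max=_other_max_common(),
        )

    def matches(self, f: dict[str, float] | pd.Series) -> list[str]:
        """All rules satisfied by a correlation vector (at most one by
        construction; exclusivity is a tested property)."""
        out = []
        for ct in CELL_TYPES:
            if not f[ct] > self.own_min[ct]:
                continue
            if all(f[o] < cut for o, cut in self.other_max[ct].items()):
                out.append(ct)
        return out


def _other_max_common() -> dict[str, dict[str, float]]:
    # non-target thresholds are shared between the two variants: < 0.05 for
    # every other type except a looser < 0.20 bound on the TALL-104
    # correlation of the three larger types
    out: dict[str, dict[str, float]] = {}
    for ct in CELL_TYPES:
        out[ct] = {
            o: (0.20 if o == "TALL104" else 0.05) for o in CELL_TYPES if o != ct
        }
    return out


def select_markers(
    bulk: pd.DataFrame, fpkm_min: float = 50.0, ln_fc_min: float = 3.0
) -> MarkerPanel:
    """Highly expressed, highly variable genes from the bulk signature.

    A gene is kept if its FPKM exceeds ``fpkm_min`` in any bulk sample and
    the within-species contrast |ln(x_A+1) - ln(x_B+1)| exceeds
    ``ln_fc_min``.
    """
    missing = [t for t in CELL_TYPES if t not in bulk.columns]
    if missing:
        raise ValueError(f"bulk signature lacks cell types: {missing}")
    from .io import species_from_names

    species = species_from_names(bulk.index)
    rows = []
    for sp in ("human", "mouse"):
        a, b = _contrast_of(sp)
        sub = bulk.loc[species == sp]
        ln_fc = np.log(sub[a] + 1.0) - np.log(sub[b] + 1.0)
        keep = (sub[list(CELL_TYPES)].max(axis=1) > fpkm_min) & (
            ln_fc.abs() > ln_fc_min
        )
        rows.append(
            pd.DataFrame(
                {
                    "species": sp,
                    "contrast": f"{a}-vs-{b}",
                    "ln_fc": ln_fc[keep],
                }
            )
        )
    return MarkerPanel(pd.concat(rows))


def correlation_vectors(
    adata: ad.AnnData, bulk: pd.DataFrame, genes: pd.Index
) -> pd.DataFrame:
    """Pearson r between ln(count+1) and ln(FPKM+1) over ``genes``, per cell
    and bulk type.  Cells with zero variance over the panel get NaN."""
    genes = pd.Index(genes)
    missing = genes.difference(adata.var_names)
    if len(missing):
        raise ValueError(f"panel genes absent from matrix: {list(missing)[:5]} ...")
    X = adata[:, genes].X
    X = X.toarray() if not isinstance(X, np.ndarray) else np.asarray(X)
    lx = np.log1p(X.astype(float))
    ly = np.log1p(bulk.loc[genes, list(CELL_TYPES)].to_numpy(float))
    lx_c = lx - lx.mean(axis=1, keepdims=True)
    ly_c = ly - ly.mean(axis=0, keepdims=True)
    sx = np.sqrt((lx_c**2).sum(axis=1))
    sy = np.sqrt((ly_c**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (lx_c @ ly_c) / np.outer(sx, sy)
    r[sx == 0] = np.nan
    return pd.DataFrame(
        r, index=adata.obs_names, columns=[f"f_{ct}" for ct in CELL_TYPES]
    )


def classify(
    adata: ad.AnnData,
    bulk: pd.DataFrame,
    panel: MarkerPanel,
    rules: RuleSet,
    n_expected: int,
) -> pd.DataFrame:
    """Assign the top 2 x n_expected CIDs (by total count) to cell types.

    Returns a table indexed by CID with the four correlations, the assigned
    ``label`` (or ``unclassified``), and the CID's total count.  A CID
    matching two or more rules (impossible for exclusive rule sets, kept as a
    safeguard) is removed to ``unclassified``.
    """
    if n_expected <= 0:
        raise ValueError("n_expected must be positive")
    totals = np.asarray(adata.X.sum(axis=1)).ravel()
    n_top = min(2 * n_expected, adata.n_obs)
    top = np.argsort(-totals, kind="stable")[:n_top]
    sub = adata[top]
    f = correlation_vectors(sub, bulk, panel.genes)
    labels = []
    for _, row in f.iterrows():
        vec = {ct: row[f"f_{ct}"] for ct in CELL_TYPES}
        if any(np.isnan(v) for v in vec.values()):
            labels.append(UNCLASSIFIED)
            continue
        hits = rules.matches(vec)
        labels.append(hits[0] if len(hits) == 1 else UNCLASSIFIED)
    out = f.copy()
    out["label"] = labels
    out["total"] = totals[top]
    return out


def species_totals(adata: ad.AnnData) -> pd.DataFrame:
    """Per-CID total counts on each species' genes."""
    out = {}
    for sp in ("human", "mouse"):
        mask = (adata.var["species"] == sp).to_numpy()
        out[sp] = np.asarray(adata[:, mask].X.sum(axis=1)).ravel()
    return pd.DataFrame(out, index=adata.obs_names)


def detect_multiplets(
    adata: ad.AnnData, assignment: pd.DataFrame, percentile: float = 10.0
) -> tuple[pd.Series, dict[str, float]]:
    """Flag cross-species multiplets by the 10th-percentile rule.

    Species thresholds are the ``percentile``-th percentile of the same-
    species total-count distribution among cells classified to that species;
    a CID is flagged when its totals on both species strictly exceed both
    thresholds.  Returns the per-CID flags (over the CIDs of ``assignment``)
    and the counts n_h, n_m, n_hm with the thresholds used.
    """
    cids = assignment.index
    st = species_totals(adata).loc[cids]
    labels = assignment["label"]
    info: dict[str, float] = {}
    thresholds = {}
    for sp in ("human", "mouse"):
        sp_types = [ct for ct in CELL_TYPES if TYPE_SPECIES[ct] == sp]
        own = st.loc[labels.isin(sp_types).values, sp]
        info[f"n_{sp[0]}"] = int(len(own))
        if len(own) < 10:
            thresholds[sp] = None
        else:
            thresholds[sp] = float(np.percentile(own, percentile))
    if thresholds["human"] is None or thresholds["mouse"] is None:
        flags = pd.Series(False, index=cids)
        info.update(n_hm=0, threshold_human=np.nan, threshold_mouse=np.nan)
        return flags, info
    flags = pd.Series(
        (st["human"].to_numpy() > thresholds["human"])
        & (st["mouse"].to_numpy() > thresholds["mouse"]),
        index=cids,
    )
    info.update(
        n_hm=int(flags.sum()),
        threshold_human=thresholds["human"],
        threshold_mouse=thresholds["mouse"],
    )
    return flags, info


@dataclass
class MultipletRate:
    observed_fraction: float
    adjustment_lambda: float
    rate: float


def adjusted_multiplet_rate(
    n_multiplets: int, n_cells: int, n_h: int, n_m: int, n_hm: int
) -> MultipletRate:
    """Total multiplet rate from observed cross-species multiplets.

    The observed fraction n_multiplets / n_cells is divided by
    lambda = 2 * n_h * n_m / (n_h + n_m - n_hm)^2.
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    if n_h <= 0 or n_m <= 0:
        raise ValueError("need classified cells of both species (n_h, n_m > 0)")
    denom = n_h + n_m - n_hm
    if denom <= 0:
        raise ValueError("n_h + n_m - n_hm must be positive")
    lam = 2.0 * n_h * n_m / denom**2
    if lam == 0:
        raise ValueError("adjustment factor lambda is zero; rate undefined")
    observed = n_multiplets / n_cells
    return MultipletRate(
        observed_fraction=observed, adjustment_lambda=lam, rate=observed / lam
    )
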