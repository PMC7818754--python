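"""Synthetic barnyard-style scRNA-seq data with fully known ground truth.

The generator emulates a 1:1:1:1 mixture of four lymphocyte-like cell types
from two species — two mouse-like lines (EL4-like, IVA12-like) and two
human-like lines (Jurkat-like, TALL-104-like), the last with markedly lower
mRNA content — plus empty barcodes filled with ambient RNA, two-cell
multiplets, damaged cells with inflated mitochondrial fractions, and
UMI-tagged reads carrying substitution sequencing errors.  Every barcode's
latent state (member cell types, empty/multiplet/damaged flags, true depth)
is recorded so that downstream stages can be validated against truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

from .io import CELL_TYPES, TYPE_SPECIES, annotate_genes

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class GroundTruth:
    """Latent per-cell-type expression programme of the simulated mixture.

    ``genes`` indexes every simulated gene with its species and mitochondrial
    flag; ``means`` holds the FPKM-like mean expression of each gene in each
    cell type.  A gene belongs to exactly one species and each cell type
    expresses only its own species' genes.
    """

    genes: pd.DataFrame  # index: gene name; columns: species, mito
    means: pd.DataFrame  # index: gene name; columns: the four cell types

    def __post_init__(self) -> None:
        if (self.means.values < 0).any():
            raise ValueError("expression means must be non-negative")
        for ct in CELL_TYPES:
            other = self.genes["species"] != TYPE_SPECIES[ct]
            if (self.means.loc[other.values, ct] != 0).any():
                raise ValueError(f"{ct} expresses genes of the other species")
        for sp in ("human", "mouse"):
            sp_mask = self.genes["species"] == sp
            if not (sp_mask & self.genes["mito"]).any():
                raise ValueError(f"no mitochondrial gene for species {sp!r}")


@dataclass
class SimulationConfig:
    """Study-design parameters of a simulated barnyard run.

    Defaults encode the benchmark's design: equal numbers of the four cell
    types, a TALL-104-like type with a ~5x lower library-size median, ~5%
    two-cell multiplets among cell-containing barcodes, a small damaged-cell
    fraction with boosted mitochondrial load, an ambient background in empty
    barcodes, and UMI substitution errors at the per-read rate.
    """

    cells_per_type: dict[str, int] = field(
        default_factory=lambda: {ct: 500 for ct in CELL_TYPES}
    )
    lib_median: dict[str, float] = field(
        default_factory=lambda: {
            "EL4": 8000.0,
            "IVA12": 8000.0,
            "Jurkat": 8000.0,
            "TALL104": 1600.0,
        }
    )
    lib_sdlog: float = 0.35
    n_empty: int = 5000
    ambient_median: float = 40.0
    ambient_sdlog: float = 0.6
    multiplet_rate: float = 0.05
    damaged_frac: float = 0.05
    mito_boost: float = 10.0
    damaged_lib_factor: float = 0.4
    umi_length: int = 10
    umi_error_rate: float = 0.01
    reads_per_umi_mean: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("multiplet_rate", "damaged_frac", "umi_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if any(n < 0 for n in self.cells_per_type.values()) or self.n_empty < 0:
            raise ValueError("cell and empty-barcode counts must be >= 0")
        if self.umi_length < 4:
            raise ValueError("UMI length must be >= 4 bases")
        if self.reads_per_umi_mean < 1:
            raise ValueError("mean reads per UMI must be >= 1")
        if not 0.0 < self.damaged_lib_factor <= 1.0:
            raise ValueError("damaged_lib_factor must be in (0, 1]")
        if any(m <= 0 for m in self.lib_median.values()):
            raise ValueError("library-size medians must be > 0")


@dataclass
class SyntheticDataset:
    """A simulated run: UMI counts, per-barcode truth, bulk signature."""

    adata: ad.AnnData
    truth: pd.DataFrame  # cid, types, is_empty, is_multiplet, is_damaged, true_umis
    bulk: pd.DataFrame  # gene x cell type, FPKM-like
    tagged: pd.DataFrame | None = None
    umi_provenance: pd.DataFrame | None = None


def generate_ground_truth(
    n_genes_per_species: int,
    n_markers: int = 25,
    n_mito: int = 5,
    mito_frac: float = 0.03,
    seed: int = 0,
) -> GroundTruth:
    """Draw a per-type mean-expression table with recoverable marker structure.

    Per-gene means are log-normal (heavy-tailed, many lowly expressed genes).
    For each within-species pair of cell types, ``n_markers`` genes are given
    a >= e^3-fold mean separation at high absolute expression, alternating
    direction between the two types, so the FPKM > 50 & ln-FC > 3 marker
    filter can recover them.  ``n_mito`` mitochondrial genes per species are
    scaled so the baseline mitochondrial fraction is ``mito_frac``.
    """
    if n_genes_per_species <= 0 or n_markers <= 0 or n_mito <= 0:
        raise ValueError("gene, marker and mito counts must be positive")
    if n_markers + n_mito >= n_genes_per_species:
        raise ValueError("n_markers + n_mito must be < n_genes_per_species")

    rng = np.random.default_rng(seed)
    names, species, mito = [], [], []
    for sp, prefix in (("human", "hg_"), ("mouse", "mm_")):
        for i in range(n_genes_per_species):
            tag = "MT-" if i < n_mito else ""
            names.append(f"{prefix}{tag}G{i:05d}")
            species.append(sp)
            mito.append(i < n_mito)
    genes = pd.DataFrame({"species": species, "mito": mito}, index=names)

    means = pd.DataFrame(0.0, index=names, columns=list(CELL_TYPES))
    pairs = {"mouse": ("EL4", "IVA12"), "human": ("Jurkat", "TALL104")}
    for sp, (type_a, type_b) in pairs.items():
        sp_idx = np.where((genes["species"] == sp).values)[0]
        n_sp = len(sp_idx)
        for ct in (type_a, type_b):
            means.iloc[sp_idx, means.columns.get_loc(ct)] = rng.lognormal(
                mean=1.0, sigma=1.5, size=n_sp
            )
        # marker block: non-mito genes, alternating direction, ln-FC > 3
        # after the +1 pseudocount used by the marker filter
        candidates = sp_idx[n_mito:]
        marker_idx = rng.choice(candidates, size=n_markers, replace=False)
        high = rng.uniform(100.0, 500.0, size=n_markers)
        low = np.zeros(n_markers)  # lineage markers: fully off in the other line
        up_in_a = np.arange(n_markers) % 2 == 0
        col_a, col_b = means.columns.get_loc(type_a), means.columns.get_loc(type_b)
        means.iloc[marker_idx, col_a] = np.where(up_in_a, high, low)
        means.iloc[marker_idx, col_b] = np.where(up_in_a, low, high)
        # pin the mitochondrial share of each type's transcriptome
        mito_idx = sp_idx[:n_mito]
        for col in (col_a, col_b):
            col_vals = means.iloc[sp_idx, col].to_numpy().copy()
            non_mito_sum = col_vals[n_mito:].sum()
            target = mito_frac / (1.0 - mito_frac) * non_mito_sum
            weights = rng.uniform(0.5, 1.5, size=n_mito)
            means.iloc[mito_idx, col] = target * weights / weights.sum()
    return GroundTruth(genes=genes, means=means)


def _type_probs(gt: GroundTruth, mito_boost: float = 1.0) -> dict[str, np.ndarray]:
    probs = {}
    mito = gt.genes["mito"].to_numpy()
    for ct in CELL_TYPES:
        m = gt.means[ct].to_numpy().astype(float).copy()
        if mito_boost != 1.0:
            m[mito] *= mito_boost
        probs[ct] = m / m.sum()
    return probs


def simulate_cells(gt: GroundTruth, config: SimulationConfig) -> SyntheticDataset:
    """Simulate a full barnyard run at the configured study design.

    Each cell draws a log-normal library size with its type's parameters and
    multinomial gene counts from the type's normalized mean vector.  With
    probability ``multiplet_rate`` a cell-containing barcode holds two
    independently drawn cells whose counts are summed.  Empty barcodes draw
    from the depth-weighted average profile at ambient depth.  Damaged cells
    have mitochondrial probabilities multiplied by ``mito_boost``.
    """
    if gt.means.empty:
        raise ValueError("empty GroundTruth")
    rng = np.random.default_rng(config.seed)
    n_genes = gt.means.shape[0]
    type_names = list(CELL_TYPES)
    type_w = np.array([config.cells_per_type[ct] for ct in type_names], dtype=float)
    n_cell_cids = int(type_w.sum())
    if n_cell_cids == 0 and config.n_empty == 0:
        raise ValueError("nothing to simulate")
    type_p = (
        type_w / type_w.sum()
        if type_w.sum() > 0
        else np.full(len(type_names), 1.0 / len(type_names))
    )
    probs = _type_probs(gt)
    probs_damaged = _type_probs(gt, config.mito_boost)

    is_multiplet = rng.random(n_cell_cids) < config.multiplet_rate
    is_damaged = rng.random(n_cell_cids) < config.damaged_frac
    n_members = np.where(is_multiplet, 2, 1)
    total_members = int(n_members.sum())
    member_cid = np.repeat(np.arange(n_cell_cids), n_members)
    member_type = rng.choice(len(type_names), size=total_members, p=type_p)
    medians = np.array([config.lib_median[ct] for ct in type_names])
    member_lib = rng.lognormal(
        mean=np.log(medians[member_type]), sigma=config.lib_sdlog
    )
    # damaged cells leak cytoplasmic mRNA: smaller library, higher mito share
    member_lib = np.where(
        is_damaged[member_cid], member_lib * config.damaged_lib_factor, member_lib
    ).astype(np.int64)
    member_lib = np.maximum(member_lib, 1)

    rows, cols, vals = [], [], []

    def _draw_block(cid_idx, libs, p):
        if len(cid_idx) == 0:
            return
        counts = rng.multinomial(libs, p)  # (n, n_genes)
        r, c = np.nonzero(counts)
        rows.append(cid_idx[r])
        cols.append(c)
        vals.append(counts[r, c])

    member_damaged = is_damaged[member_cid]
    for t in range(len(type_names)):
        for dmg in (False, True):
            sel = (member_type == t) & (member_damaged == dmg)
            p = (probs_damaged if dmg else probs)[type_names[t]]
            _draw_block(member_cid[sel], member_lib[sel], p)

    # ambient profile: depth-weighted mean of the type profiles
    if config.n_empty > 0:
        w = type_w * medians
        p_amb = np.zeros(n_genes)
        for t, ct in enumerate(type_names):
            p_amb += w[t] * probs[ct]
        p_amb /= p_amb.sum()
        amb_depth = np.maximum(
            rng.lognormal(
                np.log(config.ambient_median), config.ambient_sdlog, config.n_empty
            ).astype(np.int64),
            1,
        )
        _draw_block(n_cell_cids + np.arange(config.n_empty), amb_depth, p_amb)

    n_cids = n_cell_cids + config.n_empty
    order = rng.permutation(n_cids)  # shuffle cells and empties together
    inv = np.argsort(order)
    row_idx = inv[np.concatenate(rows)] if rows else np.array([], dtype=int)
    mat = sparse.coo_matrix(
        (
            np.concatenate(vals) if vals else np.array([], dtype=np.int64),
            (row_idx, np.concatenate(cols) if cols else np.array([], dtype=int)),
        ),
        shape=(n_cids, n_genes),
    ).tocsr()
    cids = np.array([f"CID{i:06d}" for i in range(n_cids)])

    types_per_cid = [[] for _ in range(n_cell_cids)]
    for cid, t in zip(member_cid, member_type):
        types_per_cid[cid].append(type_names[t])
    all_types = ["+".join(sorted(ts)) for ts in types_per_cid] + [""] * config.n_empty
    truth = pd.DataFrame(
        {
            "cid": cids,
            "types": np.asarray(all_types, dtype=object)[order],
            "is_empty": np.concatenate(
                [np.zeros(n_cell_cids, bool), np.ones(config.n_empty, bool)]
            )[order],
            "is_multiplet": np.concatenate(
                [is_multiplet, np.zeros(config.n_empty, bool)]
            )[order],
            "is_damaged": np.concatenate(
                [is_damaged, np.zeros(config.n_empty, bool)]
            )[order],
            "true_umis": np.asarray(mat.sum(axis=1)).ravel(),
        }
    )

    adata = ad.AnnData(
        X=mat,
        obs=pd.DataFrame(index=cids),
        var=gt.genes.copy(),
    )
    annotate_genes(adata)

    noise = np.random.default_rng([config.seed, 101]).lognormal(
        0.0, 0.1, size=gt.means.shape
    )
    bulk = gt.means * noise
    bulk[gt.means == 0] = 0.0
    return SyntheticDataset(adata=adata, truth=truth, bulk=bulk)


def simulate_dropout_curve(
    a: float,
    b: float,
    x_grid: np.ndarray,
    n_cells: int,
    seed: int = 0,
) -> np.ndarray:
    """Simulate a gene x cell 0/1 detection matrix from the exponential
    dropout model: gene at bulk level x is missed in each cell independently
    with probability min(1, a*exp(-b*x))."""
    x_grid = np.asarray(x_grid, dtype=float)
    if not 0.0 < a <= 1.0:
        raise ValueError("amplitude a must be in (0, 1]")
    if b <= 0:
        raise ValueError("decay b must be > 0")
    if (x_grid <= 0).any():
        raise ValueError("expression grid must be positive")
    rng = np.random.default_rng(seed)
    p_drop = np.minimum(1.0, a * np.exp(-b * x_grid))
    return (rng.random((len(x_grid), n_cells)) >= p_drop[:, None]).astype(np.int8)


def _umi_int_to_str(umi_int: np.ndarray, length: int) -> np.ndarray:
    shifts = 2 * np.arange(length - 1, -1, -1, dtype=np.int64)
    digits = (umi_int[:, None] >> shifts) & 3
    return _BASES[digits].view(f"S{length}").ravel().astype(str)


def umi_str_to_int(umis, length: int) -> np.ndarray:
    """Encode fixed-length ACGT strings as base-4 integers (A<C<G<T)."""
    arr = np.asarray(umis, dtype=f"S{length}")
    bytes_view = arr.view("S1").reshape(len(arr), length)
    lut = np.full(256, -1, dtype=np.int8)
    for v, b in enumerate(b"ACGT"):
        lut[b] = v
    digits = lut[bytes_view.view(np.uint8)]
    if (digits < 0).any():
        raise ValueError("UMI contains characters outside {A,C,G,T}")
    shifts = 2 * np.arange(length - 1, -1, -1, dtype=np.int64)
    return (digits.astype(np.int64) << shifts).sum(axis=1)


def emit_tagged_reads(
    dataset: SyntheticDataset, config: SimulationConfig
) -> pd.DataFrame:
    """Expand UMI counts into a tagged-read table with UMI sequencing errors.

    Every true molecule receives a random UMI sequence; reads per molecule are
    1 + Poisson(mean - 1); each read's UMI is independently corrupted by one
    random substitution with probability ``umi_error_rate``.  The table is
    grouped by (cid, gene, observed UMI).  True-molecule provenance per
    (cid, gene) is stored on ``dataset.umi_provenance``.
    """
    L = config.umi_length
    umi_space = 4**L
    X = sparse.coo_matrix(dataset.adata.X)
    if X.nnz and X.data.max() > umi_space:
        warnings.warn(
            "per-(cid,gene) UMI count exceeds the UMI sequence space; "
            "collisions are unavoidable",
            RuntimeWarning,
        )
    rng = np.random.default_rng([config.seed, 7])
    counts = X.data.astype(np.int64)
    entry = np.repeat(np.arange(X.nnz), counts)  # one row per true molecule
    n_mol = len(entry)
    true_umi = rng.integers(0, umi_space, size=n_mol, dtype=np.int64)
    reads = 1 + rng.poisson(config.reads_per_umi_mean - 1.0, size=n_mol)
    n_err = rng.binomial(reads, config.umi_error_rate)
    clean = reads - n_err

    err_mol = np.repeat(np.arange(n_mol), n_err)
    pos = rng.integers(0, L, size=len(err_mol))
    shift = rng.integers(1, 4, size=len(err_mol))
    s = 2 * (L - 1 - pos)
    base = (true_umi[err_mol] >> s) & 3
    new = (base + shift) % 4
    err_umi = true_umi[err_mol] - (base << s) + (new << s)

    obs_entry = np.concatenate([entry[clean > 0], entry[err_mol]])
    obs_umi = np.concatenate([true_umi[clean > 0], err_umi])
    obs_reads = np.concatenate([clean[clean > 0], np.ones(len(err_mol), np.int64)])

    grouped = (
        pd.DataFrame({"entry": obs_entry, "umi": obs_umi, "reads": obs_reads})
        .groupby(["entry", "umi"], sort=True, as_index=False)["reads"]
        .sum()
    )
    cid_names = dataset.adata.obs_names.to_numpy()
    gene_names = dataset.adata.var_names.to_numpy()
    table = pd.DataFrame(
        {
            "cid": cid_names[X.row[grouped["entry"]]],
            "gene": gene_names[X.col[grouped["entry"]]],
            "umi": _umi_int_to_str(grouped["umi"].to_numpy(), L),
            "reads": grouped["reads"].to_numpy(),
        }
    )
    distinct_true = (
        pd.DataFrame({"entry": entry, "umi": true_umi})
        .groupby("entry")["umi"]
        .nunique()
        .reindex(np.arange(X.nnz), fill_value=0)
    )
    dataset.umi_provenance = pd.DataFrame(
        {
            "cid": cid_names[X.row],
            "gene": gene_names[X.col],
            "true_umis": counts,
            "distinct_true_umis": distinct_true.to_numpy(),
        }
    )
    dataset.tagged = table
    return table
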