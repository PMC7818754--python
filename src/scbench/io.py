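"""Reading and writing of the on-disk formats used throughout the package.

Count matrices travel as a 10x-style Matrix Market triplet
(``matrix.mtx`` + ``barcodes.tsv`` + ``features.tsv``); feature names carry a
species prefix (``hg_`` for human-like, ``mm_`` for mouse-like) and
mitochondrial genes carry an ``MT-`` tag after the prefix.  Bulk signatures
are CSV tables of gene x cell-type FPKM.  Tagged reads are TSV with columns
``cid``, ``gene``, ``umi``, ``reads``.
"""

from __future__ import annotations

import os

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

HUMAN_PREFIX = "hg_"
MOUSE_PREFIX = "mm_"
MITO_TAG = "MT-"

CELL_TYPES = ("EL4", "IVA12", "Jurkat", "TALL104")
TYPE_SPECIES = {
    "EL4": "mouse",
    "IVA12": "mouse",
    "Jurkat": "human",
    "TALL104": "human",
}


def species_from_names(names) -> np.ndarray:
    """Infer the species of each gene from its ``hg_``/``mm_`` prefix."""
    names = np.asarray(names, dtype=object)
    out = np.empty(len(names), dtype=object)
    for i, n in enumerate(names):
        if n.startswith(HUMAN_PREFIX):
            out[i] = "human"
        elif n.startswith(MOUSE_PREFIX):
            out[i] = "mouse"
        else:
            raise ValueError(f"gene name {n!r} lacks an hg_/mm_ species prefix")
    return out


def mito_from_names(names) -> np.ndarray:
    names = np.asarray(names, dtype=object)
    return np.array([MITO_TAG in n for n in names], dtype=bool)


def annotate_genes(adata: ad.AnnData) -> ad.AnnData:
    """Fill ``var['species']`` and ``var['mito']`` from the gene names."""
    adata.var["species"] = species_from_names(adata.var_names)
    adata.var["mito"] = mito_from_names(adata.var_names)
    return adata


def write_mtx_dir(adata: ad.AnnData, path: str) -> None:
    """Write a cells x genes matrix as an uncompressed 10x-style triplet."""
    os.makedirs(path, exist_ok=True)
    mat = sparse.csr_matrix(adata.X)
    # MTX convention is genes x cells, matching 10x output
    spio.mmwrite(os.path.join(path, "matrix.mtx"), mat.T.tocoo())
    pd.Series(adata.obs_names).to_csv(
        os.path.join(path, "barcodes.tsv"), sep="\t", index=False, header=False
    )
    pd.Series(adata.var_names).to_csv(
        os.path.join(path, "features.tsv"), sep="\t", index=False, header=False
    )


def read_mtx_dir(path: str) -> ad.AnnData:
    mat = spio.mmread(os.path.join(path, "matrix.mtx")).tocsr().T.tocsr()
    barcodes = pd.read_csv(
        os.path.join(path, "barcodes.tsv"), sep="\t", header=None
    )[0].astype(str)
    features = pd.read_csv(
        os.path.join(path, "features.tsv"), sep="\t", header=None
    )[0].astype(str)
    adata = ad.AnnData(
        X=mat,
        obs=pd.DataFrame(index=barcodes.values),
        var=pd.DataFrame(index=features.values),
    )
    return annotate_genes(adata)


def write_tagged_reads(table: pd.DataFrame, path: str) -> None:
    table[["cid", "gene", "umi", "reads"]].to_csv(path, sep="\t", index=False)


def read_tagged_reads(path: str) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"cid": str, "gene": str, "umi": str})
    return table


def write_bulk_signature(bulk: pd.DataFrame, path: str) -> None:
    bulk.to_csv(path, index_label="gene")


def read_bulk_signature(path: str) -> pd.DataFrame:
    bulk = pd.read_csv(path, index_col="gene")
    missing = [t for t in CELL_TYPES if t not in bulk.columns]
    if missing:
        raise ValueError(f"bulk signature lacks cell types: {missing}")
    return bulk


def write_truth(truth: pd.DataFrame, path: str) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"cid": str, "types": str})
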