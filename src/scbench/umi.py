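"""Single-base UMI error correction by read-weighted neighbor merging.

Reads are grouped by (cid, gene, UMI).  Within each (cid, gene), a group
whose UMI lies at Hamming distance 1 from a strictly larger group's UMI is
treated as a sequencing error of the larger group and merged into it.  Merge
targets are decided on the original (pre-merge) group sizes; a small group
adjacent to several larger groups joins the largest, with ties broken toward
the lexicographically smaller UMI; equal-size neighbors are never merged.
Chains (C -> B -> A) resolve in one pass: every group's reads end up with the
surviving root of its target.
"""

from __future__ import annotations

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

from .io import annotate_genes
from .synthetic import umi_str_to_int


def _resolve_roots(parent: np.ndarray) -> np.ndarray:
    """Follow parent pointers to the root (-1-terminated), by pointer jumping."""
    root = parent.copy()
    has_parent = root >= 0
    while True:
        jump = has_parent & (parent[np.where(has_parent, root, 0)] >= 0)
        if not jump.any():
            break
        root[jump] = parent[root[jump]]
    idx = np.arange(len(parent))
    return np.where(root >= 0, root, idx)


def collapse(
    groups: pd.DataFrame, annotate: bool = True
) -> tuple[ad.AnnData, ad.AnnData]:
    """Collapse a tagged-read table into UMI-count and read-count matrices.

    Parameters
    ----------
    groups
        Table with columns ``cid``, ``gene``, ``umi`` (fixed-length ACGT
        string) and ``reads`` (positive int).
    annotate
        Infer species/mito gene annotations from gene names (requires the
        ``hg_``/``mm_`` naming convention).

    Returns
    -------
    A pair of cells x genes AnnData objects: surviving UMI counts and total
    read counts.  Total reads are conserved per (cid, gene).
    """
    required = {"cid", "gene", "umi", "reads"}
    if not required.issubset(groups.columns):
        raise ValueError(f"tagged-read table must have columns {sorted(required)}")
    if len(groups) == 0:
        empty = ad.AnnData(
            X=sparse.csr_matrix((0, 0), dtype=np.int64),
            obs=pd.DataFrame(index=pd.Index([], dtype=object)),
            var=pd.DataFrame(index=pd.Index([], dtype=object)),
        )
        return empty, empty.copy()
    lengths = groups["umi"].str.len().unique()
    if len(lengths) != 1:
        raise ValueError(f"mixed UMI lengths in input: {sorted(lengths)}")
    L = int(lengths[0])
    if (groups["reads"] < 1).any():
        raise ValueError("read counts must be >= 1")

    cid_codes, cid_names = pd.factorize(groups["cid"], sort=True)
    gene_codes, gene_names = pd.factorize(groups["gene"], sort=True)
    umi = umi_str_to_int(groups["umi"].to_numpy(), L)
    reads = groups["reads"].to_numpy(np.int64)
    key = cid_codes.astype(np.int64) * len(gene_names) + gene_codes

    nodes = pd.DataFrame({"key": key, "umi": umi, "reads": reads})
    if nodes.duplicated(["key", "umi"]).any():
        nodes = nodes.groupby(["key", "umi"], as_index=False, sort=True)["reads"].sum()
    n = len(nodes)
    node_umi = nodes["umi"].to_numpy()
    node_reads = nodes["reads"].to_numpy()
    node_key = nodes["key"].to_numpy()

    # composite (cid, gene, umi) code for O(log n) neighbor lookup
    umi_space = np.int64(4) ** L
    if node_key.max() >= (2**62) // umi_space:
        raise ValueError("cid x gene space too large for composite indexing")
    code = node_key * umi_space + node_umi
    order = np.argsort(code)
    sorted_code = code[order]

    # scan Hamming-1 neighbors one (position, substitution) at a time,
    # keeping each group's best strictly-larger neighbor (ties to the
    # lexicographically smaller UMI, A<C<G<T = numeric order)
    all_idx = np.arange(n)
    best_reads = np.zeros(n, dtype=np.int64)
    best_umi = np.full(n, umi_space, dtype=np.int64)
    parent = np.full(n, -1, dtype=np.int64)
    for pos in range(L):
        s = 2 * (L - 1 - pos)
        base = (node_umi >> s) & 3
        for shift in (1, 2, 3):
            new = (base + shift) % 4
            nb_umi = node_umi - (base << s) + (new << s)
            nb_code = node_key * umi_space + nb_umi
            loc = np.searchsorted(sorted_code, nb_code)
            loc_c = np.minimum(loc, n - 1)
            found = sorted_code[loc_c] == nb_code
            src = all_idx[found]
            tgt = order[loc_c[found]]
            tr = node_reads[tgt]
            nu = nb_umi[found]
            better = (tr > node_reads[src]) & (
                (tr > best_reads[src])
                | ((tr == best_reads[src]) & (nu < best_umi[src]))
            )
            sel = src[better]
            best_reads[sel] = tr[better]
            best_umi[sel] = nu[better]
            parent[sel] = tgt[better]
    root = _resolve_roots(parent)

    root_reads = np.zeros(n, dtype=np.int64)
    np.add.at(root_reads, root, node_reads)
    survivors = parent < 0

    shape = (len(cid_names), len(gene_names))
    row = (node_key[survivors] // len(gene_names)).astype(np.intp)
    col = (node_key[survivors] % len(gene_names)).astype(np.intp)
    umi_mat = sparse.coo_matrix(
        (np.ones(survivors.sum(), np.int64), (row, col)), shape=shape
    ).tocsr()
    read_mat = sparse.coo_matrix(
        (root_reads[survivors], (row, col)), shape=shape
    ).tocsr()

    obs = pd.DataFrame(index=pd.Index(cid_names, name=None).astype(str))
    var = pd.DataFrame(index=pd.Index(gene_names, name=None).astype(str))
    umi_adata = ad.AnnData(X=umi_mat, obs=obs.copy(), var=var.copy())
    read_adata = ad.AnnData(X=read_mat, obs=obs.copy(), var=var.copy())
    if annotate:
        try:
            annotate_genes(umi_adata)
            annotate_genes(read_adata)
        except ValueError:
            pass  # gene names without species prefixes are fine for counting
    return umi_adata, read_adata
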