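"""Independent brute-force oracles shared by the test modules."""

import numpy as np


def oracle_collapse(groups: dict) -> dict:
    """Exhaustive single-(cid,gene) UMI merge: each group's target is its
    largest strictly-larger Hamming-1 neighbor (ties to the smaller UMI),
    decided on original sizes; reads follow targets to surviving roots."""
    umis = list(groups)
    reads = dict(groups)

    def hamming(a, b):
        return sum(x != y for x, y in zip(a, b))

    target = {}
    for u in umis:
        nbrs = [v for v in umis if hamming(u, v) == 1 and reads[v] > reads[u]]
        if nbrs:
            target[u] = max(nbrs, key=lambda v: (reads[v], [-ord(c) for c in v]))
    roots = {}
    for u in umis:
        v = u
        while v in target:
            v = target[v]
        roots[u] = v
    out = {}
    for u in umis:
        out[roots[u]] = out.get(roots[u], 0) + reads[u]
    return out


def finite_difference_extrema(spline, x_lo, x_hi, n_grid=10_000):
    """Brute-force argmins of the first derivative (inflection) and of the
    signed curvature at or above the inflection (knee), via finite
    differences on a dense grid."""
    grid = np.linspace(x_lo, x_hi, n_grid)
    y = spline(grid)
    d1 = np.gradient(y, grid)
    d2 = np.gradient(d1, grid)
    curvature = d2 / (1 + d1**2) ** 1.5
    infl = np.argmin(d1)
    knee = np.argmin(curvature[: infl + 1])
    return grid[knee], grid[infl]
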