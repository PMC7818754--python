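"""Canned parameter-recovery experiments over the synthetic generator.

These wire several stages together into self-contained, seeded procedures:
simulate a dataset with a known latent parameter, run the estimation pipeline
on it, and return both the estimate and the generating truth.  They back the
reproducibility checks and the analysis drivers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import classify, sensitivity, synthetic
from .io import CELL_TYPES


@dataclass
class MultipletRecovery:
    true_rate: float
    adjusted_rate: float
    observed_fraction: float
    adjustment_lambda: float
    n_cells: int
    counts: dict


def multiplet_recovery(
    n_cells: int = 5000,
    multiplet_rate: float = 0.05,
    n_genes_per_species: int = 1000,
    seed: int = 1,
) -> MultipletRecovery:
    """Estimate the multiplet rate of a barnyard mixture against truth.

    Simulates ``n_cells`` cell-containing barcodes (1:1:1:1 over the four
    types, hence half human-like and half mouse-like) with two-cell
    multiplets injected at ``multiplet_rate``, classifies singlets by the
    standard correlation rules, applies the per-species 10th-percentile
    cross-species detection rule, and adjusts the observed fraction by the
    composition factor lambda.
    """
    ss = np.random.SeedSequence([int(seed), 21])
    s_truth, s_cells = [int(s) % 2**31 for s in ss.generate_state(2)]
    gt = synthetic.generate_ground_truth(
        n_genes_per_species, n_markers=25, seed=s_truth
    )
    cfg = synthetic.SimulationConfig(
        cells_per_type={ct: n_cells // 4 for ct in CELL_TYPES},
        n_empty=0,
        multiplet_rate=multiplet_rate,
        seed=s_cells,
    )
    ds = synthetic.simulate_cells(gt, cfg)
    panel = classify.select_markers(ds.bulk)
    assignment = classify.classify(
        ds.adata, ds.bulk, panel, classify.RuleSet.standard(),
        n_expected=ds.adata.n_obs // 2,
    )
    _, counts = classify.detect_multiplets(ds.adata, assignment)
    est = classify.adjusted_multiplet_rate(
        n_multiplets=counts["n_hm"],
        n_cells=len(assignment),
        n_h=counts["n_h"],
        n_m=counts["n_m"],
        n_hm=counts["n_hm"],
    )
    return MultipletRecovery(
        true_rate=multiplet_rate,
        adjusted_rate=est.rate,
        observed_fraction=est.observed_fraction,
        adjustment_lambda=est.adjustment_lambda,
        n_cells=len(assignment),
        counts=counts,
    )


@dataclass
class GD50Recovery:
    true_gd50: float
    fitted_gd50: float
    fitted_a: float
    fitted_b: float
    n_genes: int
    n_cells: int


def gd50_recovery(
    gd50: float = 13.6,
    a: float = 0.9,
    n_genes: int = 3000,
    n_cells: int = 300,
    seed: int = 1,
) -> GD50Recovery:
    """Recover a known GD50 from simulated dropout data.

    Gene expression levels are drawn log-uniformly on [0.1, 1000] FPKM; the
    decay b is set so a*exp(-b*x) crosses 0.5 at ``gd50``; per-gene dropout
    fractions over ``n_cells`` simulated cells are fit by nonlinear least
    squares and GD50 read off the closed form ln(2a)/b.
    """
    ss = np.random.SeedSequence([int(seed), 22])
    s_x, s_det = [int(s) % 2**31 for s in ss.generate_state(2)]
    rng = np.random.default_rng(s_x)
    x = 10 ** rng.uniform(-1.0, 3.0, n_genes)
    b = np.log(2.0 * a) / gd50
    detection = synthetic.simulate_dropout_curve(a, b, x, n_cells, seed=s_det)
    frac = 1.0 - detection.mean(axis=1)
    model = sensitivity.fit_dropout(x, frac)
    return GD50Recovery(
        true_gd50=gd50,
        fitted_gd50=model.gd50,
        fitted_a=model.a,
        fitted_b=model.b,
        n_genes=n_genes,
        n_cells=n_cells,
    )
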