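"""Shared configuration for the analysis drivers.

Every driver regenerates the benchmark dataset from the same seed so the
scripts can run independently and in any order.  The design mirrors the
benchmark mixture: four cell types 1:1:1:1 across two species, a low-mRNA
TALL-104-like type, ambient-filled empty barcodes, ~5% two-cell multiplets,
and a small damaged-cell fraction.
"""

import os

from scbench import classify, synthetic
from scbench.io import CELL_TYPES

ROOT = os.path.dirname(os.path.dirname(os.path.abspath(__file__)))
RESULTS = os.path.join(ROOT, "results")
SCRATCH = os.path.join(ROOT, "scratch")

SEED = 17
N_GENES_PER_SPECIES = 1500
CELLS_PER_TYPE = 300
N_EMPTY = 4000
N_LOADED = 2400  # cells loaded on the instrument in the simulated run


def results_path(name: str) -> str:
    os.makedirs(RESULTS, exist_ok=True)
    return os.path.join(RESULTS, name)


def scratch_path(name: str) -> str:
    path = os.path.join(SCRATCH, name)
    os.makedirs(os.path.dirname(path), exist_ok=True)
    return path


def benchmark_dataset() -> synthetic.SyntheticDataset:
    gt = synthetic.generate_ground_truth(
        N_GENES_PER_SPECIES, n_markers=25, seed=SEED
    )
    cfg = synthetic.SimulationConfig(
        cells_per_type={ct: CELLS_PER_TYPE for ct in CELL_TYPES},
        n_empty=N_EMPTY,
        seed=SEED + 1,
    )
    ds = synthetic.simulate_cells(gt, cfg)
    ds.sim_config = cfg
    return ds


def classified(ds: synthetic.SyntheticDataset):
    panel = classify.select_markers(ds.bulk)
    assignment = classify.classify(
        ds.adata, ds.bulk, panel, classify.RuleSet.standard(),
        n_expected=4 * CELLS_PER_TYPE,
    )
    return panel, assignment
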