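import numpy as np
import pytest

from scbench import classify, synthetic
from scbench.io import CELL_TYPES


@pytest.fixture(scope="session")
def ground_truth():
    return synthetic.generate_ground_truth(600, n_markers=20, seed=42)


@pytest.fixture(scope="session")
def sim_config():
    return synthetic.SimulationConfig(
        cells_per_type={ct: 150 for ct in CELL_TYPES},
        n_empty=2000,
        seed=7,
    )


@pytest.fixture(scope="session")
def dataset(ground_truth, sim_config):
    return synthetic.simulate_cells(ground_truth, sim_config)


@pytest.fixture(scope="session")
def truth_by_cid(dataset):
    return dataset.truth.set_index("cid")


@pytest.fixture(scope="session")
def marker_panel(dataset):
    return classify.select_markers(dataset.bulk)


@pytest.fixture(scope="session")
def assignment(dataset, marker_panel):
    return classify.classify(
        dataset.adata,
        dataset.bulk,
        marker_panel,
        classify.RuleSet.standard(),
        n_expected=600,
    )


@pytest.fixture(scope="session")
def cell_totals(dataset):
    return np.asarray(dataset.adata.X.sum(axis=1)).ravel()
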