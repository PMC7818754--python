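"""The generator's contracts: determinism, species purity, marker structure,
count conservation, and the statistical behavior of dropout simulation."""

import numpy as np
import pandas as pd
import pytest

from scbench import classify, synthetic
from scbench.io import CELL_TYPES, TYPE_SPECIES


class TestGroundTruth:
    def test_seeded_determinism(self):
        a = synthetic.generate_ground_truth(300, n_markers=10, seed=5)
        b = synthetic.generate_ground_truth(300, n_markers=10, seed=5)
        pd.testing.assert_frame_equal(a.means, b.means)

    def test_species_exclusive_expression(self, ground_truth):
        genes = ground_truth.genes
        for ct in CELL_TYPES:
            other = genes["species"] != TYPE_SPECIES[ct]
            assert (ground_truth.means.loc[other.values, ct] == 0).all()

    def test_marker_filter_recovers_designed_markers(self):
        gt = synthetic.generate_ground_truth(500, n_markers=20, seed=9)
        panel = classify.select_markers(gt.means)  # noiseless bulk
        per_species = panel.table.groupby("species").size()
        assert (per_species >= 20).all()

    def test_mito_genes_present_per_species(self, ground_truth):
        g = ground_truth.genes
        for sp in ("human", "mouse"):
            assert ((g["species"] == sp) & g["mito"]).any()

    @pytest.mark.parametrize("bad", [dict(n_genes_per_species=0),
                                     dict(n_genes_per_species=10, n_markers=0),
                                     dict(n_genes_per_species=10, n_markers=20)])
    def test_invalid_sizes_rejected(self, bad):
        kwargs = dict(n_genes_per_species=100, n_markers=5)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            synthetic.generate_ground_truth(**kwargs)


class TestSimulateCells:
    def test_zero_multiplet_rate_boundary(self, ground_truth):
        cfg = synthetic.SimulationConfig(
            cells_per_type={ct: 50 for ct in CELL_TYPES},
            n_empty=0,
            multiplet_rate=0.0,
            seed=3,
        )
        ds = synthetic.simulate_cells(ground_truth, cfg)
        assert not ds.truth["is_multiplet"].any()

    def test_type_frequencies_within_binomial_bound(self):
        gt = synthetic.generate_ground_truth(60, n_markers=5, n_mito=2, seed=2)
        n = 10_000
        cfg = synthetic.SimulationConfig(
            cells_per_type={ct: n // 4 for ct in CELL_TYPES},
            lib_median={ct: 200.0 for ct in CELL_TYPES},
            n_empty=0,
            multiplet_rate=0.0,
            seed=4,
        )
        ds = synthetic.simulate_cells(gt, cfg)
        freqs = ds.truth["types"].value_counts(normalize=True)
        bound = 3 * np.sqrt(0.25 * 0.75 / n)
        for ct in CELL_TYPES:
            assert abs(freqs[ct] - 0.25) < bound

    def test_singlet_species_purity(self, dataset, truth_by_cid):
        singlets = truth_by_cid[
            ~truth_by_cid["is_empty"] & ~truth_by_cid["is_multiplet"]
        ]
        adata = dataset.adata
        for sp in ("human", "mouse"):
            own_types = [ct for ct in CELL_TYPES if TYPE_SPECIES[ct] == sp]
            cids = singlets.index[singlets["types"].isin(own_types)]
            other = (adata.var["species"] != sp).to_numpy()
            sub = adata[cids][:, other]
            assert sub.X.sum() == 0

    def test_truth_covers_every_cid_once(self, dataset):
        assert len(dataset.truth) == dataset.adata.n_obs
        assert dataset.truth["cid"].is_unique
        assert set(dataset.truth["cid"]) == set(dataset.adata.obs_names)

    def test_recorded_totals_match_matrix(self, dataset, truth_by_cid):
        row_sums = np.asarray(dataset.adata.X.sum(axis=1)).ravel()
        np.testing.assert_array_equal(
            row_sums, truth_by_cid.loc[dataset.adata.obs_names, "true_umis"]
        )

    def test_multiplets_list_two_members(self, truth_by_cid):
        mult = truth_by_cid[truth_by_cid["is_multiplet"]]
        assert len(mult) > 0
        assert (mult["types"].str.count("\\+") == 1).all()

    def test_library_median_monotonicity(self):
        gt = synthetic.generate_ground_truth(80, n_markers=5, n_mito=2, seed=6)
        medians = []
        for lib in (500.0, 4000.0):
            per_seed = []
            for seed in (1, 2, 3):
                cfg = synthetic.SimulationConfig(
                    cells_per_type={"EL4": 100, "IVA12": 0, "Jurkat": 0,
                                    "TALL104": 0},
                    lib_median={ct: lib for ct in CELL_TYPES},
                    n_empty=0,
                    seed=seed,
                )
                ds = synthetic.simulate_cells(gt, cfg)
                per_seed.append(ds.truth["true_umis"].median())
            medians.append(np.median(per_seed))
        assert medians[1] > medians[0]

    def test_empty_ground_truth_rejected(self, sim_config):
        gt = synthetic.generate_ground_truth(50, n_markers=5, n_mito=2, seed=1)
        gt.means = gt.means.iloc[0:0]
        with pytest.raises(ValueError):
            synthetic.simulate_cells(gt, sim_config)


class TestSimulationConfigValidation:
    @pytest.mark.parametrize(
        "field,value",
        [("multiplet_rate", 1.5), ("damaged_frac", -0.1),
         ("umi_error_rate", 2.0), ("umi_length", 3),
         ("reads_per_umi_mean", 0.5)],
    )
    def test_invalid_config_rejected(self, field, value):
        with pytest.raises(ValueError):
            synthetic.SimulationConfig(**{field: value})


class TestDropoutCurveSimulation:
    def test_detection_fraction_at_half_crossing(self):
        a, b = 1.0, 0.05
        x_half = np.log(2 * a) / b
        n_cells = 2000
        det = synthetic.simulate_dropout_curve(
            a, b, np.full(50, x_half), n_cells, seed=0
        )
        frac = det.mean()
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / (50 * n_cells))

    def test_full_dropout_limit(self):
        det = synthetic.simulate_dropout_curve(
            1.0, 1e-12, np.linspace(1, 100, 20), 500, seed=1
        )
        assert det.mean() < 0.01

    @pytest.mark.parametrize("a,b", [(1.5, 0.1), (0.5, -1.0), (0.5, 0.0)])
    def test_parameter_validation(self, a, b):
        with pytest.raises(ValueError):
            synthetic.simulate_dropout_curve(a, b, np.ones(5), 10)


class TestTaggedReads:
    def _tiny_dataset(self, count, n_cids=1):
        import anndata as ad
        from scipy import sparse

        X = sparse.csr_matrix(np.full((n_cids, 1), count, dtype=np.int64))
        adata = ad.AnnData(
            X=X,
            obs=pd.DataFrame(index=[f"CID{i}" for i in range(n_cids)]),
            var=pd.DataFrame(index=["mm_G00001"]),
        )
        return synthetic.SyntheticDataset(
            adata=adata, truth=pd.DataFrame(), bulk=pd.DataFrame()
        )

    def test_zero_error_rate_preserves_distinct_umis(self):
        ds = self._tiny_dataset(200)
        cfg = synthetic.SimulationConfig(umi_error_rate=0.0, seed=5)
        table = synthetic.emit_tagged_reads(ds, cfg)
        prov = ds.umi_provenance.iloc[0]
        assert len(table) == prov["distinct_true_umis"]

    def test_seeded_determinism(self):
        ds1, ds2 = self._tiny_dataset(100), self._tiny_dataset(100)
        cfg = synthetic.SimulationConfig(umi_error_rate=0.1, seed=8)
        t1 = synthetic.emit_tagged_reads(ds1, cfg)
        t2 = synthetic.emit_tagged_reads(ds2, cfg)
        pd.testing.assert_frame_equal(t1, t2)

    def test_collision_warning_when_umi_space_too_small(self):
        ds = self._tiny_dataset(300)
        cfg = synthetic.SimulationConfig(umi_length=4, seed=1)  # space 256
        with pytest.warns(RuntimeWarning, match="collision"):
            synthetic.emit_tagged_reads(ds, cfg)

    def test_read_counts_cover_all_molecules(self):
        ds = self._tiny_dataset(150)
        cfg = synthetic.SimulationConfig(
            umi_error_rate=0.05, reads_per_umi_mean=3.0, seed=2
        )
        table = synthetic.emit_tagged_reads(ds, cfg)
        assert table["reads"].sum() >= 150  # every molecule has >= 1 read
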