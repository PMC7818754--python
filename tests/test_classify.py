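"""Marker selection, correlation rules, multiplet detection and Eq-style
lambda adjustment for the cross-species mixture."""

import numpy as np
import pandas as pd
import pytest

from scbench import classify
from scbench.io import CELL_TYPES, TYPE_SPECIES


def bulk_frame(rows):
    """rows: dict gene -> (EL4, IVA12, Jurkat, TALL104)."""
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(CELL_TYPES))


class TestSelectMarkers:
    def test_pseudocount_fold_change_passes(self):
        # FPKM (100, 1) within species: ln(101/2) ~ 3.92 > 3
        bulk = bulk_frame({
            "mm_Gmark": (100.0, 1.0, 0.0, 0.0),
            "mm_Gflat": (80.0, 60.0, 0.0, 0.0),
            "hg_Ghigh": (0.0, 0.0, 400.0, 2.0),
        })
        panel = classify.select_markers(bulk)
        assert "mm_Gmark" in panel.genes and "mm_Gflat" not in panel.genes

    def test_low_expression_excluded(self):
        bulk = bulk_frame({
            "mm_Glow": (40.0, 0.1, 0.0, 0.0),  # ln FC big but FPKM <= 50
            "mm_Gok": (90.0, 0.5, 0.0, 0.0),
            "hg_Gok": (0.0, 0.0, 90.0, 0.5),
        })
        panel = classify.select_markers(bulk)
        assert "mm_Glow" not in panel.genes

    def test_panel_matches_hand_enumeration(self):
        rng = np.random.default_rng(11)
        genes, vals = [], []
        for i in range(50):
            genes.append(f"mm_G{i:03d}")
            vals.append((rng.uniform(0, 200), rng.uniform(0, 200), 0.0, 0.0))
        for i in range(50):
            genes.append(f"hg_G{i:03d}")
            vals.append((0.0, 0.0, rng.uniform(0, 200), rng.uniform(0, 200)))
        bulk = bulk_frame(dict(zip(genes, vals)))
        expected = set()
        for g, (e, i, j, t) in zip(genes, vals):
            if g.startswith("mm_"):
                keep = max(e, i, j, t) > 50 and abs(
                    np.log(e + 1) - np.log(i + 1)
                ) > 3
            else:
                keep = max(e, i, j, t) > 50 and abs(
                    np.log(j + 1) - np.log(t + 1)
                ) > 3
            if keep:
                expected.add(g)
        try:
            panel = classify.select_markers(bulk)
            assert set(panel.genes) == expected
        except ValueError:
            # a species ended up with no qualifying gene; the hand
            # enumeration must agree that one species is empty
            sp_counts = {"mm": 0, "hg": 0}
            for g in expected:
                sp_counts[g[:2]] += 1
            assert min(sp_counts.values()) == 0

    def test_missing_cell_type_rejected(self):
        bulk = bulk_frame({"mm_G1": (1, 1, 0, 0)}).drop(columns=["TALL104"])
        with pytest.raises(ValueError):
            classify.select_markers(bulk)


class TestRules:
    @pytest.mark.parametrize(
        "f,expected",
        [({"EL4": 0.80, "IVA12": 0.01, "Jurkat": 0.02, "TALL104": 0.10}, "EL4"),
         ({"EL4": 0.03, "IVA12": 0.02, "Jurkat": 0.45, "TALL104": 0.15},
          "Jurkat"),
         ({"EL4": 0.03, "IVA12": 0.02, "Jurkat": 0.01, "TALL104": 0.45},
          "TALL104"),
         ({"EL4": 0.50, "IVA12": 0.01, "Jurkat": 0.01, "TALL104": 0.01}, None)],
    )
    def test_standard_rule_application(self, f, expected):
        hits = classify.RuleSet.standard().matches(f)
        assert hits == ([expected] if expected else [])

    def test_relaxed_variant_lowers_own_thresholds(self):
        f = {"EL4": 0.50, "IVA12": 0.01, "Jurkat": 0.01, "TALL104": 0.01}
        assert classify.RuleSet.relaxed().matches(f) == ["EL4"]

    @pytest.mark.parametrize("variant", ["standard", "relaxed"])
    def test_rule_exclusivity_on_correlation_grid(self, variant):
        """No correlation vector on a [-1,1]^4 grid at step 0.05 satisfies
        two rules of one rule set."""
        rules = getattr(classify.RuleSet, variant)()
        axis = np.round(np.arange(-1.0, 1.0001, 0.05), 10)
        g = np.meshgrid(axis, axis, axis, axis, indexing="ij")
        vecs = {ct: g[i].ravel() for i, ct in enumerate(CELL_TYPES)}
        n_match = np.zeros(len(axis) ** 4, dtype=np.int8)
        for ct in CELL_TYPES:
            m = vecs[ct] > rules.own_min[ct]
            for other, cut in rules.other_max[ct].items():
                m &= vecs[other] < cut
            n_match += m
        assert int(n_match.max()) <= 1


class TestClassify:
    def test_singlet_accuracy_on_generator(self, dataset, assignment,
                                           truth_by_cid):
        joined = assignment.join(truth_by_cid)
        singlets = joined[~joined["is_empty"] & ~joined["is_multiplet"]]
        called = singlets[singlets["label"] != classify.UNCLASSIFIED]
        assert len(called) > 0.8 * len(singlets)
        assert (called["label"] == called["types"]).mean() >= 0.95

    def test_zero_variance_cell_unclassified(self, dataset, marker_panel):
        import anndata as ad
        from scipy import sparse

        n_genes = dataset.adata.n_vars
        X = sparse.csr_matrix((2, n_genes), dtype=np.int64)
        flat = ad.AnnData(
            X=X,
            obs=pd.DataFrame(index=["z1", "z2"]),
            var=dataset.adata.var.copy(),
        )
        out = classify.classify(
            flat, dataset.bulk, marker_panel, classify.RuleSet.standard(), 1
        )
        assert (out["label"] == classify.UNCLASSIFIED).all()

    def test_correlation_matches_direct_oracle(self, dataset, marker_panel):
        adata = dataset.adata[:5]
        f = classify.correlation_vectors(adata, dataset.bulk, marker_panel.genes)
        X = adata[:, marker_panel.genes].X.toarray()
        for i in range(5):
            lx = np.log1p(X[i].astype(float))
            for ct in CELL_TYPES:
                ly = np.log1p(dataset.bulk.loc[marker_panel.genes, ct].to_numpy())
                if lx.std() == 0:
                    continue
                expected = np.corrcoef(lx, ly)[0, 1]
                assert f.iloc[i][f"f_{ct}"] == pytest.approx(expected, abs=1e-12)


class TestMultipletDetection:
    def test_threshold_rule_and_pure_singlet(self, dataset, assignment,
                                             truth_by_cid):
        flags, counts = classify.detect_multiplets(dataset.adata, assignment)
        joined = assignment.join(truth_by_cid)
        singlets = joined[~joined["is_empty"] & ~joined["is_multiplet"]]
        # pure singlets have zero other-species counts: never flagged
        assert not flags.loc[singlets.index].any()
        assert counts["n_hm"] == int(flags.sum())

    def test_cross_species_overlap_with_truth(self, dataset, assignment,
                                              truth_by_cid):
        flags, _ = classify.detect_multiplets(dataset.adata, assignment)
        joined = assignment.join(truth_by_cid)
        mult = joined[joined["is_multiplet"].fillna(False)]
        is_cross = mult["types"].str.contains("EL4|IVA12") & mult[
            "types"
        ].str.contains("Jurkat|TALL")
        cross = mult[is_cross]
        assert len(cross) > 0
        assert flags.loc[cross.index].mean() >= 0.6

    def test_species_absent_gives_no_flags(self, dataset, assignment):
        human_only = assignment[assignment["label"].isin(["Jurkat", "TALL104"])]
        flags, counts = classify.detect_multiplets(dataset.adata, human_only)
        assert not flags.any()
        assert counts["n_hm"] == 0


class TestAdjustedMultipletRate:
    def test_equal_species_no_multiplets(self):
        out = classify.adjusted_multiplet_rate(
            n_multiplets=25, n_cells=1000, n_h=100, n_m=100, n_hm=0
        )
        assert out.adjustment_lambda == pytest.approx(0.5)
        assert out.rate == pytest.approx(0.05)

    def test_hand_evaluated_lambda(self):
        out = classify.adjusted_multiplet_rate(
            n_multiplets=10, n_cells=500, n_h=150, n_m=50, n_hm=10
        )
        assert out.adjustment_lambda == pytest.approx(15000 / 36100, abs=1e-9)

    def test_absent_species_rejected(self):
        with pytest.raises(ValueError):
            classify.adjusted_multiplet_rate(1, 100, n_h=10, n_m=0, n_hm=0)
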