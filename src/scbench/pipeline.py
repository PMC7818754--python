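"""End-to-end orchestration: simulate/load -> correct -> call -> classify ->
sensitivity -> concordance -> DE -> report.

A single root seed is fanned out to the stages through
``numpy.random.SeedSequence([root, stage_index])`` so each stage is
independently reproducible.  The report mirrors a benchmark summary table:
multiplet rate, capture/pool efficiency, per-type median nUMI/nGene, GD50,
mean nDE with a 95% CI, and recall/precision against bulk truth.
"""

from __future__ import annotations

import json
import os
import warnings

import numpy as np
import pandas as pd
import yaml

from . import calling, classify, concordance, de, depth, io, sensitivity, synthetic

STAGE_IDS = {
    "ground_truth": 1,
    "cells": 2,
    "reads": 3,
    "thinning": 4,
    "sensitivity": 5,
    "concordance": 6,
    "de": 7,
}

DEFAULTS = {
    "seed": 0,
    "rules": "standard",
    "emit_reads": False,
    "mito_threshold": 0.2,
    "n_loaded": None,  # defaults to 2x simulated cells
    "normalization": {"target_depth": None},
    "accumulation": {"max_size": 50, "iterations": 50},
    "concordance": {"max_size": 50, "iterations": 50},
    "de": {"n": 199, "reps": 10, "test": "hurdle", "alpha": de.FDR_THRESHOLD},
    "synthetic": {"n_genes_per_species": 1500, "n_markers": 25},
}


def stage_seed(root: int, stage: str) -> int:
    """Derived per-stage seed (stable, < 2^31)."""
    ss = np.random.SeedSequence([int(root), STAGE_IDS[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(config) -> dict:
    if isinstance(config, (str, os.PathLike)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValueError("configuration must be a mapping")
    cfg = _merge(DEFAULTS, config)
    if cfg["rules"] not in ("standard", "relaxed"):
        raise ValueError(f"unknown rule variant {cfg['rules']!r}")
    if "synthetic" not in config and "inputs" not in config:
        raise ValueError("config needs either a 'synthetic' or an 'inputs' block")
    return cfg


def _build_dataset(cfg: dict) -> synthetic.SyntheticDataset:
    if "inputs" in cfg:
        adata = io.read_mtx_dir(cfg["inputs"]["mtx_dir"])
        bulk = io.read_bulk_signature(cfg["inputs"]["bulk_csv"])
        truth = (
            io.read_truth(cfg["inputs"]["truth_tsv"])
            if "truth_tsv" in cfg["inputs"]
            else pd.DataFrame()
        )
        return synthetic.SyntheticDataset(adata=adata, truth=truth, bulk=bulk)
    syn = dict(cfg["synthetic"])
    root = cfg["seed"]
    gt = synthetic.generate_ground_truth(
        n_genes_per_species=syn.pop("n_genes_per_species"),
        n_markers=syn.pop("n_markers"),
        n_mito=syn.pop("n_mito", 5),
        seed=stage_seed(root, "ground_truth"),
    )
    cells = syn.pop("cells_per_type", None)
    sim_kwargs = {k: v for k, v in syn.items()}
    if cells is not None:
        if isinstance(cells, int):
            cells = {ct: cells for ct in io.CELL_TYPES}
        sim_kwargs["cells_per_type"] = cells
    sim = synthetic.SimulationConfig(seed=stage_seed(root, "cells"), **sim_kwargs)
    ds = synthetic.simulate_cells(gt, sim)
    ds.sim_config = sim  # stash for the read-emission stage
    return ds


def _align_genes(adata, var_template):
    """Reindex a collapsed matrix onto the full gene panel (zero-filling
    genes that vanished from the tagged reads)."""
    import anndata as ad
    from scipy import sparse

    missing = var_template.index.difference(adata.var_names)
    if len(missing) == 0 and adata.n_vars == len(var_template):
        return adata[:, var_template.index].copy()
    pad = sparse.csr_matrix((adata.n_obs, len(missing)), dtype=adata.X.dtype)
    X = sparse.hstack([sparse.csr_matrix(adata.X), pad]).tocsr()
    var = pd.concat(
        [adata.var, var_template.loc[missing]]
    ) if len(missing) else adata.var
    out = ad.AnnData(X=X, obs=adata.obs.copy(), var=var)
    return out[:, var_template.index].copy()


def run_pipeline(config, outdir: str | None = None) -> dict:
    """Run every stage from a YAML config (path or dict); return the report.

    With ``outdir`` set, stage artifacts (matrices, assignments, curves,
    report JSON/CSV) are written beneath it.
    """
    cfg = load_config(config)
    root = cfg["seed"]
    report: dict = {"config": {k: v for k, v in cfg.items() if k != "inputs"}}

    ds = _build_dataset(cfg)
    adata = ds.adata
    reads_per_cid = None

    if cfg["emit_reads"] and getattr(ds, "sim_config", None) is not None:
        tagged = synthetic.emit_tagged_reads(ds, ds.sim_config)
        from . import umi as umi_mod

        umi_adata, read_adata = umi_mod.collapse(tagged)
        umi_adata = _align_genes(umi_adata, adata.var)
        read_adata = _align_genes(read_adata, adata.var)
        # preserve simulated CID order; collapse sorts lexicographically
        order = [c for c in adata.obs_names if c in set(umi_adata.obs_names)]
        umi_adata = umi_adata[order].copy()
        read_adata = read_adata[order].copy()
        adata = umi_adata
        reads_per_cid = np.asarray(read_adata.X.sum(axis=1)).ravel()

    totals = np.asarray(adata.X.sum(axis=1)).ravel()

    # classification of the deepest CIDs (feeds the rank-curve lower bound)
    n_cells_design = (
        int(sum(ds.sim_config.cells_per_type.values()))
        if getattr(ds, "sim_config", None) is not None
        else cfg.get("n_expected") or max(100, adata.n_obs // 4)
    )
    rules = (
        classify.RuleSet.standard()
        if cfg["rules"] == "standard"
        else classify.RuleSet.relaxed()
    )
    panel = classify.select_markers(ds.bulk)
    assignment = classify.classify(adata, ds.bulk, panel, rules, n_cells_design)
    classified = assignment[assignment["label"] != classify.UNCLASSIFIED]

    curve = calling.build_rank_curve(totals)
    lower = float(classified["total"].min()) if len(classified) else 100.0
    points = calling.knee_inflection(curve, lower_bound=lower)
    n_loaded = cfg["n_loaded"] or 2 * n_cells_design
    eff = calling.efficiency_metrics(points, totals, n_loaded)

    above = totals > points.inflection_total
    called = adata[above]
    modal_depth = depth.first_significant_mode(
        np.asarray(called.X.sum(axis=1)).ravel()
    )
    target = cfg["normalization"]["target_depth"]
    if target is not None and target < modal_depth:
        s = target / modal_depth
        adata = depth.downsample_counts(adata, s, seed=stage_seed(root, "thinning"))
        totals = np.asarray(adata.X.sum(axis=1)).ravel()
    else:
        s = 1.0

    assign_above = assignment.loc[assignment.index.intersection(adata.obs_names[above])]
    flags, counts = classify.detect_multiplets(adata, assign_above)
    try:
        mrate = classify.adjusted_multiplet_rate(
            n_multiplets=int(counts["n_hm"]),
            n_cells=int(above.sum()),
            n_h=int(counts["n_h"]),
            n_m=int(counts["n_m"]),
            n_hm=int(counts["n_hm"]),
        )
        multiplet = {
            "observed_fraction": mrate.observed_fraction,
            "lambda": mrate.adjustment_lambda,
            "adjusted_rate": mrate.rate,
        }
    except ValueError as err:
        multiplet = {"error": str(err)}

    stats = sensitivity.detection_stats(adata, reads_per_cid)
    kept = sensitivity.mito_filter(stats, cfg["mito_threshold"])
    per_type = {}
    labels = classified["label"]
    acc_cfg = cfg["accumulation"]
    sens_seed = stage_seed(root, "sensitivity")
    for ct in io.CELL_TYPES:
        cells = labels.index[labels == ct].intersection(kept)
        if len(cells) < 10:
            continue
        st = stats.loc[cells]
        entry = {
            "n_cells": int(len(cells)),
            "median_n_umi": float(st["n_umi"].median()),
            "median_n_gene": float(st["n_gene"].median()),
        }
        sp = io.TYPE_SPECIES[ct]
        genes = adata.var_names[(adata.var["species"] == sp).to_numpy()]
        genes = genes[ds.bulk.loc[genes, ct].to_numpy(float) > 0]
        frac = sensitivity.dropout_fractions(adata[cells], genes)
        try:
            model = sensitivity.fit_dropout(
                ds.bulk.loc[genes, ct].to_numpy(float), frac.to_numpy()
            )
            entry.update(
                dropout_a=model.a, dropout_b=model.b, gd50=model.gd50
            )
        except ValueError:
            pass
        per_type[ct] = entry
    pool_type = "EL4"
    pool = labels.index[labels == pool_type].intersection(kept)
    accumulation = None
    if len(pool) >= 2:
        accumulation = sensitivity.gene_accumulation(
            adata[pool],
            sizes=range(1, min(acc_cfg["max_size"], len(pool)) + 1),
            iterations=acc_cfg["iterations"],
            seed=sens_seed,
        )

    conc_cfg = cfg["concordance"]
    conc = concordance.pseudobulk_concordance(
        adata,
        labels,
        ds.bulk,
        sizes=range(1, conc_cfg["max_size"] + 1),
        iterations=conc_cfg["iterations"],
        seed=stage_seed(root, "concordance"),
    )

    de_cfg = cfg["de"]
    de_report = _de_stage(adata, labels, kept, ds.bulk, de_cfg, stage_seed(root, "de"))

    report.update(
        {
            "thresholds": {
                "knee_rank": points.knee_rank,
                "knee_total": points.knee_total,
                "inflection_rank": points.inflection_rank,
                "inflection_total": points.inflection_total,
                "no_transition": points.no_transition,
            },
            "efficiency": eff,
            "modal_depth": modal_depth,
            "depth_scaling_factor": s,
            "multiplet": multiplet,
            "n_classified": int(len(classified)),
            "per_type": per_type,
            "de": de_report,
        }
    )

    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        assignment.to_csv(os.path.join(outdir, "assignments.tsv"), sep="\t")
        conc.to_csv(os.path.join(outdir, "concordance.csv"), index=False)
        if accumulation is not None:
            accumulation.to_csv(
                os.path.join(outdir, "gene_accumulation.csv"), index=False
            )
        with open(os.path.join(outdir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=2, default=_jsonable)
        _report_csv(report).to_csv(os.path.join(outdir, "report.csv"), index=False)
    return report


def _de_stage(adata, labels, kept, bulk, de_cfg, seed) -> dict:
    group_a = labels.index[labels == "EL4"].intersection(kept)
    group_b = labels.index[labels == "IVA12"].intersection(kept)
    if len(group_a) < 2 or len(group_b) < 2:
        return {"error": "insufficient classified mouse cells for DE"}
    mouse = (adata.var["species"] == "mouse").to_numpy()
    genes = adata.var_names[mouse]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        normA = de._dense(de.normalize(adata[group_a])[:, genes])
        normB = de._dense(de.normalize(adata[group_b])[:, genes])
    rng = np.random.default_rng(seed)
    n_eff = min(de_cfg["n"], normA.shape[0], normB.shape[0])
    counts, recalls, precisions = [], [], []
    for _ in range(de_cfg["reps"]):
        ia = rng.choice(normA.shape[0], size=n_eff, replace=False)
        ib = rng.choice(normB.shape[0], size=n_eff, replace=False)
        table = de.de_table(
            normA[ia], normB[ib], genes, test=de_cfg["test"], alpha=de_cfg["alpha"]
        )
        sig = table.loc[table["significant"], "gene"]
        counts.append(int(len(sig)))
        score = de.bulk_truth_and_score(bulk["EL4"], bulk["IVA12"], sig, genes)
        recalls.append(score.recall)
        precisions.append(score.precision)
    from scipy import stats as sps

    mean = float(np.mean(counts))
    sd = float(np.std(counts, ddof=1)) if len(counts) > 1 else 0.0
    half = (
        float(sps.t.ppf(0.975, len(counts) - 1) * sd / np.sqrt(len(counts)))
        if sd > 0
        else 0.0
    )
    return {
        "test": de_cfg["test"],
        "n_per_group": n_eff,
        "reps": de_cfg["reps"],
        "mean_nde": mean,
        "ci_low": mean - half,
        "ci_high": mean + half,
        "recall_mean": float(np.nanmean(recalls)),
        "recall_sd": float(np.nanstd(recalls, ddof=1)) if len(recalls) > 1 else 0.0,
        "precision_mean": float(np.nanmean(precisions)),
        "precision_sd": (
            float(np.nanstd(precisions, ddof=1)) if len(precisions) > 1 else 0.0
        ),
    }


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _report_csv(report: dict) -> pd.DataFrame:
    row = {
        "adjusted_multiplet_rate": report["multiplet"].get("adjusted_rate"),
        "capture_efficiency": report["efficiency"]["capture_efficiency"],
        "pool_efficiency": report["efficiency"]["pool_efficiency"],
        "modal_depth": report["modal_depth"],
        "mean_nde": report["de"].get("mean_nde"),
        "recall": report["de"].get("recall_mean"),
        "precision": report["de"].get("precision_mean"),
    }
    for ct, entry in report["per_type"].items():
        row[f"median_n_umi_{ct}"] = entry["median_n_umi"]
        row[f"median_n_gene_{ct}"] = entry["median_n_gene"]
        if "gd50" in entry:
            row[f"gd50_{ct}"] = entry["gd50"]
    return pd.DataFrame([row])
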