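# scbench

A benchmarking toolkit for barnyard-style single-cell RNA-seq experiments:
quality-control and sensitivity metrics for a defined two-species cell-line
mixture, computed end to end from count data with a fully synthetic,
truth-annotated stand-in for sequencing data.

The package is aimed at method evaluators who want the complete quantitative
machinery of a cell-line-mixture benchmark — from raw tagged reads to a
summary metrics table — as tested, reusable library code.

## What it computes

The benchmark design mixes four lymphocyte cell lines 1:1:1:1 from two
species (mouse EL4 and IVA12; human Jurkat and the small, low-mRNA
TALL-104), so that cross-species barcodes unambiguously reveal multiplets
and bulk RNA-seq signatures provide per-type ground truth. Over this design
the package implements:

- **UMI error correction** (`scbench.umi`): reads grouped by
  ⟨barcode, gene, UMI⟩; a group whose UMI is Hamming distance 1 from a
  strictly larger group's UMI is merged into it (decided on pre-merge sizes,
  ties to the lexicographically smaller UMI).
- **Depth normalization** (`scbench.depth`): per-library modal depth *dᵢ*
  from the first significant mode of a Gaussian KDE of log₁₀ per-CID totals
  (normal-reference bandwidth); scaling factors *sᵢ = minⱼ(dⱼ)/dᵢ* realized
  as binomial count thinning.
- **Cell calling** (`scbench.calling`): knee and inflection of the log-log
  barcode-rank curve via a cubic regression spline with 20 degrees of
  freedom — knee = argmin of signed curvature y″/(1+y′²)^{3/2}, inflection =
  argmin of y′ — plus capture and library-pool efficiencies and theoretical
  capture under Poisson/sub-Poisson loading models.
- **Classification** (`scbench.classify`): per-cell Pearson correlation
  *f(y) = r(ln(x+1), ln(y+1))* against bulk FPKM signatures over a marker
  panel (FPKM > 50, |ln FC| > 3), thresholded by mutually exclusive rules;
  cross-species multiplet detection by the per-species 10th-percentile rule
  and rate adjustment by λ = 2·n_h·n_m/(n_h+n_m−n_hm)².
- **Sensitivity** (`scbench.sensitivity`): per-cell nUMI/nGene/mito
  statistics, gene-accumulation curves, and the exponential dropout model
  *f(x) = a·e^(−bx)* with GD50 = ln(2a)/b, globally and within UMI-quantile
  bins.
- **Concordance** (`scbench.concordance`): per-cell and pseudo-bulk Pearson
  correlation to bulk signatures over pools of 1–50 cells.
- **DE evaluation** (`scbench.de`): log₂(count/total·10⁴+1) normalization, a
  two-part hurdle test (binomial detection + Gaussian continuous LRT) and a
  Wilcoxon alternative, BH-FDR at 10⁻⁴, repeated subsampling to n = 199
  cells, and recall/precision against a 1.5-fold bulk-change ground truth.
- **Synthetic data** (`scbench.synthetic`): the truth-annotated generator
  that emulates the mixture — ambient-filled empty barcodes, ~5% two-cell
  multiplets, damaged cells with inflated mitochondrial load, and UMI-tagged
  reads with substitution errors.

## Worked example

```python
from scbench import synthetic, classify

gt = synthetic.generate_ground_truth(n_genes_per_species=1000, seed=1)
cfg = synthetic.SimulationConfig(
    cells_per_type={ct: 1250 for ct in synthetic.CELL_TYPES},
    n_empty=0, multiplet_rate=0.05, seed=2,
)
ds = synthetic.simulate_cells(gt, cfg)

panel = classify.select_markers(ds.bulk)
assignment = classify.classify(
    ds.adata, ds.bulk, panel, classify.RuleSet.standard(), n_expected=2500
)
flags, c = classify.detect_multiplets(ds.adata, assignment)
est = classify.adjusted_multiplet_rate(
    c["n_hm"], len(assignment), c["n_h"], c["n_m"], c["n_hm"]
)
print(f"observed {est.observed_fraction:.4f}  lambda "
      f"{est.adjustment_lambda:.3f}  adjusted {est.rate:.4f}")
```

prints

```
observed 0.0202  lambda 0.522  adjusted 0.0387
```

— of 5,000 simulated cell-containing barcodes, 2.02% were flagged as
cross-species multiplets by the 10th-percentile rule; dividing by
λ ≈ 0.52 (the correction for undetectable same-species multiplets at this
species composition) estimates a total multiplet rate of ~4%, close to but
slightly below the generating 5% because each doublet member independently
falls under its species' 10th-percentile threshold with probability ~0.1.

## Analysis walkthrough

`analysis/01_simulate.py` … `analysis/07_de_benchmark.py` are numbered
narrative drivers that regenerate the benchmark dataset from a fixed seed,
run one stage each, print what they find, and write tables under
`results/`. A YAML-driven end-to-end run is also available:

```bash
scbench report --config config.yaml --outdir results/run
```

with subcommands `simulate`, `correct-umis`, `normalize-depth`,
`call-cells`, `classify`, `sensitivity`, `concordance` and `de-eval` for
individual stages.

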