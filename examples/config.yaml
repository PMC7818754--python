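# Example end-to-end configuration for `scbench report`.
# A synthetic block makes the run fully self-contained; replace it with an
# `inputs:` block (mtx_dir, bulk_csv, optional truth_tsv) to run on files.

seed: 17

synthetic:
  n_genes_per_species: 1500
  n_markers: 25
  cells_per_type: 300
  n_empty: 4000
  multiplet_rate: 0.05
  damaged_frac: 0.05

# collapse simulated tagged reads (slower but exercises UMI correction)
emit_reads: false

rules: standard          # or: relaxed
n_loaded: 2400           # cells loaded on the instrument
mito_threshold: 0.2

normalization:
  target_depth: null     # set to thin counts toward a common modal depth

accumulation:
  max_size: 50
  iterations: 50

concordance:
  max_size: 50
  iterations: 50

de:
  n: 199
  reps: 10
  test: hurdle           # or: wilcoxon
  alpha: 1.0e-4
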