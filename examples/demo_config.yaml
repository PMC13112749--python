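# Demo pipeline run: a small two-species barnyard library with doublets,
# background barcodes and planted melting/concretion states.
seed: 7
outdir: demo_out
simulate:
  n_cells: {alpha: 100, beta: 100}
  doublet_rate: 0.06
  n_background_barcodes: 500
  mean_pairs_per_cell: 1500
melting:
  equal_depth: 400
  depth_guard: 600
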