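# schicmelt

Single-cell Hi-C quality control, cell calling, and TAD melting/concretion
analysis — with a planted-truth contact simulator so every stage can be
tested as a parameter-recovery problem.

## Who this is for

Split-pool barcoded single-cell chromatin conformation libraries produce a
stream of barcode-tagged contact pairs. Before any biology can be read
off, each pair must be classified as informative or artifactual, barcodes
must be separated into real cells, cross-species doublets and background,
and per-cell 3D-genome summaries (insulation, compartments, contact
decay) must be computed at depths of a few hundred thousand contacts per
cell. `schicmelt` implements that downstream stack as a library plus a
thin CLI, and ships a simulator that emits the same data with known
ground truth.

## What it computes

- **Contact classification (HiC-Pro conventions).** Read ends are
  assigned to restriction fragments (DpnII-style `^GATC` digestion).
  Same-fragment inward pairs are *dangling ends*, same-fragment outward
  pairs *self-circles*, adjacent-fragment inward pairs *religations*;
  everything else that maps well is a *valid pair*. The library
  efficiency benchmark is the **valid pair ratio** = valid pairs (before
  deduplication) / reported pairs.
- **Cell calling.** Barcodes ranked by unique valid pairs; two knee
  points split the curve into doublet-prone / valid / background. In a
  two-species barnyard design, called cells with < 89% of contacts on a
  single genome are cross-species doublets; their share of valid cells
  is the **collision rate**.
- **Library complexity.** Unique valid pairs *Y* versus sequencing depth
  *X* is fit to the hyperbolic saturation model *Y = B<sub>max</sub> X /
  (K<sub>d</sub> + X)*; *B<sub>max</sub>* is the saturation point.
- **Matrix analysis.** Sparse binned contact matrices, ICE balancing
  (iterative correction until the balanced row-sum CV < 1e-5), distance
  decay curves, bin-coverage fractions, and aggregate peak analysis
  (center over max-distance-corner enrichment).
- **Tracks.** Multi-window insulation ("TAD-separation") scores: diamond
  means at window sizes 200–750 kb on 50 kb bins, z-scored per
  chromosome and averaged; boundaries are prominent local minima. A/B
  compartment scores: leading eigenvector of the observed/expected
  Pearson correlation matrix.
- **Melting states.** For a region of interest (typically a long
  B-compartment gene), cells are Ward-clustered (k = 2) on z-scaled
  per-bin insulation scores; the lower-median cluster is the *melting*
  state. The melting degree is the one-sided Kolmogorov–Smirnov distance
  *D* between the pooled insulation-score distributions of the two
  clusters, with p = exp(−2D²mn/(m+n)) and significance at p < 1e-5.
- **Phasing.** Early/late replication-domain contact ratio
  (repli-score) orders cells along S phase; a sex-chromosome content
  score normalized to the diploid expectation
  (L<sub>X</sub>+L<sub>Y</sub>)/(2L<sub>auto</sub>+L<sub>X</sub>+L<sub>Y</sub>)
  separates haploid from diploid cells.

## Worked example

Run the bundled demo (a 100+100-cell two-species library with 6%
planted doublets and 500 background barcodes):

```bash
schicmelt run --config examples/demo_config.yaml --outdir demo_out
```

The run report (abridged) prints:

```json
"callcells": { "knee1": 0, "knee2": 200, "n_valid_cells": 200,
               "n_doublets": 9, "collision_rate": 0.045 },
"qc_summary": { "n_barcodes": 700,
                "median_valid_pair_ratio": 0.493,
                "median_log2_cis_trans": 1.839 }
```

Reading this: the knee finder placed the cell/background boundary at
rank 200, recovering exactly the 200 simulated cells out of 700
barcodes; 9 of them failed the 89% species-purity threshold and were
called cross-species doublets (collision rate 0.045, consistent with
the planted 6% given binomial noise at n = 200); the median valid-pair
ratio of 0.49 matches the simulator's planted 50% valid fraction; and
log2 cis/trans ≈ 1.8 reflects the configured 20% trans rate. Per-cell
QC, barcode ranks, insulation/compartment tracks, melting-state labels
and phasing scores are written as TSV/bedGraph/BED files in
`demo_out/`.

Library use mirrors the CLI:

```python
from schicmelt import SimConfig, simulate_cells, classify_pairs, deduplicate, cell_qc
from schicmelt.classify import FragmentMap

res = simulate_cells(config=SimConfig(n_cells={"alpha": 50}, rng_seed=0))
fm = FragmentMap({c.name: g.cut_sites[c.name] for g in res.genomes.values()
                  for c in g.chromosomes},
                 {c.name: c.length for g in res.genomes.values()
                  for c in g.chromosomes})
qc = cell_qc(deduplicate(classify_pairs(res.pairs, fm)))
```

## Scale

The simulator works on a fixed two-species toy reference (41 Mb + 30 Mb)
rather than full genomes; per-cell depths are mapped by contact density,
so 2,500 pairs/cell on the toy genome plays the role of 500k valid
pairs/cell on a 3 Gb genome. See `docs/methods.md` for the model, all
defaults, and known limitations.
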