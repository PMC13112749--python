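# Methods

This note documents the models, defaults and numerical choices behind
`schicmelt`, and what the planted-truth simulator does and does not
emulate.

## The simulator

### Toy reference

Two fixed species ("alpha": chrA1 20 Mb, chrA2 15 Mb, chrX 5 Mb, chrY
1 Mb, chrM 16 kb; "beta": chrB1 18 Mb, chrB2 12 Mb, chrMb 16 kb).
Restriction cut sites are drawn once as a Poisson process with 500 bp
mean spacing (the scale of a 4-cutter digest) and held fixed like a
genome build; consecutive sites are kept at least one motif length
apart so an emitted FASTA can plant the literal `GATC` motif at every
site and sequence-level digestion round-trips exactly. The small genome
keeps 50 kb binning meaningful (400 bins on chrA1) while a full
simulation runs in seconds.

### Contact model

Valid cis contacts follow a truncated power law p(s) ∝ s^−α on
[1 kb, 0.9·L], α = 1 by default (the observed regime of mammalian
contact decay at sub-10-Mb separations). Structure is imposed by
rejection sampling:

- **TADs**: boundary grid every 1 Mb; contacts crossing a boundary are
  accepted with probability 1/3 (`tad_weight = 3`).
- **Compartments**: alternating A/B blocks of 2.5 Mb; cross-compartment
  contacts accepted with probability 1/3 (`compartment_weight = 3`).
  The checkerboard is deliberately strong so that eigenvector recovery
  is a sharp test rather than a marginal one.
- **Replication timing**: alternating early/late 2 Mb blocks (offset
  1 Mb from the compartment grid). A cell's cycle position
  `phase` ∈ [0,1] tilts anchor placement toward early domains
  (p_early = 0.5 + 0.4·(0.5 − phase)) and modulates the decay exponent
  (α·(1 + 0.3·(phase − 0.5))). The tilt strength 0.4 is chosen so the
  repli-score gradient is clearly recoverable without the periodic
  early/late density pattern becoming a confounder for state
  clustering.
- **Melting/concretion**: one designated region of interest
  (chrA1:5–10 Mb). Concretion-state cells carry a dense 500 kb boundary
  grid there; melting-state cells have no internal boundaries in the
  region and their sub-Mb contacts anchored there are accepted with
  probability 1/8 (`melt_suppression = 8`), shifting mass to longer
  range. This gives melting cells systematically lower diamond
  insulation scores across the region — the direction the state labels
  encode — with an effect size (~3 SD on the per-cell region mean at
  the 500k-equivalent depth) large enough that two-state clustering is
  reliable, and small enough that it degrades visibly at low depth.
  Both states share all boundaries outside the region.

Trans contacts (rate 0.2) pick two distinct chromosomes with
probability proportional to copy-number-weighted length. End positions
are snapped 0–300 bp inside the covering restriction fragment,
mimicking post-ligation fragmentation.

### Artifacts and nuisance processes

Per-pair category probabilities default to valid 0.50, dangling end
0.18, self-circle 0.08, religation 0.12, dumped (same-fragment
same-strand) 0.12 — the efficiency regime of an enrichment-based
single-cell library, in which roughly half of reported pairs are
informative. Artifact ends are jittered 0–40 bp inside their fragment
(rather than placed exactly at the termini) so that independently
planted artifacts are never byte-identical and a library simulated with
`duplicate_rate = 0` really contains zero duplicates. Duplicates are
re-emissions of already-emitted pairs at rate 0.15 of the stream;
mito-nuclear false positives replace 1% of valid pairs with one end on
the mitochondrial contig. Doublet barcodes merge two full cells of
*different* species (same-species collisions are invisible to a
barnyard readout and are not modeled). Background barcodes are sliced
from a bulk ambient pool (mixture of both species, ~25 pairs each).

### Depth scaling

Real per-cell depths are mapped to the toy genome by contact density:
500k valid pairs on 3 Gb ≈ 0.167 pairs/kb ≈ 2,500 pairs/cell here
(100k ≈ 500). The default target of 6,800 pairs/cell (lognormal,
0.2 dex SD) corresponds to a well-sequenced cell. All per-bin contact
densities — what insulation and compartment calculations actually see —
then match the real-data regime.

### What the simulator does not emulate

No polymer physics or loop extrusion, no read-level sequence errors
(barcode errors are available as an explicit mutation mode for
demultiplexer tests), no mapping ambiguity (all pairs carry mapq 60
unless planted otherwise), no chromosome-specific biases beyond copy
number, and no gradual melting — states are binary. Passing
recovery tests therefore demonstrates that the analysis stack measures
what it claims on data with known structure, not that real libraries
meet the same effect sizes.

## Analysis choices

- **Classification** follows the standard rule table on canonically
  ordered mates; `min_mapq = 10`. Same-fragment same-strand pairs go to
  the generic dumped bucket rather than a category of their own. No
  fragment-end distance filter is applied by default (exposed as an
  option upstream tools sometimes enable).
- **Valid pair ratio** uses valid pairs *before* deduplication over
  reported (mapq-passing) pairs; duplication is reported separately as
  1 − unique/valid.
- **Knee finding.** Kneedle-style chord distance is computed on a
  (linear rank, normalized log10 count) plot; a knee is accepted only
  where a single-rank count gap concentrates ≥ 10% of the curve's
  dynamic range *and* exceeds 5× the median gap in a log-spaced window
  (i/2 … 2i). The second condition is scale-free, so self-similar
  curves — log-linear or pure power law — yield an explicit no-knee
  result anywhere. On barcode-rank curves with a genuine cell cliff the
  accepted base with maximal chord distance lands at the cliff; the
  pure log–log difference-curve argmax does not (it settles mid-way
  into the cell block whenever the cell-count distribution is concave
  on log–log axes), which is why the rank axis is linear here. knee1
  (doublet plateau) is searched on the sub-curve above knee2 with the
  same rule; absent a genuine plateau it returns 0 and no barcode is
  discarded as doublet-prone. Limitation: cliffs that are spread over
  many ranks (heavily mixed cell/ambient populations) are reported as
  no-knee rather than guessed.
- **Species assignment** is inclusive at the threshold (≥ 0.89) and
  symmetric between species; ties at the minimal barcode-decoding
  distance are unassigned rather than arbitrarily broken, so collision
  estimates are never inflated by mis-assignment.
- **Collision rate** = cross-species doublets / valid (post-knee)
  cells, doublets included in the denominator.
- **ICE** masks zero-coverage bins plus the lowest 2% of nonzero
  marginals (skipped when marginals are uniform), then updates biases
  multiplicatively until the balanced row-sum CV < 1e-5 (≤ 200
  iterations). Non-convergence returns the last weights with a flag.
- **Insulation** uses diamonds that exclude the anchor bin, full
  windows only (edge bins masked), z-scored per chromosome per window
  size, averaged across windows — deterministic and directly testable
  against a nested-loop oracle. Per-cell tracks are computed on raw
  counts (per-cell matrices are too sparse to balance); pseudo-bulk
  tracks may be balanced. Boundary calls use prominence (≥ 0.01) of
  local minima with a 2-bin merge rule; no rank-sum significance test.
- **Compartment eigenvector**: observed/expected by diagonal means,
  Pearson correlation across bins, leading (largest-|λ|) eigenvector,
  unit norm per chromosome. The sign is arbitrary per chromosome unless
  an orientation track (simulator A-ness, or gene density for real
  data) is supplied; comparisons should be per-chromosome or
  sign-oriented.
- **State clustering** first equalizes cells to the same unique-valid
  count (cells below the target are dropped) — without this,
  depth becomes the dominant clustering axis. Bins are mean-imputed and
  z-scaled, Ward linkage (squared-Euclidean) cut at k = 2; the
  lower-median cluster is melting. Degenerate cuts (singleton/empty
  cluster) are flagged unstable.
- **KS melting score** pools all (cell, bin) scores per cluster —
  per-bin medians are a visualization device, not the statistic. The
  one-sided direction is fixed as melting-CDF-above (lower scores); the
  p-value uses the asymptotic one-sided form exp(−2D²mn/(m+n)), which
  agrees with a permutation p-value to < 0.01 at m = n = 100 (checked
  in the acceptance suite). Depth guard: cells below the configured
  unique-valid threshold are listed and the output flagged; at
  100k-equivalent depth clustering accuracy drops markedly (the
  degradation is itself asserted in the acceptance suite).
- **Phasing** counts endpoints (2 per pair). The repli ratio uses +1
  pseudocounts to stay finite. The haploid score normalizes the
  sex-chromosome endpoint fraction by the XY-diploid expectation
  (L_X+L_Y)/(2·L_auto+L_X+L_Y); the haploid-X expectation on the toy
  genome is (5/40)/(6/76) ≈ 1.58, so the default call threshold 1.5
  sits between the diploid (≈ 1.0) and haploid expectations. It is
  configurable because real sex-chromosome coverage is noisier than the
  simulator's.
- **Saturation fit**: unweighted least squares in linear space with
  positivity bounds, initialized at B₀ = 2·max(Y), K₀ = median(X);
  a log-space variant is a flag away. Either raw reads or valid pairs
  can serve as X.
- **APA**: k = 10, c = 3 at 25 kb by default; enrichment is the center
  over the mean of the c×c maximum-distance corner; loops within
  k + c bins of an edge or the diagonal are excluded and reported.

## Pipeline

One YAML config drives simulate → classify → call cells → tracks →
melting → phasing. Per-stage seeds derive from the global seed by
stable hashing (crc32), so stages are independently reproducible;
re-running with the same config produces byte-identical tables. Unknown
config keys fail validation with the nearest valid name; `200k`/`1M`
unit suffixes are expanded. The CLI also exposes each stage
(`whitelist`, `demux`, `classify`, `qc`, `callcells`, `insulation`,
`saturation`) for use on externally produced pair files in the
documented text dialect.

## Problem sizes

The test and acceptance runs use: 200-cell cohorts at the
500k-equivalent depth for melting/compartment/boundary recovery, 400
cells + 2,500 background barcodes across 20 seeds for collision
recovery, 20,000 pairs for QC-fraction recovery, and 10,000
permutations for the KS p-value check. These sizes make every
stochastic bound comfortably inside its tolerance while a full suite
run stays around five minutes on one CPU.
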