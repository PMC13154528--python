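# Methods

This note records the models, formulas, parameter choices and known
limitations behind `ebatac`.  Everything quantitative here is computed
by the test suite or by `scripts/acceptance.py`; nothing is asserted
that the code does not measure.

## Setting and scope

The pipeline analyses plate-based scATAC-seq of a spontaneously
differentiating embryoid body sampled at two stages (D4, D8).  The
analytical problem is chromatin-only cell-state inference: without
matched expression data, cluster annotation, transitional-state
("early committed", EC) discovery, pseudotime and regulatory-network
construction must all be derived from accessibility.  The package
implements that chain — QC, LSI embedding, gene-activity and
motif-deviation matrices, TF consistency scores, marker-panel
clustering and annotation, LDA pseudotime, co-accessibility loops, and
a TF-loop-TF network — plus a synthetic data generator that stands in
for the (controlled-access) human data and supplies ground truth.

## Per-cell QC

Both ends of every fragment count as Tn5 insertions.  For each
insertion, the signed offset to the nearest TSS on its contig feeds
three metrics: the support-weighted fragment count; reads-in-TSS
(insertions within TSS ± 2 kb, half-open); and the TSS enrichment
score,

    (center insertions / 2·center_bp) / (edge insertions / 2·edge_bp + 0.1),

with a ±50 bp centre window and the two outermost 100 bp windows of
the ±2 kb flank as edges.  All windows are symmetric and half-open, so
a flat insertion profile scores 1 up to the pseudocount (0.1), which
stabilizes shallow cells.  Retention bounds are inclusive on both
sides; "between a and b" is read inclusively as the weaker
interpretation, and cells with zero TSS reads always fail (log10
undefined).  `filter_cells` defaults to deep-library bounds (fragments
in [10^4.5, 10^5], log10 TSS reads in [3.5, 4.5]); the pipeline config
defaults are scaled for the synthetic depth regime (min 100 fragments,
log10 TSS reads in [1.5, 4.5]).  Doublet removal is a documented no-op
hook (`remove_doublets`) — the seam exists, the inference does not.

## LSI embedding

Binarized counts are TF-IDF weighted (term frequency per cell total;
IDF = log(1 + N/(1 + df))).  The weighted matrix is **centered per
peak across cells** before the SVD: centering makes every retained
component exactly zero-mean and mutually orthogonal, which the
downstream contracts assume; without it the leading singular vector of
a nonnegative matrix is a near-constant "size" direction.  Components
whose |Pearson r| with log10 depth exceeds 0.9 are flagged and
dropped.  A single pass is used rather than the iterative
cluster-reweight variant common in large atlases; at the scales this
package targets (10^2–10^3 cells) one pass separates the populations,
and the simplification is deliberate.

## Gene activity and binding activity

Gene activity uses an exponential distance decay from the TSS
(constant 5 kb, window 100 kb, no gene-body term): the simplest
distance-decay model consistent with scoring "regulatory elements in
close proximity".  Cells are normalized to 10^4 total and
log1p-transformed; the raw (pre-normalization) matrix is linear in the
counts and exposed for testing.

Binding activity is a chromVAR-family motif deviation: observed motif
counts vs expectation e = (cell total)·(motif's share of all peak
counts), y = (o − e)/e, standardized against n_background = 50
background draws in which each member peak is replaced by one of its
nearest neighbours in standardized (GC, log1p mean accessibility)
space (ddof = 1; sd floor 1e-6).  The neighbour pool is 50 by default;
the pipeline config uses 250 for the desk-scale 600-peak reference,
because 50 neighbours drawn from 600 peaks are a seed-lucky subset of
one or two lineage programs, whereas 50 of ~10^5 real peaks span many
— widening the pool restores that diversity at small scale.

## The consistency score

Both matrices are smoothed over each cell's k = 10 nearest neighbours
in the LSI embedding (self included, ties broken by barcode order),
row-standardized, and combined per TF as

    C[t,c] = sign(z_g)·sqrt(z_g·z_b)  if z_g·z_b > 0,  else 0.

The signed geometric mean is this package's concrete definition of the
consistency statistic: it rewards joint magnitude *and* sign
agreement, satisfies |C| ≤ max(|z_g|, |z_b|), equals z when both
tracks equal z, and is symmetric in its arguments.  The same combiner
quantifies loop signals (below), making "consistency" literally a loop
signal whose two anchors are a TF's gene track and binding track.
Whether the original statistic binned cells into metacells before
scoring is unknowable from its description; here smoothing precedes
standardization and both tracks are treated symmetrically.

## Clustering and annotation

k-means (k = 7, k-means++, best of 50 restarts, seeded) runs on the
consistency submatrix of the 13 marker TFs only — clustering on "known
marker TFs" is the point of the design, and k = 7 anticipates one
intermediate per germ layer.  A cluster's annotation derives from
which marker sets are *elevated* (mean consistency > tau = 0.25 on the
standardized scale): {ESC} → ESC; one germ layer → that layer;
{ESC, X} → EC-X; anything else → unassigned.  The tau rule is a
formalization of a verbal criterion; 0.25 sits well below the observed
pure-population set means (~1.3–1.7) and above background (≈ −0.7),
and is configurable.  TBXT is accepted under its alias T.

## Trajectory and pseudotime

Fisher LDA on the marker-consistency matrix with cluster labels:
generalized eigenproblem Sb·w = λ·Sw·w, Sw ridge-regularized by
γ = 1e-3·trace(Sw)/d; directions unit-norm with the largest-magnitude
loading positive.  Per lineage X, members are the cells annotated ESC,
EC-X or X; pseudotime is the scalar projection onto the unit axis from
the ESC centroid to the X centroid, min-max rescaled to [0, 1], then
cut into 10 equal-width bins (bin = ⌈pt·10⌉, pt = 0 → bin 1).
Centroid-axis projection is the simplest monotone ordering for a
linear three-state trajectory; principal curves would add machinery
without adding testable structure here.  Bin profiles report empty
bins as missing, never as zero.

## Loops and inferred loop signals

Cells are grouped into k-means metacells (target size 10) in the LSI
embedding.  Candidate pairs are same-contig peaks with midpoint
distance in [1 kb, 500 kb].  Per metacell, the peak signal is
log1p(mean count × 10^4 / metacell total); **the per-metacell mean
signal over all peaks is then subtracted** before computing the
Pearson correlation of anchor pairs across metacells.  This second
centering matters: metacells differ in size and depth, and the concave
log1p biases noisy means, giving every background peak a shared
technical offset (empirically one component carrying ~23% of
background-peak variance, correlated −0.78 with metacell depth) that
would otherwise put a correlation floor of ~0.4 under *all* pairs.
Removing the metacell-level offset is the minimal correction; the
regularized partial-correlation methods used at atlas scale absorb
this component implicitly.  Anchors with no accessibility variation
are flagged with r = 0.  Pairs with r ≥ 0.35 become loops.

The inferred loop signal of loop (a, b) in cell group g applies the
consistency combiner to the two anchors' smoothed standardized signals
averaged over g's cells.  Grouping is parameterized; the pipeline uses
the cluster annotations.

## TF-loop-TF network

An edge t→u exists when a called loop joins one of t's motif-bearing
peaks to a peak overlapping u's TSS ± 2 kb window (half-open on the
right).  Per group, W(t,u) = max(0, mean ILS of supporting loops) ×
max(0, mean consistency of t); zero-weight edges drop.  The weight
uses the source TF's consistency only — the minimal faithful product
of "loop signal and TF consistency"; the target's consistency is
observable in the exports but not multiplied in.  Both the full
network and the TF-only subnetwork are emitted; hub ranking by
weighted out-degree excludes self-edges (flagged in exports), since
autoregulatory loops would otherwise dominate the ranking.

## The synthetic embryoid-body generator

The generator defines the study conditions for every test:

* **Populations and stages.** Seven types — ESC, END, MES, ECT and
  three EC intermediates — over stages D4/D8, 100 cells per type
  (700 total), with D4 rich in ESC/EC (80/70 per type) and D8 rich in
  terminal types (70 each), echoing the expected differentiation
  dynamic.
* **Genome.** One contig; 300 genes every 200 kb, each with one
  promoter peak (TSS ± 250 bp) and one enhancer peak 5–100 kb away
  (600 peaks).  Genes are assigned round-robin to four lineage pools,
  so same-pool genes are ≥ 800 kb apart — outside the 500 kb loop
  window.  This is deliberate: with random placement, co-active genes
  of one program would sit within the window and their peak pairs
  would be genuinely correlated yet unplanted, making loop precision
  untestable by construction rather than informative about the method.
* **Regulons.** The 13 marker TFs plus 15 "novel" TFs (5 per germ
  layer; none for ESC, where extra TFs would be statistically
  indistinguishable from the two ESC markers).  Every pool gets the
  same target budget (32 = regulon_size 8 × the largest panel), split
  within the pool so the first germ-layer marker (the master: SOX17,
  EOMES, TFAP2A) takes a double share.  Equal budgets keep each type's
  program the same share of accessible mass — as in real data, where
  one lineage program is a tiny, near-constant fraction of the
  accessible genome — so depth normalization does not imprint a
  type-specific profile on background peaks.  Novel TFs are themselves
  regulon targets of their pool's markers (giving TF→TF edges) and
  regulate already-active non-TF genes.
* **Counts.** A peak is open with probability p1 = 0.85 in its
  program's home type and p0 = 0.05 otherwise; EC types mix
  probabilities, π = α·π(ESC) + (1−α)·π(layer) with α = 0.5.  Counts
  are Poisson(λ_c·π) with λ_c ~ LogNormal(2.1, 0.35) — about 700
  in-peak fragments per cell, the sparse near-binary regime real
  scATAC occupies, in which binarized LSI is informative.  Background
  fragments per cell are Poisson(40·λ_c), ~30% of the library, placed
  uniformly on the contig; fragment length is clamp(N(200, 50), 50,
  600).  Planted pseudotime: ESC ~ U(0, 0.2), EC ~ U(0.35, 0.65),
  terminal ~ U(0.8, 1.0).
* **Motifs.** Each TF's motif marks its own promoter and all its
  targets' enhancers, plus random hits at rate 0.001 per (motif,
  peak).  The rate is set so spurious count mass stays a small
  fraction of a motif's true mass: at desk scale a motif has ~17
  peaks, and a single random hit on another lineage's active peak
  would otherwise double the motif's signal there — a small-sample
  artifact with no analogue at real motif sizes (10^2–10^3 hits).
* **Determinism.** One seed feeds named substreams (reference, counts,
  fragments; the pipeline derives per-stage seeds by hashing the stage
  name), so any stage is reproducible in isolation and the full run is
  byte-identical under a fixed seed.

What the generator does **not** model — and what passing tests
therefore do not show about real data: doublets, batch and chemistry
effects, nucleosomal fragment-length structure, non-uniform genomic
background (blacklist regions, copy-number), overlapping or nested
regulatory programs, trans (inter-chromosomal or > 500 kb) regulation,
continuous (rather than three-plateau) differentiation kinetics, and
motif families with correlated binding preferences.  Recovery numbers
on this generator are upper bounds on, not estimates of, real-data
performance.

## Problem sizes and numerics

Default test and acceptance runs use the full 700-cell × 600-peak
design; the byte-identity rerun inside the test suite uses a reduced
168-cell design with identical structure (determinism is
scale-independent), while `scripts/acceptance.py` checks it at full
scale.  Numerical conventions: sd floors of 1e-6 guard
standardization and deviation denominators; k-NN ties break by barcode
order; k-means uses seeded k-means++ with 50 restarts (10 for
metacells); LSI uses a dense SVD (appropriate below ~10^3 cells) with
a deterministic sign convention (largest-|loading| positive, also used
for LDA); rank-deficient inputs return the achievable rank with a
warning; weights serialize with 6 significant digits, and all pipeline
TSVs with 10, which round-trips the comparisons made on them.

## Known limitations

* The consistency combiner and the edge-weight product are this
  package's concrete definitions of verbally-specified statistics;
  alternative combiners (e.g. products of rectified z-scores, weighted
  blends of the two tracks) would also fit the verbal description.
* Single-pass LSI and centroid-axis pseudotime are simplifications
  chosen for transparency at desk scale.
* Loop calling by thresholded metacell correlation has no
  distance-decay background model; at atlas scale a regularized
  partial-correlation method should replace it.
* The annotation rule assumes the marker panel is complete and
  disjoint; a population elevated in two germ layers is left
  unassigned rather than resolved.
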