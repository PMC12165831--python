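# Methods

This note documents the modelling choices, numerical details, synthetic
study design and known limitations of `kansformer-epi`.

## Feature extraction

Coordinates are 0-based half-open throughout (BED/bigWig convention);
the TSV pair reader documents its columns as already 0-based. A promoter
is TSS −1500/+500 bp on the gene's strand, clipped at the chromosome
origin. For each pair a fixed window (default 2.5 Mbp, the maximum pair
separation in the benchmark tables) is centered on the midpoint between
the element midpoints (floor division); if it would overrun a chromosome
edge it is shifted to fit rather than truncated, so real signal is kept in
preference to padding. Each signal track is averaged within consecutive
500 bp bins (5000 bins per window); uncovered bases count as zero.
narrowPeak tracks are rasterised per base using signalValue, maximum on
overlap (binary occupancy behind a flag). An extra channel records, per
bin, the shortest base-level distance to either anchor element (zero on
bins overlapping an element), divided by the window size so all channels
are O(1).

Signal channels are z-scored per channel with mean/SD fitted **on the
training split only** (SD floor 1e-8); the distance channel is already
scaled and is left untouched. Normalisation is applied after binning. An
optional `log1p` compression before z-scoring is available for
coverage-like tracks with heavy-tailed peak heights. The
TPM < 1 transcript filter belongs to the upstream pair-table provider;
the reader validates schema only.

## KAN layers

Every edge (p, q) of a layer carries
`φ(x) = w_b[p,q]·silu(x) + w_s[p,q]·Σ_j c[p,q,j]·B_j(x)`; a node sums its
incoming edges. The B-spline basis is cubic by default with 5 uniform grid
intervals on [−1, 1] (basis size = grid + order), matching z-scored
inputs; there is no dynamic grid refinement. Outside the grid range each
basis function is continued by its first-order Taylor expansion from the
clamped boundary point. This makes extrapolation linear, keeps the
partition of unity *exact* everywhere (the derivative terms sum to zero),
and gives bounded gradients. The forward pass is a basis expansion plus a
single matrix contraction — no per-edge loops — and the basis primitive
backpropagates to its input through the analytic B-spline derivative.

Initialisation: spline coefficients ~ N(0, 0.1/n_basis); `w_s = 1`;
`w_b ~ U(−√(3/n_in), +√(3/n_in))`. The symmetric, fan-in-scaled base
weight matters: silu has a positive mean, so a constant `w_b` drifts a
wide layer's output by `n_in · E[silu]`, which saturates downstream
sigmoids at initialisation (we observed p ≡ 1.0 and a dead classification
head with unit base weights on the 4h = 256-wide head input).

## Network

CNN (same-padding, odd kernel) → ReLU → max-pool → BiLSTM (h/2 per
direction) → encoder blocks → attention pooling → aggregate → KAN heads.
Encoder blocks are pre-norm: `Z ← Z + Drop(MHA(LN(Z)))`,
`Z ← Z + Drop(KAN(LN(Z)))` with the KAN applied position-wise
(h → 256 → h). Multi-head attention is the standard projected form: the
attention output already includes V, and a learned output projection with
bias follows; a `literal_mv` flag provides the alternative reading in
which the per-head output is additionally modulated elementwise by V.
Attention pooling uses `A_s = softmax(W² tanh(W¹ H₀ᵀ))` with `A_s ∈
R^{r×l}` row-stochastic and `H₁ = A_s H₀ ∈ R^{r×h}` (the dimensionally
consistent choice). Anchor states `h_e`, `h_p` are read from the
**post-encoder** sequence at the pooled indices `⌊bin/pool⌋`. The heads
are KAN networks `4h → 128 → 64 → 1` with dropout 0.2 after each hidden
layer; the classifier ends in a sigmoid, the distance head is linear in
window-scaled units.

Unstated widths were fixed as: `h = 180` (equal to the CNN channels and
divisible by the 6 heads), attention-pool `s = 64`, `r = 8`, residual
dropout 0.1. The loss is the unweighted sum `L = L_class + L_dist`;
scaling distances by the window size keeps the two terms commensurate.
Probabilities are clamped at 1e-7 inside the cross-entropy.

## Training protocol

Five-fold cross-validation partitions **chromosomes**, assigning them
greedily (largest pair count first, to the currently lightest fold, seeded
shuffle breaking ties) so folds are balanced and no chromosome straddles
the train/validation boundary. AdamW (lr 1e-4, decoupled weight decay)
with early stopping on mean(val AUROC, val AUPR), patience 10, maximum 300
epochs; monitor ties keep the earlier epoch and the best-epoch parameters
are restored. Optional 1:1 undersampling keeps all positives and a seeded
sample of negatives, applied to training folds only — validation keeps its
natural imbalance. Batch size defaults to 16. NaN losses abort with a
diagnostic. Fixed seeds make runs bit-reproducible on CPU.

## Evaluation

AUROC is the rank statistic (midrank ties) and AUPR the step-interpolated
precision–recall area, both via scikit-learn; the test suite checks them
against exhaustive concordance-counting and threshold-sweep oracles.
Repeated-run model comparison uses Welch's two-sample t-test (α = 0.05) by
default — the pooled-variance form sits behind a flag — with the
convention t = 0, p = 1 for two constant equal groups. Windowed feature
importance flattens the five windows around each anchor (e−2…e+2,
p−2…p+2; 500 bp windows) × signal channels into tabular columns and fits
a random-forest classifier (pluggable estimator), reporting per-cell
importances and per-feature averages; the distance channel is excluded.

## Synthetic study design

The generator emulates what the predictor consumes — per-base nonnegative
tracks with peak-like enrichment at regulatory elements, and distance-
bounded E-P pair tables — with a fully known generative rule:

* Elements (default 70 enhancers + 28 promoters per chromosome, six
  1.2 Mb chromosomes) are placed with ≥ 4 kb center spacing and carry
  latent activities a ~ N(0, 1). The spacing is a deliberate fidelity
  choice: distinct regulatory elements whose signal footprints overlap
  would make the planted pair labels unattributable from the tracks.
* Tracks are |N(0, 0.3)| background plus Gaussian peaks (fixed 150 bp SD
  at elements; decoy peaks of width 50–500 bp at random loci) whose
  heights scale with exp(0.6·a) for the class-associated marks (DNase at
  both element classes, H3K4me1 at enhancers, H3K4me3 at promoters);
  repressive marks and CTCF are mostly decoy-driven.
* Each element's **observed activity** is the standardized log mean
  signal of its class marks in a 500 bp window at its center, read back
  from the synthesised tracks. Labels are Bernoulli with
  `P = σ(−1 + 4·(s_e + s_p) − 2·d/d_max + ε)`, ε ~ N(0, 0.5²). Driving
  the rule with observed rather than latent activities makes the returned
  generating probabilities an *achievable* Bayes ceiling — with latent
  activities, track noise put even an oracle learner several AUROC points
  below the nominal ceiling, which would make end-to-end learnability
  unverifiable.
* Positives are label-1 candidates (distance 5–220 kb); negatives are
  sampled from label-0 candidates whose distances fall within the central
  95% of the positive distance distribution, mirroring the
  distance-matched negative construction of the benchmark tables (the
  Kolmogorov–Smirnov distance between the two distance distributions is
  ≈ 0.08 at the default settings).

What the generator does **not** emulate: replication structure, mappability
artefacts, copy-number and GC biases, cell-line-specific co-variation
between marks, TAD structure, and realistic EPI network sparsity — the
default pair density is high enough that the positive network collapses
into large many-to-many components, so its pattern census is dominated by
MIMO. Passing tests therefore demonstrate that the implementation can
read a planted, biologically shaped signal out of track data under
chromosome holdout; they do not certify real-data accuracy.

## Problem sizes

The package's synthetic benchmark runs at a reduced scale chosen for
single-CPU reproducibility: 250 kb windows at 500 bp bins (500 bins),
2000 pairs, and a reduced model (`ModelConfig.small`: h = 64, one encoder
block, 64 CNN channels, 4 heads since 64 is not divisible by 6, pool 5 so
the pooled sequence keeps the full model's resolution-to-window
proportion, 5000 → 500). The reduced 10-epoch runs use lr 1e-3 and weight
decay 0.1 — a short-budget setting; the full-scale defaults keep lr 1e-4.
With these sizes the whole benchmark (generation, featurization, training,
evaluation) completes in a few minutes; held-out AUROC lands around
0.93–0.94 against a Bayes ceiling of about 0.97–0.98 across seeds.

## Numerical choices and degenerate inputs

* Gradients flow through a reverse-topological tape over numpy arrays
  (float64); first gradient contributions are stored by reference with
  copy-on-write on the second contribution.
* Max-pooling and max-reductions send gradient to the first argmax on
  ties.
* `bin_signal` requires the window length to divide evenly into bins;
  queries beyond track coverage return zeros.
* Windows wider than the chromosome shift to the origin (content beyond
  the chromosome end reads as zero signal).
* Undersampling with fewer negatives than positives keeps everything and
  warns; metric functions reject single-class inputs.
* Elements at interval distance ≤ 2.5 Mbp only; pair construction rejects
  cross-chromosome pairs.

## Limitations

* The autodiff engine is minimal by design; it supports the operations
  this model family needs and is not a general framework. Training speed
  is CPU-bound and roughly an order of magnitude slower than a compiled
  framework — consistent with KAN layers themselves being several times
  slower than MLPs of equal parameter count.
* Full-scale training (5000-bin windows, h = 180, 3 encoder layers,
  300 epochs) is supported by the code paths but is not practical on a
  single CPU; the test suite exercises that configuration only at the
  shape/correctness level.
* bigWig support requires pyBigWig; all other paths run on in-memory
  tracks.
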