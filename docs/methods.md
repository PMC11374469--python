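# Methods

This note documents the modelling assumptions, numerical choices and
limitations of `graphsurv`. Mathematical notation follows the README.

## Imaging-graph construction

A slide is downsampled 32× and foreground is detected by Otsu thresholding
of the HSV saturation channel (stained tissue is saturated, glass is not);
a `fixed` threshold mode (default 0.05 saturation) is available for
images where the bimodality assumption of Otsu fails. The slide is
tessellated into non-overlapping square patches (default 256 px; the
remainder at the right/bottom borders is truncated) and a patch is kept
when ≥ 50 % of its area is tissue. Nodes are foreground patches; edges
connect patches at Chebyshev distance 1 (8-connectivity, the default) or
Manhattan distance 1 (4-connectivity). Coordinates are 0-based row-major
grid indices with the pixel origin at top-left.

Every node must have degree in [1, 8]. Patches left isolated after
foreground filtering are dropped with a logged warning rather than
force-connected: the degree bound is an invariant of the representation
and no principled repair rule exists; a graph with fewer than two
connected nodes is rejected. Graphs are serialized one per slide to HDF5
(`H` float32, COO adjacency indices, coords, patch size and slide id as
attributes); node features round-trip bit-exactly.

Only plain PNG/TIFF inputs are supported. Pyramidal SVS readers and stain
normalization are out of scope.

## Patch featurization

Patch features come from a convolutional encoder trained with the NT-Xent
contrastive objective: two augmented views per patch form a positive
pair, all other in-batch views are negatives, similarities are cosine
scaled by a temperature (default 0.5, the conventional value), and a
2-layer projection head is used during training and discarded for
feature extraction. Augmentations are random color jitter
(brightness/contrast/saturation/hue jointly, strength 0.4), random
Gaussian blur (σ ∈ [0.1, 1]) and random crop (area scale ∈ [0.6, 1])
resized back to the input size; magnitudes are configurable since no
canonical values exist for H&E patches. Blur is skipped below σ = 0.01 so
that the zero-strength configuration is an exact identity.

The default backbone is a 3-block strided CNN (16/32/64 channels, global
average pooling, linear head) — sufficient for the synthetic and
small-image regimes this package targets; `resnet18`/`resnet50` select
deeper residual variants of the same numpy layers. No external pretrained
weights are bundled, so `pretrained_source` is `random` or `contrastive`.

## Gene-expression preprocessing

Raw counts (genes × samples) are filtered by two rules: zero
interquartile range across samples (computed on the normalized scale with
linear-interpolation / type-7 quantiles) and cumulative raw count ≤ 1.
The cumulative-sum rule is evaluated on raw counts — a threshold of one
is only meaningful on the count scale — and per-gene raw totals are
carried through normalization so the filter is idempotent. Duplicate gene
symbols collapse to the highest-mean row (the "maxMean" rule); matching
is case-sensitive exact string comparison for determinism.

Normalization is log2 counts-per-million with a pseudo-count (default
0.5): v = log2((c + p) / (lib + 2p) · 10⁶). A per-sample scaling hook
(e.g. TMM factors) can be multiplied into the library sizes; none is
applied by default. Cross-checked against edgeR's `cpm(log=TRUE)`, the
values agree to ~10⁻⁴ at moderate counts; edgeR additionally scales the
pseudo-count by relative library size, so low-count entries can differ in
the second decimal. Batch correction is an external preprocessing concern
and is not performed here.

Each signature's per-sample vector contains the normalized values of its
genes in list order; genes absent from the matrix are dropped with a
warning, and a signature matching nothing is an error. Per-signature
trainable affine encoders map the heterogeneous-length vectors to a
common dimension D.

## Architecture choices

Defaults follow the reference configuration L = 3 mixer layers, D = 64,
M = 5 signatures, 4 survival bins, batch size 1 (graphs vary in size).
Open points were resolved as follows:

* **Self-loops** are added before graph attention so each node's own
  features participate in its aggregation (standard GAT practice; without
  them a node's representation would be built solely from neighbours).
* **Single attention head**; LeakyReLU slope 0.2 and ELU as the
  aggregation nonlinearity (the GAT defaults).
* **GAM scaling**: scores are divided by √D by default (the standard
  scaled dot-product), with `gam_scale="dim"` available to divide by D.
* **Mixer MLPs**: two affine layers with GELU, expansion 2, dropout 0.1;
  layer norm is pre-norm, applied to the attention output inside the NML
  and to H' inside the CML, with both residual additions exact.
* **Gated pool width** is an independent hyperparameter (default 64):
  V, U map D → width and w maps width → 1.
* **FSM pooling** runs over the M fused signature tokens, following the
  N → M → 1 reduction; consequently TAH (node-pooling weights) is defined
  only for node-pooled (imaging-only) models, and the per-node saliency
  of the fusion model comes from SAM or CoAttn.
* **Initialization** is seeded Glorot-uniform; the head is a plain affine
  map (sigmoids live in the survival transforms).

## Survival machinery

Bin edges are the k/4 quantiles (type-7) of uncensored training times
only; the timescale is unit-agnostic (edges are learned from whatever
unit the data supply). Discretization is lower-inclusive half-open
binning with t₀ = 0 and t₄ = ∞. Hazards are 0-indexed, S(d) = Π_{k<d}
(1 − h_k), P(Y = d) = S(d)·h_d, so the uncensored loss is
−log S(Y) − log h_Y and the censored loss −log S(Y+1) — the standard
discrete-time bookkeeping. Log arguments are clamped at ε = 10⁻⁷ to keep
the loss finite under saturated sigmoids. Loss weights default to
α = β = 0.5 (only α + β = 1 is constrained).

The risk score is −Σ_{d=0}^{n_bins−1} S(d), the negative expected
survival mass over the modelled horizon. Note the absorbing last bin's
hazard does not enter this sum, so risk is strictly monotone in hazards
0..n_bins−2 only. The concordance index uses the exhaustive-pair
definition (ties count ½; a pair is comparable when the earlier time is
an observed event). Time-dependent AUC is the Uno-style IPCW
cumulative/dynamic estimator (via scikit-survival) with censoring weights
from the training split; evaluation horizons are the bin cut points that
fall strictly inside the observed follow-up window of the evaluation set,
and the metric is reported as undefined when no horizon qualifies (an
expected occurrence at very small n).

## Interpretability

SAM differentiates the pre-sigmoid logit of the earliest (highest-risk)
bin — the GradCAM convention of differentiating a raw class score —
with respect to the last mixer layer's N×D feature map; for the fusion
model the gradient is taken upstream of the genomic attention so the map
stays per-node. Channel weights are the node-averaged gradients, node
scores the absolute channel-weighted activations (magnitude rather than
ReLU: negative evidence is equally relevant to risk). Maps are min-max
rescaled per slide before thresholding; Dice is defined as 1 when both
the thresholded map and the annotation are empty and 0 when exactly one
is. Dropout is disabled during map computation so maps are deterministic.

## Synthetic cohorts

The generator emulates the three inputs jointly. Each sample is a full
H×W patch grid (default 16×16) of unit-variance Gaussian node features; a
random axis-aligned rectangle covering a fraction of the grid drawn from
`region_fraction_range` has its feature mean shifted by `effect_size`
(default 2.0). Rectangles were chosen because saliency evaluation needs a
contiguous region with a trivially exact ground-truth mask. Signature
values are noisy linear readouts of the region prevalence
(prevalence·w_m + N(0,1) per entry, loadings w_m fixed per cohort), and
survival follows the same discrete hazard family the model assumes:
per-year-bin hazard h = hazard_base + hazard_slope·prevalence (defaults
0.1 and 0.5), geometric event bin, uniform time within the bin (the loss
only sees bin membership, so the within-bin law is immaterial), and
censoring that replaces the event with a uniform earlier time at rate
0.2. Each sample draws from stream `seed + index`, so enlarging a cohort
never changes existing samples, and regeneration is bit-identical.

`region_fraction_range` defaults to (0.05, 0.9): tumor content in
resection cohorts spans nearly the full range, and the induced spread of
per-subject hazards (0.125–0.55) gives the cohort a Bayes-optimal
concordance of roughly 0.64 (ordering by true prevalence) — detectable
signal with realistic irreducible noise. Narrow prevalence ranges
compress the hazard spread until even the true risk factor barely ranks
patients above chance.

What passing on these cohorts does *not* show: robustness to stain and
scanner variation, non-rectangular or multifocal lesions, batch effects
in expression, hazards that violate the discrete-time factorization, or
informative censoring. The generator is single-batch and noise-free in
exactly the ways real cohorts are not.

## Training protocol and problem sizes

Adam (lr 2·10⁻⁴, weight decay 10⁻⁵), batch size 1, stratified k-fold
assignment by event indicator, bin edges refit on each fold's training
split only. Optional early stopping monitors validation loss with
configurable patience (off by default). All randomness flows from a
single integer seed (cohort, initialization, shuffling, dropout), making
runs exactly reproducible on one device.

The study-scale experiments in the test suite use a 200-sample cohort
(16×16 grids, 32 feature channels, 5 signatures), a 150/50 split and 30
training epochs; the demo uses 40 samples on 8×8 grids for a
quick-turnaround end-to-end run. These sizes keep a full verification
pass in the minutes range on a single CPU core while leaving the planted
signal comfortably detectable.

## Known limitations

* The hazard model assumes the discrete-time factorization; censoring is
  handled in the likelihood but not reweighted (no IPCW in the loss).
* Dense N×N attention limits graphs to ~10⁴ nodes; very large slides
  should be tessellated at a coarser patch size.
* Single-head attention throughout; no multi-resolution graphs.
* Gene-symbol matching is exact; identifier translation must happen
  upstream.
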