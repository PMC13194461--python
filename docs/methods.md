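# Methods

This note documents the models and procedures implemented in
`seedling3d`, the synthetic study conditions, the numerical choices, and
what the passing tests do and do not establish about real data.

## The synthetic study system

The generator emulates tray-grown eggplant seedlings at the cotyledon
stage as they appear in multi-view-stereo reconstructions after ground
alignment and scale calibration:

* **Tray**: a 25 cm × 25 cm plate at z = 0 with four 1.5 cm walls,
  sampled at 250 points/cm² (semantic label 0). Together with the walls
  this yields ≥ 75 % background points per scene, matching the extreme
  foreground/background imbalance of real tray regions (130–190 k tray
  points versus a few thousand plant points per region).
* **Seedlings**: a 6 × 6 grid at 41 mm pitch, 4 trays = 144 plants.
  Each plant is a cylindrical hypocotyl (label 1) topped by two planar
  elliptical cotyledons (label 2, aspect ratio 0.45, petiole gap 0.15 cm,
  opposite azimuths), sampled at 400 points/cm², with outward unit
  normals and fixed per-class colors. The attachment height is chosen so
  the noise-free maximum z equals the nominal plant height exactly; one
  sample anchors each geometric extreme so the cloud extent matches the
  ground truth within a sampling step.
* **Growth**: traits are monotone interpolations over anchors at
  24/48/72/96/120 h — height 1.20→2.90 cm, stem diameter
  0.070→0.125 cm (0.102 cm at 72 h), inclination (leaf normal vs +Z)
  15°→72°, per-cotyledon area 0.50→1.35 cm² — with per-plant
  multiplicative jitter (lognormal, σ = 0.06) drawn once per plant so
  monotonicity holds along each plant's time series. These spans follow
  the reported ranges (height below 1.5 cm and diameter 0.06–0.08 cm at
  24 h, area below 0.8 cm² early, near-maximal inclination at 120 h).
* **Noise**: Gaussian displacement along the surface normal,
  σ = 0.01 cm; ground truth is recorded pre-noise.

The generator does **not** model leaf curvature by default (a bend-radius
knob exists but defaults to flat so plane-fit angle recovery is exact),
self-occlusion, reconstruction holes, color variation, soil texture, or
true leaves. Passing tests therefore demonstrate correctness of the
algorithms under clean, fully-sampled geometry — not robustness to the
artifacts of real photogrammetry.

## Preprocessing

* **Purification** removes exactly the label-0 points, preserving order
  and the source cloud.
* **Ground alignment**: RANSAC plane detection (default 1000 three-point
  hypotheses, 0.05 cm inlier threshold, seeded; winning hypothesis
  refined by a total-least-squares fit of its inliers) followed by a
  Rodrigues rotation taking the plane normal to +Z. An anti-parallel
  normal is handled by a fixed 180° turn about a perpendicular axis.
* **Scale calibration**: `k = L_real / L_virtual` from the known 25 cm
  tray side.
* **Augmentation** applies, in a fixed order, dropout (10–20 %) →
  rotation (±10° per axis) → scaling (0.7–1.3) → translation (±0.1 cm
  per axis) → jitter (σ = 0.01 cm clipped at ±0.05) → shuffling. Every
  sampled parameter is recorded in a per-sample ledger
  (`sample_id, op, param_name, param_value`), and the geometric
  operations invert exactly (≤ 1e−9); dropout and jitter are flagged
  irreversible. The fixed order makes the ledger inverse well defined.
* **Partitioning** assigns whole pots (trays) to train/val/test at
  7:1:2 by largest-remainder rounding with at least one pot per split,
  so no pot's timepoints straddle splits (144 pots → 101/14/29).

## Segmentation network

A hierarchical encoder/decoder on 2049-point scenes. Input features are
scene-centered unit-sphere-normalized xyz plus unit normals (6 channels;
RGB is optional and off by default — synthetic colors are class-constant
and would leak labels). Encoder stages perform farthest-point sampling,
radius grouping (k nearest within the ball, padded by the nearest
neighbor), a shared MLP and max pooling. Decoder stages interpolate by
inverse-square-distance over the 3 nearest coarse points (exact copy at
coincident points), concatenate the skip features, refine, and map to the
output width. A 3-class per-point head ends the network.

The four improvements, independently toggleable (8 ablation
configurations):

* **MS** — multi-scale residual blocks after each encoder stage:
  parallel 1D convolutions with kernels 1/3/5 along the point sequence,
  concatenated and fused 1×1, wrapped with an identity (or 1×1-projected)
  residual shortcut. Convolving an unordered set requires a canonical
  ordering; we use the farthest-point-sampling output order, which is
  deterministic given the input order, and document results as
  order-dependent. Sequences shorter than the kernel fall back to
  reflective extension.
* **SE** — squeeze-and-excitation channel attention
  `s = σ(W₂ δ(W₁ z))` with z the per-channel mean over points; inside
  each MS block when MS is on, standalone after each stage otherwise.
  Zero weights give an exact ×0.5 gate.
* **GC** — global context at the decoder end:
  `F + broadcast(W_u δ(W_d g))` with g the mean feature; exact identity
  at zero recovery weights, permutation-invariant pooling. Compression
  ratio r = 4 for both SE and GC (small widths make larger ratios
  degenerate).
* **Improved FP** — the fused skip features pass through an MS residual
  block before the final 1×1 mapping; with the toggle off, a plain
  two-layer shared MLP reproduces the baseline decoder. The improved
  layer is built from MS blocks, so it follows the MS toggle in the
  ablation grid.

Training: unweighted cross-entropy (mean negative log-softmax of the true
class), Adam (lr 1e−3, weight decay 1e−4 added to the gradient), step
decay ×0.5 every 10 epochs, batch 16 (8 in the compact benchmark),
150 epochs nominally; the best-validation-mIoU weights are retained.
Everything is seeded and single-threaded deterministic. The engine is a
small numpy reverse-mode autodiff (float32 model math; float64 available
for exactness tests); sampling/grouping indices are computed once per
scene and cached across epochs.

Initialization uses He scaling only on ReLU-followed layers and
unit-variance scaling elsewhere, with a sub-unit gain on the MS fuse
layer so residual main branches start small — without this the
12-layer-deep linear stacks explode at initialization.

Metrics: per-class precision, recall, F1 and IoU from exact TP/FP/FN
counts; overall accuracy ΣTP/N; mIoU is the arithmetic mean of per-class
IoU. Evaluation aggregates confusion counts over all scenes of a split
before computing metrics (micro-averaging), so it is invariant to scene
order and concatenation. Classes absent from both prediction and truth
(the tray class after purification) are excluded from the mIoU average;
undefined 0/0 metrics are reported as 0. The choices of micro-averaging
and the 0/0 convention were open; both keep empty-class scenes from
inflating scores.

### Compact benchmark (problem sizes)

The standing semantic benchmark trains the full model on 64 purified
default scenes (one tray each, timepoints cycling over the five
observation times), split 7:1:2 by tray, 2049 points per scene, 30
epochs, batch 8, with a compact architecture (3 stages sampling
512/128/32 points, widths 32/64/128, decoder widths 64/48/32, ~0.5 M
parameters). These sizes make the run a few minutes on one CPU while
leaving the task non-trivial; on this easy geometry the full model
reaches ≈ 98 % overall accuracy and ≈ 93–94 % mIoU (stem IoU is the
limiting class), comfortably above the real-data reference values it
surrogates. Nothing about real-data performance follows from this —
the benchmark establishes that the implementation trains, converges,
and separates the classes it is given.

## Instance segmentation

DBSCAN per semantic class with `eps = α · eps_est` (α = 0.8 stems, 1.2
leaves), `min_samples` = 5, Euclidean metric; the ball-tree/kd-tree
settings are acceleration hints only and do not affect results.

`eps_est` is the median 4-NN distance times a spacing factor of 3. The
factor is required, not cosmetic: under Poisson surface sampling the
k-distance of a typical point sits at the median of its distribution, so
an eps of 0.8 × median leaves the typical stem point below the
`min_samples` core threshold and stems shatter into fragments. The
factor is bounded below by requiring a ≥ 99.9 % core fraction at
α = 0.8 (factor ≥ 2.7 for Gamma-distributed squared 4-NN distances) and
above by the smallest structural separation — the 0.3 cm petiole gap
between cotyledons at α = 1.2 (factor ≤ 4.4); 3.0 sits mid-window.
`estimate_eps` exposes the raw median at factor 1.

Assembly: each stem cluster seeds one instance (ids in cluster order);
each leaf cluster attaches to the stem with the nearest XY centroid
within 2 cm (ties to the lower id), else it is an orphan. Noise points
are excluded (an optional flag reattaches them within 2·eps). Instance
scores use optimal one-to-one matching by point IoU
(Hungarian assignment); matched pairs with IoU ≥ 0.5 are true positives,
and mIoU averages the matched IoUs. The matching rule was unspecified
upstream; optimal assignment is the strictest standard choice.

## Trait estimators

* **Height**: `z_max − z_min` of the plant's points.
* **Stem diameter**: stem points with z in
  [z_min + 0.45, z_min + 0.55] cm are denoised by statistical outlier
  removal (k = 8, 2σ), projected to XY, and fit 5 times by Welzl's
  minimum enclosing circle on seeded 80 % subsamples; D = 2 × mean
  radius. A slab of [z_min + 4.5, z_min + 5.5] cm is available behind a
  `literal_slab` flag: that printed range exceeds cotyledon-stage plant
  heights, so the default slab keeps the stated 0.5 cm measurement
  height instead. An empty slab yields a flagged missing value.
* **Inclination**: RANSAC plane per cotyledon (200 iterations, 0.05 cm
  threshold, PCA refinement of the best consensus set), 3 seeded repeats
  averaged, then averaged over the two cotyledons;
  `θ = arccos(|n⃗·ẑ|)·180/π`. θ is the angle between the leaf normal
  and the vertical; the textual trait definition (angle between the leaf
  plane and the vertical plane) is its complement, so both θ and 90°−θ
  are reported without choosing between the conventions. The two largest
  leaf clusters of an instance are taken as its cotyledons; extra
  clusters are flagged.
* **Area**: ball-pivoting reconstruction at 0.2 cm ball radius, areas by
  Heron's formula, each unique triangle counted once. The pivoter keeps
  an advancing front of edges, evaluates all pivot candidates of an edge
  vectorized, and accepts the smallest-rotation contact; vertex normals
  constrain the ball to the outer surface side, which keeps thin leaf
  sheets single-sided (without this the area doubles). Clouds larger
  than 350 points are subsampled before meshing (speed only). On mesh
  failure an optional retry enlarges the ball ×1.5.
* **Scale restoration**: coordinates are divided by the augmentation
  scale traced via the sample id in the ledger, then multiplied by the
  tray calibration factor k, before any trait is measured.

### Estimator accuracy and known limitations

On noise-free synthetic plants, height is exact to the sampling step,
diameter within 2 %, inclination within 0.5°, and area within ~5 % at
dense sampling. Two systematic effects remain under the default
conditions:

* **Mesh boundary bite**: a triangulation ends at the sampled hull, about
  half a point spacing inside the true leaf boundary, so areas are biased
  low by ≈ perimeter × spacing/2 (≈ 5–7 % at 400 points/cm²). The bias
  shrinks with density and stays within the 10 % recovery band for ~97 %
  of plants in the default study.
* **Minimum-enclosing-circle noise bias**: the MEC is a max-type
  estimator, so radial surface noise inflates the fitted radius by
  roughly 0.6–1 σ for the ~15 points of a default stem slab. With
  σ = 0.01 cm on stems of true diameter 0.07–0.125 cm this is a
  +13–20 % relative error, and only ~27 % of plants recover D within
  10 % — an intrinsic property of the published estimator under this
  noise level, not an implementation defect (the noise-free fit is exact
  to 2 %, and the MEC itself matches an O(M³) brute-force search to
  1e−9). A least-squares circle fit would remove the bias but would be a
  different estimator.

## Reproducibility

All randomness flows from explicit seeds (generators per plant, stage
seeds derived from the pipeline's global seed by a fixed counter scheme);
regenerating a dataset with the same seed is byte-identical, and training
runs are deterministic given (configs, scenes). Checkpoints store weights
plus the full architecture configuration.
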