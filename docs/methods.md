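# Methods

This note records the models, the defaults and the numerical choices
behind `protoshape`, and what the synthetic corpus does and does not
establish.

## Problem setting and model

The package addresses K-way classification of rigid objects from very
few labeled photographs (single digits per class), in the regime where
object *shape* is the dominant class cue while color, texture and
illumination vary. The classifier is a prototypical network over a
two-branch embedding:

* **image branch** — a CNN applied to the background-removed RGB crop;
* **shape branch** — the frozen encoder of a convolutional autoencoder
  applied to the binary object mask.

The two vectors are concatenated per sample. Prototypes are arithmetic
means of the H support embeddings of a class; queries go to the nearest
prototype in squared Euclidean distance, and episodic training minimizes
cross-entropy over softmax(−d²) — the canonical logit map for
prototypical networks (the distance-to-probability map is otherwise
underdetermined). Inference is deliberately non-episodic: one fixed
support set, embedded once, classifies single test images, which is the
deployment mode (swap supports, never retrain).

Assumptions worth stating: classes are closed-set (every query belongs
to one of the K supported classes); masks are binary and roughly
object-tight after cleanup; one object per coupled sample.

## Preprocessing chain

`open_mask` (erosion then dilation, square k=5 kernel, zero padding at
the canvas border) → `largest_component` (8-connectivity; ties broken
by the smallest top-left bounding-box corner in row-major order, logged)
→ `remove_background` (zero outside the mask) → `crop_resize`
(isotropic: the tight bounding box's larger side is scaled to
128 − 2·20 = 88 pixels and centered, guaranteeing an empty 20-pixel
frame on the *output* canvas; masks resampled nearest-neighbor so they
stay exactly binary, RGB bilinear and re-zeroed outside the resized
mask). The chain is idempotent on its own output at the mask level,
which the suite asserts on generated objects.

Degenerate inputs: an empty mask after opening raises; a single-pixel
bounding box raises; a mask of all ones is legal for
`remove_background` (identity) but rejected upstream by the frame
invariant.

## Augmentation and folds

Each original produces exactly 80 derivatives: {identity, horizontal,
vertical, both} flips × 20 rotations of 18° (index 0 = identity, so the
×80 factor includes the untouched original). Rotations are
counterclockwise about the mask's center of mass in continuous
(row, col) coordinates; masks rotate nearest-neighbor, RGB bilinear with
zero fill. Rotation can clip object corners at the canvas edge; the
clipped fraction is logged and the 20-pixel frame keeps it marginal.

Folds are assigned at the origin-photo level, class-stratified
(per-class counts differ by ≤1 across folds), deterministic in
(origin set, seed) and independent of input order. Episode sampling
additionally forbids any origin from appearing in both support and
query of one episode — without this, a rotated copy of a support image
could appear as its own query and make episodes trivially easy. A
consequence at small scale: a fold must hold at least H+J origins per
class to generate validation episodes, which sizes the test fixtures.

Memory note: episodes draw origins first and apply one random
flip×rotation on demand instead of materializing the 80× corpus
(13,920 rasters ≈ 1.4 GB at float32); counting operations still
enumerate the full set lazily and verify exact cardinalities.

## Shape autoencoder

Architecture grid: 3–5 blocks, each halving resolution either by
stride-2 convolution (pooling off) or stride-1 convolution + 2×2 max
pooling; the decoder mirrors with stride-2 transposed convolutions and
a sigmoid output so reconstructions live in [0,1] against binary
targets. Channels default to 4·2^i per block; the shape embedding is
the flattened bottleneck (3 blocks: 16 channels × 16² = 4,096). Training
uses MSE with Adam, lr 10⁻³, weight decay 10⁻⁵, batch size 20; the grid
is scored by validation SSIM (11×11 Gaussian window, σ 1.5, data range
1) with ties going to fewer parameters; Dice is computed on the
reconstruction binarized at 0.5 (the threshold is otherwise
unspecified and 0.5 is the symmetric choice).

Capacity sanity: a single 20-mask batch is driven to Dice ≥ 0.99. With
this optimizer and architecture the trajectory crosses 0.99 at roughly
1,700 full-batch steps (0.97 at 500), so the check budgets 2,500 steps
(~2.5 min on one CPU in float32).

## Episodic training

SGD (momentum 0.9), lr 10⁻³ decayed ×0.1 at epoch 30, weight decay
10⁻⁵, 50 meta-training and 50 meta-validation episodes per epoch as
defaults; per-channel input normalization is estimated on the training
fold and stored in the checkpoint. Gradients flow through the image
branch only; the shape encoder is frozen. Backbones: `small_cnn`
(4 conv blocks + global average pooling, 64-d output) as the CPU
default, plus ResNet-18/50-style residual stacks built on the same
NumPy toolkit; pretrained weights are not bundled and requesting them
raises. All layers are verified against central finite differences, and
the episode-loss gradient with respect to the embeddings is verified
the same way.

## Reliability score

`ts_inverse` uses plain (non-squared) Euclidean distances — the ratio
of nearest to second-nearest prototype distance; `classify` reports
squared distances (its hand-checkable contract) and the two conventions
are kept explicit. The 0/0 case returns 1 (maximal ambiguity), logged.

The refined score projects support ∪ {query} by exact PCA (fit includes
the query, which is what makes the dimension bound min(D, K·H)+1 points
→ ≤ K·H retained directions), keeping the smallest leading set reaching
95% cumulative variance. Zero total variance yields a dimension-0
projection and RS ≡ 1, logged. The score itself is the expectation of
min(1, ‖q̃−s₁‖/‖q̃−s₂‖) over independent uniform draws from the two
hulls: the ratio is anchored at the projected query, and clipping at 1
preserves the stated [0,1] codomain (raw hull ratios can exceed it).
Hull points are Σ wᵢ pᵢ with Dirichlet(1,…,1) weights obtained by the
exponential-spacings map from Latin-hypercube-stratified uniforms (one
LHS dimension per hull vertex). Batches of 128 pairs are drawn until
the standard error of the running mean falls below 0.005 or 8,192
samples are used; everything is deterministic under the seed. A zero
denominator contributes ratio 1, logged.

## Evaluation conventions

Per-epoch episode accuracies are summarized as mean and *population*
STD (ddof 0); cross-fold summaries are median and IQR with
linear-interpolation quantiles — both conventions are configurable
because neither is canonical. One-vs-rest AUROC/AUPRC take
softmax(−d²) as the class score. Misclassification distributions
normalize over wrong predictions per true class; classes absent from a
test set appear as explicit nulls, never silently dropped.

## Synthetic corpus

The generator emulates the study conditions: 8 shape families with
pairwise non-congruent silhouettes (disc, bar, L, T, ring, cross,
ellipse, 5-petal star; verified by exhaustive 18° rotation/flip
alignment, IoU < 0.95), hard 0/1 masks (no anti-aliasing, so morphology
and Dice are exact), homogeneous per-image background from a small
palette, three global illumination modes (neutral/cool/warm) that act
on RGB only, and per-class base colors with ±20% multiplicative jitter
plus mild texture noise — instruments keep a brand-like characteristic
color, while per-sample appearance varies. Scale (45–70% of canvas),
position jitter and orientation are random per object. Multi-object
"preparatory table" scenes place objects without bounding-box overlap
and can degrade per-object resolution (downsample + blocky upsample) to
emulate small devices in a wide field of view. Default canvas 128×128.

What the corpus does *not* emulate: perspective, shadows, specular
highlights, occlusion, segmentation artifacts of real promptable
segmenters, and intra-class shape variation across brands. Passing
tests therefore establish the *mechanics* of the pipeline (counts,
invariants, estimator correctness, trainability on separable data), not
photographic-domain accuracy; headline accuracies on real photographs
are out of scope here.

`gen_embedding_clusters` provides labeled spherical Gaussian clusters
whose minimum centroid separation is expressed in units of within-class
spread, used to test the prototype head and the reliability score in
controlled-separability conditions.

## Problem sizes used by the suite

Test fixtures are sized for a single CPU: the training sanity run uses
3 classes × 8 originals, 2 folds, 5 epochs × 25 episodes (meta-val
accuracy reaches 100%); the pipeline smoke run uses the same corpus
with 2 tables of 3 objects; the capacity check uses 20 masks. The
acceptance script runs the full 87-original augmentation arithmetic and
the 10⁶-sample Monte-Carlo oracle at full size.

## Known limitations

* Pure-NumPy training is single-threaded and slow by deep-learning
  standards; defaults are sized for hundreds, not millions, of images.
* No batch normalization in the backbones; very deep configurations
  (ResNet-50) train poorly from random init at these learning rates and
  exist mainly to exercise the architecture surface.
* The reliability score inherits the high variance of 5-point hulls:
  it ranks classes by reliability well, but single-prediction
  thresholds are conservative (many items flagged unreliable).
* The default segmenter assumes a homogeneous background; real
  deployments should plug an external promptable segmenter into the
  `Segmenter` interface.
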