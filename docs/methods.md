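# Methods

## Problem and model

The task is K-way species classification of sawn-timber boards from RGB
surface images. Boards are rectangular solids of arbitrary dimensions, so
inputs are variable-size images with aspect ratios far from square;
preprocessing only rescales *in equal proportion* (default factor 0.2, i.e.
one fifth of the linear size) and never crops, pads or squares.

The classifier is a hybrid:

- **Trunk.** A ResNet-style stack of bottleneck residual blocks
  (1×1 → 3×3 → 1×1 convolutions with ReLU, identity shortcut
  H(x) = F(x) + x, 1×1 projection shortcut when shape changes). The stem is
  a stride-2 7×7 convolution followed by a stride-2 3×3 max-pool; each stage
  after the first halves resolution, so the default three-stage trunk has
  total stride 16. The full configuration uses stages of (3, 4, 23) blocks
  with (256, 512, 1024) output channels — deliberately truncated where the
  map is N × M × 1024; no 2048-channel stage exists here.
- **Attention.** After each stage (default placement; per-block is
  configurable), a channel gate then a spatial gate multiply the map.
  Channel gate: spatial average-pool and max-pool each yield a C-vector;
  both pass through the *same* 1×1 convolution (default no bottleneck,
  `channel_reduction=1`; a reduce–expand pair is configurable), the
  responses are summed and squashed by a logistic sigmoid. Spatial gate:
  channel-wise mean and max maps are stacked and convolved with a single
  odd kernel (default 7×7, same-padding) to one channel, then
  sigmoid-squashed. All gate values are strictly inside (0, 1); the sigmoid
  output is clamped to the open interval at float64 resolution so the
  invariant survives saturation.
- **Spatial pyramid pooling.** The final map is pooled over 4×4, 2×2 and
  1×1 bin grids (16 + 4 + 1 = 21 blocks). Bin boundaries follow the
  adaptive rule bin *i* of *n* over extent *e* = [⌊ie/n⌋, ⌈(i+1)e/n⌉): bins
  may overlap by one cell but always cover every cell, for every extent —
  the fixed window/stride alternative leaves gaps (e.g. extent 7 into 4
  bins). Each block contributes the per-channel **maximum** (mean is
  available behind `pool_statistic="mean"`); max is the standard pyramid
  convention and emphasises texture extrema. Descriptor rows are ordered
  level-major (16, then 4, then 1), row-major within a level; flattening
  puts channels innermost. The minimum admissible image side is
  trunk stride × largest grid = 16 × 4 = 64 px, and undersized inputs fail
  with that number before any weights are touched.

## Two-stage training

Stage 1 trains trunk + one affine head (flattened 21·C descriptor → class
logits; no hidden layers — the pyramid already fixes the input width) with
softmax cross-entropy and Adam (β₁ 0.9, β₂ 0.999, ε 1e−8). Defaults follow
the protocol this package implements: learning rate 1e−4, effective batch
size 16. Because images differ in size there is no batch axis; gradients
are accumulated image-by-image and applied once per batch. Epoch count is a
free parameter (default 30 in `TrainConfig`; the desk-scale runs below use
3 at lr 1e−3, which is enough for the easy synthetic classes).

Stage 2 freezes every trunk parameter (extraction is checksum-verifiably
read-only), exports a FeatureTable (one row per image, width 21·C), and
fits classical heads: `linear_margin` = SVC with linear kernel, C = 1.0,
one-vs-rest; `boosted_trees` = XGBoost with max depth 3, learning rate 0.2,
100 rounds, no early stopping (determinism); `linear_softmax` = multinomial
logistic regression. Descriptors are not standardised by default.

## Evaluation protocol

Per class, ⌈0.2·n⌉ samples are held out as the test set (ceiling is the
only rounding consistent with the published per-class test counts for
totals 807/797/805/801/969 → 162/160/161/161/194); the remaining samples
are dealt into k = 4 folds whose sizes differ by at most one, the larger
folds taking the highest ids (again matching the published fold grid,
e.g. 645 → 161/161/161/162 and 775 → 193/194/194/194). Splits are
stratified per class and are pure functions of (manifest, k, fraction,
seed). The test set is untouched by cross-validation; only
`grainkit evaluate --test` (or `evaluate_test`) uses it, and an internal
leak assertion fails loudly if a test index ever reaches a training input.

Metrics: per-class precision, recall, F1 (harmonic mean) and overall
accuracy from the confusion matrix; empty denominators are reported as NaN
(null in JSON), never coerced to 0. Cross-validated tables average each
metric *value* across folds — the convention the published prediction
matrices use, which differs from recomputing metrics on pooled counts; the
pooled-count variant is emitted alongside under its own key. The balance
statistic `f1_range` = max − min of the fold-averaged per-class F1.
Display rounding (3 d.p. for CV tables, 2 d.p. for test tables) is applied
last.

## Synthetic boards

The generator emulates the study conditions, not wood optics. Each style
defines base colour, grain period, orientation, contrast, warp amplitude
and knot density; the texture is `1 + 0.5·contrast·sin(2π(t + warp)/period)`
along the orientation axis, with `warp` a Gaussian-smoothed uniform field
scaled by the distortion amplitude, times radial knot-darkening discs whose
count is Poisson in the image area. Per-image seeds are spawned from the
dataset seed by a counter-based scheme, so outputs are bit-reproducible and
order-independent. Defaults: five styles named after the study species
(beech, ash, birch, cherry, fir) with distinct colours and grain statistics;
per-class counts default to the published totals (807, 797, 805, 801, 969);
rectangular sizes, default heights 64–128 px and widths 128–512 px
(aspect up to 1:8, never forced square).

What passing tests on this data do and do not show: classes are separable
by colour and low-order texture statistics, so high accuracy here
demonstrates that the pipeline is wired correctly (size invariance,
no leakage, heads learn from frozen descriptors) — it says nothing about
accuracy on real timber, which varies in illumination, moisture, defects
and camera response that the generator does not model.

## Scale of the bundled runs

The test suite and `scripts/acceptance.py` use the tiny trunk
(1 block per stage, 8/16/32 channels — architecture identical in kind,
21 × 32 descriptor) on datasets of 3–5 classes × 8–20 boards of 64–96 ×
96–192 px, 1–3 epochs at lr 1e−3. These sizes were chosen as the smallest
at which every contract is exercised meaningfully; the full-scale
configuration is available but is not a test vehicle.

## Numerical and design choices

- Pure-NumPy reverse-mode autodiff (float64); convolution via im2col,
  max-pool backward routes to the argmax, reduction-max splits gradient
  evenly among ties. Verified against central finite differences.
- No batch normalisation in the trunk: at the tiny scale used here,
  He-initialised ReLU bottlenecks train stably without it, and omitting it
  keeps single-image training exactly deterministic.
- "One feature per block" in SPP is read as max-pooling; the logistic
  sigmoid is used wherever a squashing function is required.
- Attention placement (per stage end, channel → spatial serial order) and
  the 7×7 spatial kernel are defaults where the design was genuinely open;
  both are configurable.
- Whether the 1024-channel pre-pyramid map arises from truncation or from a
  2048→1024 projection is an open reading; this package truncates.
- Stage-1 shuffling, Adam state and head fitting all derive from explicit
  seeds; stage-2 (extraction + linear heads) is bit-reproducible, stage-1
  reproducibility is at the level of logged per-epoch losses under
  single-threaded execution.

## Known limitations

- The full (3, 4, 23)-block trunk is provided but CPU training at that
  depth is impractical here; no pretrained weights are bundled.
- The margin head uses one-vs-rest with C = 1.0; no hyperparameter search.
- The generator's knots are radially symmetric discs and grain is
  monochrome modulation of a single base colour — adequate for class
  separability, far from photorealism.
- Undefined-metric propagation through fold averaging keeps NaN (a class
  never predicted in any fold stays undefined rather than being imputed).
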