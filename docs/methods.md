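# Methods

This note documents the models and procedures implemented in `leafcount`,
the parameters that matter, the synthetic data the package is validated on,
and the numerical/design choices made where the design was genuinely open.

## Sliced inference

High-resolution leaf photographs are decomposed into fixed `S x S` windows
(default S = 640 px) with overlap ratio `alpha` (default 0.2); the stride is
`round(S * (1 - alpha))` = 512 px.  Coordinates are 0-based and half-open
throughout the package; Pascal-VOC's 1-based inclusive convention is
converted only at the XML boundary, so `width = x_max - x_min` holds with
no off-by-one anywhere else.

Edge handling: when a window would cross the image border, its origin is
clamped so the window ends exactly at the border.  This keeps every network
input at the fixed `S x S` size at the cost of a larger overlap for the
final row/column (the alternative — emitting smaller partial tiles — would
force the detector to handle variable input sizes).  A 4080x3072 frame
yields 8 x 6 = 48 windows with clamped last origins (3440, 2432).

Training-time slicing distributes ground-truth boxes to windows when at
least `min_visibility` (default 0.25) of the box area is visible, clipping
to window bounds; windows without any target are discarded as
uninformative.  Inference-time fusion remaps per-window boxes by their
window origin and applies class-wise greedy NMS (keep highest confidence,
suppress same-class boxes with IoU above 0.5; confidence ties broken by
input order, which makes the merge deterministic).  Default inference
thresholds are confidence 0.3 and NMS IoU 0.5.  A known limitation shared
with all NMS-fused sliced inference: a target cut near a window edge can
yield a partial box whose IoU with the full box from the neighbouring
window falls below the NMS threshold; targets lying wholly inside the
overlap band are fused exactly.

## Mask refinement

The foreground-leaf mask from any segmenter is refined in three stages:

1. **Connected components** (8-connectivity): components smaller than
   `area_threshold` are dropped.  A threshold below 1 is read as a fraction
   of image area (default 1%), otherwise absolute pixels.  With
   `keep_largest_only` (default) exactly the largest component survives,
   ties broken by lowest label index.
2. **Morphological opening** with a disk element, then an explicit hole
   fill.  The element radius defaults to 5 px at 2048-px image width,
   scaled linearly with the actual width (a fixed physical smoothing scale
   across resolutions).  Note that opening cannot fill holes; the hole fill
   (background regions not connected to the image border become foreground)
   is implemented as a separate explicit step after opening.
3. **Bilateral edge refinement**: the binary mask is treated as a
   continuous field, bilateral-filtered (spatial sigma 3 px, range sigma
   0.3 on the 0-1 intensity scale) and re-binarized at 0.5.  The output is
   contained in the dilation of the input by the filter support radius, and
   an ideal step edge is a fixed point.

Counting restricts to the refined mask by **gating**: a detection is kept
iff at least `min_inside_fraction` (default 0.5) of its box area lies on
mask foreground.  Gating is preferred over blanking the image outside the
mask before detection because the detector then never sees artificial black
borders and raw detections remain available for inspection; blanking is
available behind `PipelineConfig.blank_outside`.  Whether insects partially
off the leaf should count is a survey-protocol question; the 0.5 default is
surfaced in config.

## Neural blocks

All blocks run on an in-package numpy reverse-mode autodiff core
(`leafcount.nn`): a define-by-run graph over `float32`/`float64` arrays
with convolution via explicit im2col, written so that every oracle test can
compare against nested-loop references and finite-difference gradients.

**CRW.** `X_out = X * sigmoid(W2 . relu(W1 . concat(GMP(X), GAP(X))))`,
with `W1: 2c -> c/4`, `W2: c/4 -> c`, both bias-free.  Global max pooling
routes its gradient to the first maximal position per channel, keeping
backward deterministic under ties.

**SCRF / ACRF / MCRFPN.**  The fusion equations name `Up`, `Down` and
channel bookkeeping without defining them; the choices here are:
`Down` = stride-2 3x3 convolution, `Up` = 2x nearest-neighbour
interpolation, every branch first projected to a common width by 1x1
convolution, and a 1x1 projection after CRW.  ACRF's two downsampled inputs
use separate projections.  For a three-level pyramid the boundary levels
lack a shallower or deeper neighbour, so they fuse with reduced variants:
top-down `P5' = proj(C5)`, `P4' = SCRF(C3, C4, P5')`,
`P3' = CRW-fusion(C3, Up(P4'))`; bottom-up `P3'' = proj(P3')`,
`P4'' = ACRF(P3', P4', P5', P3'')`, `P5'' = ACRF(P4', P5', -, P4'')` with
the deep branch absent.  The bottom-up levels are computed finest-first so
each ACRF can consume the already-updated `P''` of the previous level.

**DyCM-Conv.**  Queries are a 1x1 projection of the feature map; keys a
1x1 projection of its `S_r x S_r` adaptive average pool (defaults:
G = 4 groups, S_r = 4, qk channels = C/2; Q/K carry no bias so zero input
gives zero relevance).  Each pixel's relevance row (length S_r^2) passes
one shared learnable linear layer whose output splits into k_large^2 = 25
and k_small^2 = 9 logits, each slice softmax-normalized — kernels are
therefore simplex-valued at every position.  The two dynamic kernels are
applied depthwise (shared across the channels of their group, no
cross-channel mixing) with zero padding, and merged with a static 3x3
depthwise branch by **elementwise sum** (the defining description says only
"merged"; concat-then-project was the alternative and the sum keeps the
block shape- and width-preserving).  `DyCM-C3K2` wraps this as the
bottleneck of a split / bottleneck / concat / 1x1-fuse block with the
cross-stage residual retained.  A registry maps the names `c3k2`,
`dycm_c3k2`, `fpn`, `mcrfpn` to builders so ablation configs toggle modules
without code changes.

## Detector scaffold

The host detector is deliberately minimal — the package's contribution is
the blocks and the pipeline, not a faithful reproduction of a production
YOLO: a strided conv backbone (stride-4 stem, then three stages at strides
8/16/32, widths 16/32/64 in the tiny profile) with instance normalization
between stages for batch-size-independent training stability; an
anchor-free head per level predicting objectness, class scores and
softplus-positive l/t/r/b distances scaled by the stride; center-sampling
assignment (cells inside the box within 1.5 strides of its center; boxes
routed to levels by sqrt(area) with the 32/96 px COCO boundaries; contested
cells go to the smallest box); and losses = class-balanced BCE on
objectness + BCE on class scores + IoU loss (weight 2) on boxes.  Optimizer
is SGD with momentum 0.937, weight decay 5e-4, initial learning rate 0.01,
and gradient-norm clipping at 10.  Absolute accuracy parity with
GPU-trained detectors is out of reach by design; the scaffold exists so the
blocks can be trained, ablated and tested end to end on one CPU.

## Synthetic scenes

The generator targets the *statistical* structure of single-leaf survey
imagery, not photometric realism: a harmonically perturbed ellipse forms
the primary leaf (smooth irregular boundary, mild multiplicative texture);
insect counts per class are negative binomial, parameterized by the survey
moments (adults mean 15.50 / SD 29.15, nymphs 5.46 / 24.31 — the
distribution family is a modelling choice; only moments are specified, and
NB is the standard overdispersed count model); median box sizes are
24x25 px (adults) and 19x19 px (nymphs) with ±20% uniform jitter; adults
render bright-whitish, nymphs pale yellow-green, both as shaded ellipses;
dark dead-insect-like distractor spots sit on the leaf but are absent from
ground truth; and decoy leaves at the frame border carry their own insects
(default 20% of primary counts), recorded separately, strictly off the
primary mask.  Per-class counts are drawn independently (no co-occurrence
structure is specified for them).  Placement is rejection sampling with an
IoU cap of 0.3 between boxes; because overdispersed counts produce very
dense scenes, the cap is dropped after a bounded number of retries rather
than failing, and a placement error (naming the offending parameter) is
raised only when a box cannot be placed at all.  The default frame is
1280x960 (a 4080x3072 "full-scale" preset exists); all randomness flows
from one integer seed and scenes are bitwise reproducible.

What passing tests on these scenes does **not** show: robustness to real
leaf venation, specular highlights, motion blur, instar-stage morphology,
or crop-species appearance differences.  The scenes establish that the
geometry, the counting logic, the mask gating and the trainability of the
blocks are correct — not field accuracy.

## Desk-scale problem sizes

The validation experiments are sized for a single CPU: the end-to-end check
generates 300 scenes (8:1:1 split), slices them at S = 640 / alpha = 0.2
with empty-tile discard, and trains the DyCM + MCRFPN tiny profile for 10
epochs of 120-tile seeded subsamples at batch size 2 — about a thousand
optimization steps, after which held-out mAP50 on synthetic tiles
comfortably exceeds 0.5 and mask gating strictly lowers counting RMSE in
the presence of decoys.  The statistical-emulation check uses 500 scenes
with rendering skipped (annotations only).  `scripts/acceptance.py` runs a
slightly leaner cycle (150 scenes, 8 epochs, 300 stats scenes, 40 mask
fixtures) so a full reproduction fits in a coffee break.  Larger schedules
improve the detector but do not change what the tests establish.

## Known limitations

* The NMS fusion can double-count a target cut exactly at a window seam
  (see above); the overlap band makes this rare.
* The tiny segmenter is a 4-layer FCN adequate only for high-contrast
  synthetic scenes; real deployments should supply masks from a stronger
  segmenter via `PrecomputedSegmenter`.
* Instance normalization in the scaffold means per-tile statistics affect
  predictions; batch invariance holds because normalization is per-sample.
* `count_rmse` reports both the summed-class overall RMSE and per-class
  RMSEs, since either aggregation is defensible for survey error.
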