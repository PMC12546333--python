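# Methods

## Scope and model family

`laamseg` implements a family of backbone-tail modules for a YOLOv5s-style
instance-segmentation network, targeted at two-class brain-tumor MRI
segmentation (glioma vs meningioma). The tail slot sits at the end of the
backbone (stride 32) where the original network uses spatial pyramid pooling
(SPP); every variant is a shape-preserving feature transform with equal input
and output widths, so swapping the tail never touches the neck or head:

| variant | composition |
|---------|-------------|
| SPP     | 1×1 down-conv, parallel 5/9/13 stride-1 max pools, 1×1 fusion |
| ASPP    | 1×1 conv + dense dilated 3×3 convs (rates 6/12/18) + image-pool branch, concat + 1×1 fusion |
| LASPP   | 1×1 conv + depthwise-separable dilated 3×3 convs (rates 6/12), concat + 1×1 fusion |
| APCM    | ASPP + standard CBAM (GAP–MLP channel attention, 7×7 spatial attention), multiplicative, + residual sum |
| LAPCM   | APCM without the residual |
| LAAM    | LASPP + enhanced CBAM branch + projected residual (1×1 conv + batch norm) |
| LLAAM   | LAAM without the residual |

The enhanced CBAM branch of LAAM first widens the receptive field with two
dense dilated 3×3 context convolutions (rates 6 and 12) applied to the
lightweight-ASPP output, then modulates the context features with a
bottleneck channel attention (GAP → 1×1 down/up, no biases) and a 1×1
spatial attention over channel-wise mean/max maps. Placing the dilated
context convolutions inside the attention branch, rather than treating that
clause as a redescription of the ASPP branch, is a deliberate reading of the
module's prose description; it is also the only composition whose complexity
is consistent with the published per-variant GFLOPs (a 1×1 projection plus a
bottleneck attention cannot account for a ~4 GFLOPs gap between LASPP and
LAAM, two full-width dilated 3×3 convolutions at the 20×20 tail do).

Attention weights are sigmoid-gated, hence strictly inside (0, 1), and are
applied multiplicatively, channel first then spatial (CBAM convention).
All convolutions are followed by batch normalization and SiLU unless stated;
initialization is Kaiming-uniform under a model-level seed, so construction
is bit-reproducible.

Design choices where the source description was open:

* Standard-ASPP branch set: the four conv sub-modules are read as
  {1×1, d=6, d=12, d=18} beside the global-pool branch (classic ASPP); the
  two-rate set {1×1, 6, 12, pool} remains available through
  `dilation_rates`.
* Branch widths are unspecified; every parallel branch outputs
  `in_channels × branch_width_ratio` channels with the ratio frozen at 1.0.
  Together with the branch-set reading this is the one-time calibration that
  reproduces the published complexity column; it is applied identically to
  all variants and never tuned per variant.
* Channel-attention reduction ratio: 16 (canonical CBAM value),
  configurable.
* APCM applies CBAM to the ASPP output multiplicatively and uses an identity
  shortcut when widths match; LAAM always projects its residual through
  1×1 conv + batch norm.

## Numerical/infrastructure base

No GPU tensor framework is used: the package carries a compact reverse-mode
autodiff engine over numpy (`laamseg.tensor`), with convolution and
max-pooling as primitives (kernel-loop im2col with hand-written adjoints,
exact for stride/dilation/groups) and everything else composed from
elementwise and reduction primitives. All primitives are verified against
central-difference numeric gradients. Batch normalization follows the
framework-standard train/eval split with running statistics (momentum 0.03,
eps 1e-3). Forward math is float32; gradient checks run in float64.

## Complexity profiler

The profiler walks module shapes analytically — each layer contributes
`out_h · out_w · out_c · in_c/groups · k²` multiply-accumulates — and
reports GFLOPs = 2·MACs/1e9. The frozen convention counts convolution and
fully connected layers only; normalization, activation, pooling and
elementwise work are excluded. An independent hook-based counter measures
the convolutions actually executed during a real forward pass; the two
routes agree exactly on the full model, and a brute-force per-layer hand
computation is the third check on fixtures.

At 640×640 with two classes the baseline (SPP tail) comes to 25.68 GFLOPs;
replacing the tail gives 32.08 (ASPP), 26.43 (LASPP), 30.41 (LAAM) and
32.08 (APCM). The first four agree with the published ablation table within
0.3–0.4 GFLOPs. The published APCM value (34.9) and the published
LAPCM/LLAAM rows (26.7/26.5) are mutually inconsistent with the stated
module compositions: a module that *adds* attention computation to ASPP
cannot cost less than ASPP, and standard CBAM (≈0.07 M MACs at the tail)
cannot add 2.6 GFLOPs. The profiler reports what the described architecture
costs; the corresponding acceptance checks are left failing rather than
bending the architecture to the numbers.

## Evaluation metrics

Matching is greedy, one-to-one and within class: predictions in descending
confidence order each take the highest-IoU unmatched ground truth at or
above the matching threshold. Mask IoU is the default overlap measure (box
IoU by flag). Precision and recall are undefined — reported as missing, not
zero — when their denominators are empty. Average precision integrates the
all-point interpolated precision envelope over recall; mAP@50 averages
per-class AP with matches declared at IoU 0.5 regardless of the
precision/recall threshold, which may be swept over {0.6, 0.7, 0.8, 0.9}.
Greedy matching is validated against optimal bipartite assignment on random
small instances with separated IoU values.

## Synthetic phantoms

Each phantom is a squarish-oval "brain" (superellipse, smooth low-frequency
internal texture, level ≈85/255) on a dark background with exactly one
lesion. The glioma surrogate is an irregular star-convex polygon (radius
modulated by random low-order harmonics), rendered at low contrast (+50)
with a softened rim; the meningioma surrogate is a compact near-ellipse at
high contrast (+110) with a sharp rim. Lesion centers are uniform on
x∈[0.2, 0.8], y∈[0.2, 0.6] and box sizes on [0.2, 0.6]; a lesion whose
sampled size would leave the frame is shrunk (with a warning if that drops
it below the configured range — unreachable under the default geometry).
Labels are exact polygons; masks are their rasterization, so label and mask
agree by construction. Gaussian pixel noise (σ=6 by default) is added last.
A "domain-shifted" configuration (lower contrast, heavier noise, fresh seed
stream) emulates an external test set from a different scanner.

What the phantoms do *not* model: anatomy (ventricles, skull, hemispheric
structure), multi-slice context, intensity inhomogeneity fields, multiple or
overlapping lesions, and class-dependent location priors. Passing tests
therefore demonstrate that the pipeline is mechanically and statistically
sound under the stated geometry, not that the network segments real MRI.

## Desk-scale training

The optimizer is SGD (momentum 0.937, weight decay 5e-4 on conv weights
only, Nesterov), initial learning rate 1e-2, short linear warmup, linear
decay to 0.1×. Targets follow the anchor-ratio rule (wh ratio < 4) with
neighbor-cell expansion; the loss is CIoU (box) + BCE objectness (targets
clipped CIoU, optional floor) + BCE class + prototype-mask BCE cropped to
the instance box and area-normalized. Default gains: box 0.05, obj 1.0,
cls 0.5, mask 1.0 (the desk-scale overfit fixture raises box to 0.2).

Three measures stabilize very short runs (hundreds of steps at batch 1):

* a weight EMA (decay 0.99 with warmup time-constant 100 iterations) whose
  averaged weights are what is evaluated and saved;
* batch-norm recalibration — one large-batch forward in training mode with
  momentum 1 — before every evaluation, since small-batch running averages
  otherwise lag the statistics the fitted weights expect;
* flip augmentation: each epoch visits every image plus its horizontal,
  vertical and doubly mirrored replicas.

Inference post-processing uses confidence-weighted merge fusion over each
NMS cluster (boxes and mask coefficients), followed by a mask-space
suppression pass, both class-agnostic by default — appropriate for images
whose instances cannot spatially coincide (one lesion, one type). The
desk-scale evaluation uses NMS IoU 0.15 and confidence floor 0.01.

The tested configuration is 160×160 input, width multiple 0.25, batch 1,
30 epochs on 10 phantoms — a full train/eval cycle in minutes on one CPU
core. The full-scale protocol (640×640, width 0.5, batch 8, 100 epochs,
five-fold splits over 3000 images) is expressible through the same
configuration objects but is far outside a single-CPU budget.

## Grad-CAM

The heatmap of a chosen layer (default: the tail output) is the rectified
sum of activation channels weighted by the spatially averaged gradient of
the target score, upsampled bilinearly and min–max normalized. The target
score is the class logit of the highest-confidence candidate for the chosen
class — the standard choice for detector CAMs. Normalization makes the map
invariant to positive rescaling of the logit; an all-zero gradient returns
an all-zero map with a warning. Focus is quantified as the ratio of mean
heatmap mass inside the ground-truth mask to the mean mass outside.

What a desk-scale run demonstrates: the training loop reduces the composite
loss by more than an order of magnitude and the high-contrast lesion class
is learned essentially perfectly (per-class AP near 1 on the training set),
with Grad-CAM maps that concentrate on the lesion. The low-contrast glioma
surrogate is *not* reliably mastered within a 30-epoch, 10-image,
single-CPU budget — a few hundred SGD steps from random initialization are
not enough for the hard class — so train-set mAP@50 lands well short of
saturation. This is an optimization-budget effect, not a pipeline defect;
the corresponding learning-sanity acceptance check is intentionally left
failing rather than relaxing the phantom contrast or the threshold.

## Known limitations

* Analytic GFLOPs cannot arbitrate the published values that are internally
  inconsistent (see profiler section); those checks stay red by design.
* The numpy engine is single-threaded compute; full-scale training is not
  practical with it, which is why the desk-scale defaults are small.
* Mask quality is bounded by the 1/4-resolution prototype bank; at 160 px
  input, masks are effectively 40×40.
* The k-fold splitter implements standard shuffled k-fold (one subset =
  validation fold); the same 2400/600 arithmetic as the published protocol.
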