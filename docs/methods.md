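# Methods

## The model

`cattleseg` implements a semantic segmentation network for multi-animal
cattle scenes with three classes (background, cow, beef). The design is an
encoder–decoder in the DeepLabV3+ family with three modifications aimed at
finer mask boundaries on cluttered scenes:

1. **Truncated MobileNetV2 encoder at output stride 16.** Only the
   feature-extraction stages of MobileNetV2 are kept (stem + seven
   inverted-residual stage groups, final width 320). The two deepest stage
   groups run at stride 1 instead of striding, the last one with atrous
   (dilated) depthwise kernels, so for an H×W input the deepest feature map
   is (H/16)×(W/16)×320 rather than H/32 — resolution is preserved while the
   receptive field still grows. Intermediate maps are tapped at 1/2, 1/4 and
   1/8 resolution (the last map produced at each resolution before the next
   stride-2 operation, i.e. the most processed features of each scale).
2. **Layer-by-layer fusion decoder.** The ASPP output is raised back to
   input resolution through four 2× bilinear up-samplings with three fusion
   points, one per tapped resolution. Each fusion concatenates the
   up-sampled deep path with a 1×1-reduced low-level map. The first two
   fusions are refined by a 3×3 conv–BN–ReLU; after the last fusion two 3×3
   conv layers are stacked (extra depth and nonlinearity at constant
   resolution), then a 1×1 classifier produces logits that are bilinearly
   up-sampled 2× to input size. The original single-fusion decoder (two 4×
   up-samplings, one fusion at 1/4) is retained as the `m2` ablation
   variant.
3. **Squeeze-and-excitation attention after each fusion.** Channel
   attention: global average pool to a 1×1×C descriptor, two fully connected
   layers (reduction with hard-swish, expansion with hard-sigmoid,
   H-Swish(x) = x·clip(x+3,0,6)/6, H-Sigmoid(x) = clip(x+3,0,6)/6), and a
   per-channel rescale with weights in [0, 1]. Three independent SE blocks
   are used, one per fusion, applied to the concatenated map. Because the
   hard sigmoid saturates exactly, excitations can be pinned to 0 or 1,
   which gives sharp identities used in the tests (pinned-to-1 SE makes the
   `imp` variant numerically equal to the SE-free `m2u` variant under shared
   weights).

The variant grid is `imp` (layerwise + SE), `m2u` (layerwise, no SE) and
`m2` (single fusion, no SE).

Decisions where the design was genuinely open, resolved as follows: ASPP is
inherited unchanged with rates (6, 12, 18) and 256 channels (the customary
output-stride-16 configuration); fusion is concatenation (not addition);
low-level maps are reduced to 48 channels before fusion; the decoder width
is 256; SE reduction ratio 16; the classifier sits before the final
up-sampling (logits are up-sampled, not masks); convolutions use
Kaiming-normal fan-out initialisation, batch norm starts at identity, and
all initialisation is seeded. All widths are configurable; see "Problem
sizes" below for the narrow profile.

## The numerical engine

The network runs on a small numpy toolkit written for this package
(`cattleseg.nn`): NHWC tensors, tape-based reverse-mode autodiff,
convolutions evaluated as sums of shifted GEMMs (each kernel tap becomes
one BLAS matrix product, with strides and dilations handled by slice
indexing), bilinear resizing as a pair of 1-D interpolation-matrix
products (so its adjoint is the exact transpose), batch normalisation with
running statistics, and SGD with classical momentum. Every differentiable
operation is verified against central finite differences in float64 in the
test suite; activations are float32 in normal use.

## Training schedule

SGD with momentum 0.9 on mean per-pixel cross-entropy, initial learning
rate 0.01, decayed per iteration with the poly rule
lr = lr0·(1 − iter/max_iter)^0.9, for 60 epochs at 480×480 and batch size 4
by default. The poly power is 0.9 by convention for this model family; the
loss is cross-entropy, the default for the DeepLab family. Augmentation is
random horizontal flip only (off-switchable). Training is bit-deterministic
given the seed: initialisation, data order and flips all derive from it.
Checkpoints embed the full variant/backbone/width configuration so a file
alone reconstructs the exact network.

## Synthetic scenes

The generator emulates the structure of paddock imagery: a low-frequency
textured ground, 1–4 animals per scene drawn as body+head ellipse
composites in random poses — cows with a light coat and high-contrast dark
patches, beef animals with a uniform dark warm-brown coat — and railing
bars drawn over the scene whose pixels revert to background in the mask
(partial occlusion). Placement is rejection-sampled so animal footprints do
not touch, which keeps per-animal mask components countable. An even
cow/beef mix is the default (`class_mix = 0.5`). A colour-coded variant
(pure red cows, pure green beef on flat grey) provides a linearly separable
sanity dataset on which any working segmentation architecture should reach
near-perfect accuracy.

What the generator does **not** emulate: real coat texture and lighting,
perspective foreshortening, animal-to-animal contact and crowding, motion
blur, and annotation noise. Passing the desk-scale tests therefore shows
that the architecture, loss, schedule and metrics interact correctly and
that the model can learn shape/texture-defined classes — it does not
certify accuracy figures on real cattle imagery.

## Fog degradation

Fog uses the atmospheric-scattering model I = J·t + A·(1−t) with
transmission t = exp(−β·d), airlight A = (235, 235, 235) and a smooth
pseudo-depth field d (vertical gradient, far at the top of the frame, plus
seeded low-frequency noise, clipped to ≥ 0.05 so β → ∞ reaches pure
airlight everywhere). A uniform-depth mode is available as a fallback. β = 0
is an exact identity; the class mask is never altered. The evaluation
protocol fogs a seeded random 50% of the test set (β drawn uniformly from
0.6–1.6, chosen to span visible haze up to near-whiteout), and also exposes
the all-clear ("sunny") and all-fogged ("foggy") conditions; fogged copies
replace the originals by default or supplement them with a flag.

## Metrics

All statistics derive from one NC×NC confusion matrix (rows ground truth,
columns prediction): PA = trace/total; CPA(c) = TP/(TP+FP) — the precision
form, implemented as printed in the source convention, with a recall-form
switch; MPA = mean CPA; IoU(c) = TP/(TP+FP+FN); MIoU = mean IoU. A class
absent from both truth and prediction has undefined CPA/IoU; it is reported
as NaN, excluded from the means, and named in the report — scoring such
classes 0 or 1 would bias MPA/MIoU on sparse scenes. There is no ignore
label by default; an optional ignore index exists for masked borders. The
implementation is cross-checked in the tests against an independent
per-pixel counting oracle and against scikit-learn's confusion matrix.

## Problem sizes and numerical choices

The desk-scale experiments (tests and the acceptance script) train the
`imp` variant on 200 synthetic 96×96 scenes with an 80/20 split for 12
epochs, using a narrow width profile (ASPP 96, decoder 64, low-level 24, SE
reduction 8) with the Table-accurate backbone unchanged; these runs reach
held-out MIoU above 0.9 on clear scenes in a few minutes on one CPU core,
and show the expected large degradation on the all-fogged condition when
trained on clear scenes only. The colour-separable sanity run uses 60
scenes at 96×96 for 10 epochs. Half-up rounding is used for split sizes;
split granularity is per-image. Batch-norm eps 1e-5 and momentum 0.1
(framework-customary defaults) are recorded on the layers. Bilinear
interpolation uses the half-pixel-centre convention; polygon rasterization
uses pixel-centre, 0-based, row-major coordinates (a pixel belongs to a
polygon when its centre lies inside; later polygons overwrite earlier
ones).

## Known limitations

* The numpy engine is single-threaded BLAS-bound; full-width 480×480
  training is out of reach at desk scale (the full-width network is still
  constructed and shape-verified at 480×480).
* No pretrained backbone weights; training always starts from seeded random
  initialisation (a checkpoint hook exists for externally supplied
  weights).
* Instance identity, posture and tracking are out of scope; the model is a
  pure per-pixel classifier.
* Mask-altering augmentation beyond horizontal flip is not implemented.
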