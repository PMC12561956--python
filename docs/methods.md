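# Methods

## Model

`litemrinet` segments brain tumors in 2-D MRI slices with a deliberately
small network (≈1.51 M trainable parameters in the default
configuration). The design rests on a scale-invariance hypothesis: a
tumor should be recognizable by the same convolution kernels whether it
appears large or small in the frame. The input slice (S×S×3, values in
[0, 1], default S = 256) is therefore downsampled into a three-level
pyramid (S, S/2, S/4) and a *single* stack of 10 convolutional layers —
each 3×3, stride 1, BatchNorm, ReLU, 64 channels — is applied to all
three levels with one shared weight store. Sharing triples the effective
depth seen by large-scale structure without tripling parameters.

Global context is added at the two smallest grids: the quarter-scale
features are max-pooled (2×2, stride 2) to S/8 and passed through 6
Transformer blocks, then pooled again to S/16 through 4 more blocks.
Each block uses 8-head self-attention over pixel tokens of width 64.
A UNet-style decoder runs back up: four repetitions of {bilinear ×2
upsample → one conv layer → concatenate the matching skip (giving 128
channels) → two conv layers back to 64}, then a 1×1 convolution to
2-channel background/tumor logits. Prediction is the per-pixel argmax.

### Unstated internals and how we fixed them

Several Transformer internals are not constrained by the architecture's
public description; we chose standard practice and verified the result
stays under the parameter budget:

- pre-normalization blocks (LayerNorm before attention and before the
  feed-forward), GELU feed-forward with expansion ratio 4;
- a learned additive positional embedding per stage (can be disabled;
  it is the only component whose size depends on the input resolution);
- pixel-per-token flattening (no patching — the pooled maps are small);
- batch-normalization affine parameters live in the single shared store
  like every other trainable encoder parameter, but each pyramid level
  keeps its own *running statistics* (plain buffers, not parameters).
  During training each scale is normalized by its own batch statistics
  anyway; sharing the running statistics would make inference normalize
  every scale with a blend of all three scales' statistics, which we
  found breaks eval-mode predictions on models that fit the training
  data perfectly under batch statistics. Per-scale statistics make
  inference consistent with training while leaving the trainable
  weight store single and the parameter count unchanged;
- pyramid downsampling is area averaging (antialiased), which preserves
  intensity statistics across scales — the premise of weight sharing;
- decoder upsampling is bilinear interpolation followed by the stated
  conv layer (not a transposed convolution).

With these choices the default model has 1,509,442 trainable scalars:
encoder 335,424 (= 1792 + 9·36,928 + 10·128), Transformer stages
499,840 (10 blocks × 49,984), positional embeddings 81,920, decoder
592,128, head 130.

### Ablation variants

- `transformer_sharecnn` — the full model, one encoder store;
- `transformer_cnn` — identical, but each pyramid level gets its own
  independent encoder copy (costs exactly 2×335,424 extra parameters);
- `cnn_only` — additionally replaces each Transformer stage with an
  equal-depth stack of 3×3 conv layers at the same grid, keeping the
  pooling positions fixed so depth is controlled.

## Training protocol

Loss: 2-class softmax cross-entropy over the channel head —
mathematically the binary cross-entropy of the tumor-class probability —
plus an L2 penalty λ·Σw² over convolution, attention and feed-forward
kernels (biases, normalization parameters and positional embeddings
exempt). λ defaults to 1e-5, small enough that the pixel term dominates
at 256² resolution; λ = 1 reproduces a bare unit-weight penalty.

Optimizer: Adam, learning rate 1e-4, batch size 4, and a
numerical-stability epsilon of 3e-3 (an unusually large eps chosen to
guard against NaN losses). At most 300 epochs; the test set is evaluated
after every epoch. Training stops early when *either* the test mIoU has
gone 10 consecutive epochs without strict improvement *or* the test loss
has gone 20 epochs without a strict decrease — but only after more than
100 epochs have run. "Improvement" is strict (ties do not reset
patience); the monitored metric is test mIoU. The checkpoint kept is the
best-mIoU epoch.

## Metrics

Tumor is the positive class. From globally accumulated pixel counts
(TP, FP, TN, FN) we report precision, recall, F1, overall accuracy, and
a two-class mIoU in which tumor and background are each scored as
foreground and averaged:

    mIoU = ½·[TP/(TP+FN+FP) + TN/(TN+FP+FN)]

Dataset-level metrics pool pixel counts over all images (matching the
count-based definitions); a per-image mean is available as an option.
Metrics with a zero denominator are reported as 0 and flagged rather
than raising, so all-background images cannot abort an evaluation.

## Synthetic data

The generator emulates FLAIR-like tumor slices: a dark background
(intensity 0.05), a bright elliptical brain (0.45 plus smooth Gaussian-
filtered texture), and one connected star-convex tumor blob (0.85)
occupying 0.5–5 % of brain pixels by default — the small-target regime
(median tumor fraction of the whole image is well under 5 %). With
probability 0.2 a dark circular "hole" is carved inside the tumor as an
intensity feature only: hole pixels keep label 1, as necrotic cores
remain part of the tumor label in the datasets this emulates. Additive
Gaussian noise (σ = 0.02) finishes the image. Masks are the exact blob
support, values {0, 1}.

What it does not emulate: anatomical structure (ventricles, gyri,
midline), multi-focal tumors, intensity inhomogeneity fields, partial-
volume boundaries, or inter-slice correlation. Passing tests therefore
demonstrate that the implementation is correct and trainable, not that
it reaches any particular accuracy on clinical data.

File format: 8-bit PNG for images (RGB) and masks (single channel;
{0,1} or {0,255} accepted on read, any nonzero value binarizes to 1).
Loading resizes proportionally — longest side to the target, symmetric
zero padding to square — with area interpolation for images and
nearest-neighbor for masks, so masks stay binary and undistorted.

## Numerical implementation

The network runs on a small reverse-mode automatic-differentiation
engine written on NumPy (`litemrinet.nn`): convolution is evaluated as
nine shifted GEMMs with a hand-written backward pass, batch
normalization is a fused op, and everything else (attention, reductions,
padding, concatenation) composes from taped primitives. Inference runs
under a `no_grad` context so no graph is retained. All model arithmetic
is float32; gradient checks in the test suite run the same ops in
float64 against central differences.

## Problem sizes used in tests

Checks that require training run at reduced resolution so the suite
completes on a single CPU: the overfit-sanity check trains the *default
architecture* (full depth and width) at input size 32 on 8 synthetic
pairs with tumors covering 5–12 % of the brain (≈20–60 pixels at 32²,
large enough for IoU to be meaningful at that resolution), learning rate
1e-3 for the bounded sanity run with the early-stopping rule disabled,
at most 200 gradient steps, and asserts tumor IoU ≥ 0.9 on the training
pairs. Integration tests of the CLI use
a thin 16² configuration (2 encoder layers, 8 channels, 1+1 Transformer
blocks). Shape and parameter checks run the full default model at sizes
64–256, which needs no training.

## Known limitations

- 2-D slices only; no volumetric context.
- Binary segmentation; no tumor subregion labels.
- No augmentation, learning-rate schedules or mixed precision.
- CPU-bound NumPy training is practical at reduced resolutions only;
  the implementation is written for correctness and auditability, not
  throughput.
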