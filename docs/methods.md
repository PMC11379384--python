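# Methods

## The model

The network is a four-level U-Net: encoder widths 64, 128, 256, 512 (scaled
by `width_multiplier`), a 1024-channel bottleneck, 2×2 max-pooling on the
main contracting path, and a decoder of stride-2 transposed convolutions
with skip concatenations, ending in a 1×1 convolution and a sigmoid. Inputs
are RGB in [0,1], NCHW; spatial dims must be divisible by 16 (level *i*
features live at input/2^(i−1), the bottleneck at input/16). Five optional
modules extend this backbone; all are independent flags of `NetworkSpec`,
and the nine canonical ablation configurations are exposed as
`NetworkSpec.ablation_row(1..9)`.

Design choices where the architecture description leaves room, fixed a
priori and used everywhere:

* **Residual block**: conv3×3–BN–ReLU–conv3×3–BN plus shortcut, *no*
  activation after the addition. This makes the block's contract exact: a
  zeroed transform branch returns the shortcut bitwise (batch-normalizing a
  zero map yields zero in both training and inference mode at
  initialization). Convolutions followed by BN carry no bias; projection
  shortcuts (1×1) do.
* **Down-sampling fusion** seeds its channel recurrence at the encoder's
  first-level width (64), not at the image's 3 channels: the literal 2C
  doubling from C=3 would produce 6/12/24/48-channel maps, an order of
  magnitude narrower than the encoder maps they join. Pyramid maps are
  *concatenated* (not summed) before each encoder block, matching the
  "additional inputs" role; each level is one stride-2 3×3 conv–BN–ReLU of
  the previous. The main path keeps max-pooling; the stride-2 convolutions
  belong to the side pyramid only.
* **DAC block** (1024 channels): branches with dilation sequences {1}, {3},
  {1,3}, {1,3,5}; branches with more than one dilated convolution end in a
  1×1 convolution; ReLU after every convolution; branch outputs are summed
  onto the input. Same-padding everywhere, so any spatial size (down to
  1×1) is preserved.
* **RMP block**: max-pool at kernel=stride ∈ {2,3,4,6}, 1×1 reduction to a
  single channel per branch, bilinear upsampling back, concatenation with
  the input (C+4 channels), and a 1×1 fusion convolution restoring C
  channels so decoder widths stay powers of two. The standalone block
  rejects inputs smaller than the largest kernel; inside the assembled
  network kernels are clamped to `min(k, H, W)` so that small training
  patches (e.g. 64² inputs with a 4² bottleneck) remain usable.
* **Attention gate**: additive attention with intermediate width
  skip_channels/2; `W_x` is a stride-2 1×1 convolution on the skip, `W_g` a
  1×1 convolution on the gate (the next-deeper feature map before
  upsampling); ReLU, a 1-channel ψ with sigmoid, bilinear upsampling of α
  to skip resolution, and channel-broadcast multiplication.
* **Up-sampling fusion**: each deeper decoder output reaches level *i*
  through its own chain of (j−i) stride-2 transposed convolutions that
  preserve channel width; members are concatenated deepest-first. With all
  modules on, every decoder block input is exactly 16× the base width.
* **Transposed convolutions are 3×3** (stride 2, output padding 1). Two
  published anchors support this over 2×2 kernels: the baseline U-Net's
  reported size (34 M parameters / 131 MB) matches a 3×3-upconv U-Net
  (34.5 M here) rather than the classic 2×2 variant (31.0 M), and the
  context-extractor lineage uses 3×3 deconvolutions.

With these choices the complete network at base width 64 counts
**131,727,593** trainable parameters — 132 M rounded, equal to the published
count for the full model (whose 505 MB float32 size implies ≈132.4 M); the
all-flags-off configuration counts 34.5 M against the baseline's published
34 M. Parameter counts for every configuration are verified against an
independent per-layer closed-form sum in the test suite.

## Objective and metrics

The loss is `β·L_Dice + (1−β)·L_BCE` with β = 0.75, computed as a pixel
mean over the whole batch. Probabilities are clipped to [ε, 1−ε], ε = 1e−7,
before logarithms; the same ε smooths the Dice ratio in numerator and
denominator so an empty prediction of an empty mask is a perfect score.

Evaluation binarizes at 0.5 (configurable) and aggregates confusion counts
over all pixels of the evaluated set before computing Precision, Accuracy,
Dice and MIoU ("global" aggregation; per-image counts can be summed by the
caller in any grouping since counts are additive). Zero denominators follow
the convention: vacuously perfect outcomes score 1 (e.g. Dice with no
foreground anywhere), otherwise 0 (e.g. precision with no predicted
positives but existing misses). ROC pools raw probabilities across images,
takes one operating point per distinct threshold plus the all-negative
origin, and integrates by the trapezoidal rule; this equals the
concordant-pair (Mann–Whitney) statistic, which the tests verify.

## Data protocol

Whole 1000² images are cut into four non-overlapping 500² quadrants
(row-major `_q0.._q3`) resized to 512²: bilinear for images and probability
maps, nearest-neighbour for masks, which are re-binarized after any resize.
Stitching inverts the geometry (the round trip agrees with the source mask
on ≥99% of pixels; disagreement is confined to the 500↔512 resampling at
nucleus boundaries). Grouped splitting sends one seeded-uniform pick per
group to the test set; validation holds out floor(0.3·n) of the training
pool after a seeded shuffle. No training-time augmentation is applied.

Training uses Adam at 1e-3, batch size 4, multiplied by 0.1 once after
epoch 50 by default (`lr_decay_epoch`; a per-update decay interpretation is
deliberately not implemented — the single step is exposed in the config so
the choice is explicit). The best checkpoint is selected by validation
Dice. One integer seed drives weight initialization, the validation split
and batch shuffling; geometry and splits reproduce bit-exactly, weights up
to floating-point accumulation order.

## The numerical engine

All layers run on a small reverse-mode autodiff engine over numpy arrays
(NCHW). Convolutions loop over kernel taps, each tap a channel-mixing
einsum on a strided view — memory stays proportional to the input, where
im2col materialization grows with the kernel footprint and dominates at
wide concatenations. Transposed convolution, max-pooling (stride = kernel,
ties to the first element), batch normalization (momentum 0.1, eps 1e-5)
and half-pixel bilinear resizing all have hand-written backward passes,
each validated against central differences in the test suite. Inference
runs under `no_grad()` with batch-norm running statistics.

## The synthetic generator

Scenes emulate the failure modes the architecture targets: variable nucleus
size (uniform radius range, default 6–18 px at 512²), eccentric rotated
ellipses, adhesions (a configurable fraction placed tangent to a
neighbour), optional overlaps, a contrast knob interpolating nucleus color
toward the background (lower contrast provably weakens boundary gradients),
and Gaussian pixel noise. Placement is rejection sampling with 100 retries
per nucleus; when overlaps are forbidden, footprints are kept 8-disconnected
so connected-component counts equal nucleus counts exactly. Defaults
(60 nuclei, contrast 0.6, noise 0.03) describe a moderately dense,
well-stained patch. Per-image seeds are `seed + index`.

What passing on synthetic data does *not* show: real H&E stain variation,
chromatin texture inside nuclei, out-of-focus regions, or annotation noise.
The generator validates the machinery (shapes, losses, protocol, learnings
dynamics), not clinical-grade accuracy; the published benchmark scores
require the external datasets and GPU-scale training and are out of scope
here.

## Problem sizes in tests

The suite trains only width-multiplier-0.125 networks (first-layer width 8)
on 64² scenes — small enough for a single CPU while exercising every module
at full depth, including the clamped-kernel RMP path. The overfit check
(four fixed scenes to Dice > 0.9) converges in ~20 Adam steps; the
end-to-end CLI run uses 8 scenes and 15–20 epochs. Full-scale (width 64)
networks are built for parameter counting only, never trained in tests.

## Known limitations

* Batch normalization in float32 with batch size 4 reproduces the training
  protocol but not bit-exact cross-platform weights.
* The engine is single-threaded numpy; full-scale 512² training is out of
  reach by design (the package targets protocol fidelity and CPU-scale
  verification).
* `lr_decay_epoch` implements one decay step; exotic schedules are not
  supported.
* Instance separation (touching-nuclei splitting) is out of scope: the task
  is semantic segmentation.
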