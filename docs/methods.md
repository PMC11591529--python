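# Methods

## Problem and pipeline

Mitral regurgitation (MR) is graded semi-quantitatively on apical
four-chamber color-Doppler frames from the area-based regurgitant fraction

    RF = 100 · area(MR jet) / area(left atrium),

with RF < 30 % mild, 30–49 % moderate and ≥ 50 % severe (the boundary
values 30 and 50 belong to the higher grade). An area *ratio* is used so
the index is invariant to the image scale of different ultrasound devices.
The pipeline is: segment each frame into background / MR jet / left atrium
(LA), count pixels, form RF, grade. Because the jet occludes atrial pixels
in a single-label mask, the atrial denominator defaults to the union of
jet and LA labels (`la_includes_jet=True`); the strict label-2 denominator
is available behind a flag but inflates RF anatomically.

## Segmentation model

The segmentation network is a UNet whose encoder is the initial stages of
a ResNet-style bottleneck network and whose decoder carries Efficient
Multi-Scale Attention (EMA) blocks:

* **Encoder.** Stage 0 is a 7×7 convolution + batch norm + ReLU; stages
  1–4 are bottleneck residual blocks (1×1 → 3×3 → 1×1 convolutions with a
  projection or identity shortcut, learning F(x) = H(x) − x). The default
  depth mirrors ResNet50's (3, 4, 6, 3) bottlenecks with base width 64 and
  expansion 4. Strides are arranged so the five pyramid levels sit at /1,
  /2, /4, /8 and /16 of the input resolution (the stem keeps full
  resolution and a 3×3/2 max-pool precedes stage 1); inputs must be
  divisible by 16, and a pad helper maps 800×600 frames to 800×608.
* **Decoder.** Four levels; each applies a 2×2 transposed convolution
  (stride 2) to double the spatial size, concatenates the matching encoder
  feature, applies two 3×3 conv+BN+ReLU blocks and then, if the level is in
  `attention_stages` (default: all four), an EMA block. Decoder widths
  mirror standard UNet doubling (64, 128, 256, 512, scaled by
  `width_mult`). EMA is placed after the skip-concatenation convolutions.
  A 1×1 convolution and per-pixel softmax produce the 3-class
  probabilities; the predicted mask is the per-pixel argmax with ties
  broken toward the lower class index.
* **Ablations.** `encoder="unet_conv"` (plain double-conv UNet encoder) and
  `attention ∈ {none, ema_original, ema_improved}` make all five studied
  variants (UNet, ResUNet, ResUNet+EMA, UNet+improved EMA, ResUNet+improved
  EMA) pure configuration.

Pretrained encoder weights are not bundled; `pretrained_encoder=True`
raises. All experiments here run from seeded random initialization.

## EMA attention

EMA splits C channels into G groups (default G = 8; per decoder level G is
reduced to the largest divisor of the block width) and processes each
group independently:

1. **1×1 branch (G1):** global average pooling along H and along W, the two
   profiles concatenated and passed through a shared 1×1 convolution, split
   back, sigmoid-gated onto the input per direction, then group-normalized.
2. **3×3 branch (G3):** a 3×3 convolution on the grouped input.
3. **Cross-spatial fusion:** `cross_term(A, B)` projects the globally
   pooled channel descriptor of A against the flattened spatial map of B
   and applies a softmax over spatial positions. The original variant sums
   `cross_term(G1, G3) + cross_term(G3, G1)`, applies a sigmoid, and
   multiplies the map onto the grouped input.

The **improved** variant adds an independent third 1×1-convolution branch
GN and two further terms, `cross_term(G1, GN)` and `cross_term(GN, G3)`,
summed with the original pair. The fused pre-sigmoid map is group
normalized before the sigmoid (`prenorm=True`; the alternative order is a
flag, since the source description "sigmoid activation and normalization"
does not fix it). The new branch has its own weights; weight sharing with
the original 1×1 branch is not assumed. `cross_term` is exposed as a named
function so alternative fusion wirings can be composed and tested rather
than hidden in the forward pass.

## Losses

Training minimizes `L = L_focal + L_dice` (1:1, overridable):

* Focal: mean over pixels of −α_t (1 − p_t)^γ log p_t with p_t the
  predicted probability of the true class, clipped to [1e−7, 1 − 1e−7].
  α_t = 0.25 and γ = 2 are the canonical focal-loss settings; the source
  protocol does not state them.
* Dice: 1 − (2Σp_i g_i + s)/(Σp_i² + Σg_i² + s) per class, averaged over
  the two foreground classes (MR, LA; background excluded), s = 1e−5 to
  protect empty classes (tests of the printed form use s = 0).

## Training recipe

Adam with lr 1e−4, betas (0.9, 0.999), weight decay 0, batch size 2,
100 epochs, encoder frozen for the first 50 epochs — the reference recipe,
reproduced at configurable scale. Augmentation applies the same random
rotation (±15° default) and scaling ([0.8, 1.2] default) to image and mask
(nearest-neighbour for the mask). A 10 % validation fold is carved from
the training set for checkpoint selection (the reference protocol reports
only train/test, so this fold is an addition); the retained checkpoint is
the best-validation MR-class Jaccard by default, last-epoch behind a flag.
All randomness (shuffling, augmentation, init) descends from the config
seed; two runs with the same seed and data give identical losses.

Desk-scale runs in the test suite use the `ModelConfig.tiny()` preset —
width 1/8, one bottleneck per stage, G = 4, 64×64 inputs — trained with
lr 1e−3 and freeze_epochs 0: training starts from random initialization
rather than pretrained weights, so freezing the encoder would be
counterproductive and the reference learning rate (tuned for a pretrained
full-width model) is scaled up for the short from-scratch run. With those
settings 16 synthetic frames reach a held-out MR Jaccard above 0.8 in
under 50 epochs on one CPU core.

## Synthetic data

The clinical dataset is private, so the generator renders stand-ins with
exact ground truth: a dark speckled sector (gamma-distributed, smoothed),
an elliptical LA cavity inside it, and a star-convex jet blob whose radial
profile is a random 5-harmonic series scaled by `jet_irregularity`
(default 0.35). The jet's size is set by rank-ordering candidate pixels by
normalized radial distance and thresholding at exactly
round(target_RF · LA area), so the achieved RF differs from the target by
at most one pixel's worth of area (the contract tolerates ±2 RF points).
Jet colors follow a smooth signed pseudo-velocity field mapped to red/blue
with random yellow/green mosaic flecks. Dataset generation samples target
RF uniformly from 5–29 (mild), 31–49 (moderate) and 51–90 (severe), so no
generated case sits on a grading boundary.

What the generator does **not** emulate: Doppler aliasing physics, wall
motion and probe geometry, anatomical variability of chamber shape,
eccentric wall-hugging jets, annotation noise. Passing tests therefore
demonstrate that the architecture, losses, training loop and grading rule
are implemented correctly and can learn a jet-inside-atrium geometry —
not that clinical-grade accuracy transfers to real echocardiograms.

## Metrics

All metrics derive from confusion matrices (rows = truth, columns =
prediction) one-vs-rest: Jaccard TP/(TP+FP+FN), precision TP/(TP+FP),
recall TP/(TP+FN), accuracy (TP+TN)/total, F1 = 2TP/(2TP+FP+FN) (equal to
the harmonic precision/recall mean), and MPA = mean over evaluated classes
of per-class accuracy TP_i/(TP_i+FN_i). Segmentation reports cover the two
foreground classes and their unweighted mean (consistent with published
single-target rows where MPA and recall coincide); both MR-only and
MR/LA-mean reductions are available. Case-level severity metrics use the
3×3 mild/moderate/severe matrix with macro ("Total") rows as unweighted
per-class means. Note the published Total F1 (90.30) matches neither the
macro mean of the per-class F1s nor the harmonic mean of the Total
precision/recall; this module reports the macro mean and does not chase
the printed value. Divisions by zero (empty classes) report 0.0 with a
flag rather than NaN.

## Numerical engine

No deep-learning framework is part of the runtime stack; `mrseg.nn` is a
compact reverse-mode automatic differentiation engine on NumPy — float32
tensors, im2col convolutions via BLAS matmuls, transposed convolution with
kernel = stride, overlapping max-pooling with index scatter, batch/group
normalization, Adam. It is sized for the models used here (small batches,
dense 4-D maps, CPU) and verified against central-difference gradients and
per-layer loop oracles in the test suite.

## Other design choices

* Labelme rasterization: even-odd rule at pixel centers ((col+0.5,
  row+0.5)); points exactly on an edge count inside; MR paints over LA on
  overlap. Verified against a naive per-pixel scan oracle.
* Masks persist as paletted PNG with palette index = class label
  (lossless round trip).
* Dataset splitting is case-level and stratified per grade with
  n_train = floor(0.8 n); the split seed is recorded in the manifest.
* Checkpoints are `.npz` archives of named weights plus a JSON-encoded,
  versioned model config.
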