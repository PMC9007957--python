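# Methods

## Segmentation model family

The package implements a family of U-Nets parametrized by the pair
(k, f₀): k depth levels with encoder widths f₀·2⁰ … f₀·2^(k−1) (so k−1
pooling/upsampling stages), all convolutions 3×3.  The block micro-structure
is fixed as:

* **ConvBlock(c_in → c_out)** — [3×3 conv (with bias) → ReLU → BatchNorm] ×2,
  plus a residual shortcut [1×1 conv (no bias) → BatchNorm] added to the block
  output.  Whether a final ReLU follows the addition is count-neutral; it is
  on by default and configurable (`shortcut_relu`).
* **Encoder** — k ConvBlocks; blocks 2…k are preceded by 2×2 max-pooling.
* **Decoder** — per level: a 2×2 stride-2 transposed convolution halving the
  channel count; the matching encoder skip passes through a channel-preserving
  "bridge" (3×3 conv → ReLU → BatchNorm) before concatenation; then
  ConvBlock(2c → c).
* **Head** — 1×1 convolution to the class count; sigmoid for one class,
  channel softmax otherwise.

This structure makes the trainable-parameter count a pure function of
(k, f₀, input channels, classes); the little models land exactly on
34,201 (φ_{3,8}), 76,213 (φ_{3,12}) and 68,482 (Little W-Net) parameters,
which the test suite pins down.  Batch-norm contributes 2 trainable scalars
per channel (scale and shift); running statistics are buffers, not
parameters.

The W-Net cascade Φ(x) = φ²(x, φ¹(x)) feeds the *post-sigmoid probability
map* of subnet 1 (not logits) into subnet 2, concatenated with the image —
the map acts as a spatial attention prior, and probabilities keep the second
subnet's input in a bounded range.  Both subnet outputs are exposed because
the loss penalizes both.

On the meaning of k: the printed parameter counts are only consistent with k
counting *depth levels* (k−1 resolution halvings), and that convention is
used throughout.

## Numeric engine

The network runs on a small reverse-mode autodiff engine written on numpy
(`lwvessel.nn`): NHWC layout, float32, convolutions lowered to im2col + BLAS
matmul, exact 2×2 stride-2 transposed convolution as a reshaped matmul,
batch-norm with the standard closed-form backward, argmax-routed max-pool
gradients, and Adam (β = 0.9/0.999, ε = 1e-8 — conventional defaults; only
the learning rate is scheduled).  Gradients are verified against central
finite differences in the test suite.  Weight initialization is
fan-in-scaled Gaussian (He), seeded; parameter counts are seed- and
input-size-invariant.

Probabilities entering the cross-entropy are clamped to [ε, 1−ε] with
ε = 1e-6, so losses are finite even on saturated outputs; the clamp composes
with the sigmoid backward to the usual well-conditioned (p − y) gradient.

## Training protocol

* Loss: mean pixel binary cross-entropy; for the W-Net the unit-weight sum of
  both subnets' losses.  Soft targets are supported (needed for pseudo-label
  fine-tuning).  Pixels outside the FOV are *included* in the loss by default
  (FOV exclusion is an evaluation rule, not a training rule); a
  `loss_in_fov_only` switch exists.
* Optimizer: Adam, learning rate cosine-annealed within each cycle from
  1e-2 to 1e-8 over `cycle_epochs` = 50 epochs, restarting at 1e-2 each
  cycle.  Optimizer moments are carried across cycle restarts.
* "Iterations" are gradient steps.  The number of cycles is
  ceil(target_iterations / (50 · steps_per_epoch)), so small training sets run
  more cycles; the default target is 4000 iterations, batch size 4.
* Augmentation ("standard"): random horizontal/vertical flips, rotation
  within ±45°, scale jitter ±10%, brightness/contrast/gamma jitter ±20%.
  Geometric transforms are applied identically to image, label and FOV
  (nearest-neighbour for binary grids, bilinear for soft ones); photometric
  jitter touches only the image.  Every component is individually switchable
  and all draws come from the run seed.
* Model selection: pooled validation AUC at each cycle end (computed at the
  training resolution without TTA, for speed); the first cycle achieving the
  maximum wins ties.

## Inference

Test-time augmentation averages predictions over the closed 4-element flip
group {identity, horizontal, vertical, both}.  Closure makes TTA exactly
flip-equivariant, which the suite asserts; a 3-transform variant is available.
Images whose sides are not multiples of 2^(k−1) are reflect-padded and the
output cropped — the input is never resampled.  Probability maps are restored
to native resolution by bilinear interpolation *before* thresholding and
clamped to [0, 1].

## Evaluation protocol

All metrics pool FOV pixels across the whole split (pooled ≠ mean-per-image,
and a test guards against that pitfall).  AUC uses the exact rank/trapezoid
method (ties counted half) up to 5·10⁶ pooled pixels and a 1024-bin histogram
ROC beyond; the exact path is oracle-checked against brute-force pair
counting.  The binarization threshold maximizes pooled Dice on the *training*
split over the 8-bit grid {0, 1/255, …, 1} (matching 8-bit prediction export;
ties go to the smallest level) and is then frozen for test and cross-dataset
use.  Binarization is `prob ≥ t`.

Zero-denominator conventions: Dice = 1 when TP = FP = FN = 0; MCC = 0 when a
marginal is empty; FDR = 0 when nothing is predicted vessel; a rate with an
empty class is 0 (G-mean inherits this); Kappa of a degenerate pool is 1 for
perfect agreement, else 0.  Nothing returns NaN.

## Domain adaptation

Single-round pseudo-label self-training: TTA probability maps on the target
images (kept soft — never thresholded) are merged with the labeled source
pool; the model is fine-tuned for 10 epochs at the constant rate
lr_max/100 = 1e-4 (no cosine restart — the schedule is part of full training,
not of a short fine-tune), source and target items mixed uniformly.  The best
epoch is chosen by pooled AUC over the merged pool; since AUC needs binary
references, pseudo-labels are binarized at 0.5 *for this monitoring only*,
while the loss always sees the soft targets.  The adapted model is a new
object; inputs are never mutated.

## Model comparison

Stratified pixel bootstrap, 100 rounds: each round resamples the pooled FOV
pixels with replacement separately within the vessel and background strata,
preserving both stratum sizes exactly.  Per round, AUC and Dice (each model
at its own pre-calibrated, fixed threshold) are computed for both models via
multiset weights, and the difference is oriented better-minus-other with
"better" fixed a priori by full-pool AUC.  The p-value is the fraction of
rounds with difference ≤ 0; significance at α = 0.05.

## Synthetic fundus generator

The generator is the package's stand-in for fundus photographs; it is not a
model of any real dataset.  It emulates: dark branching vasculature grown
from an optic-disc locus (random walk with heading noise; per-step taper
0.995; bifurcation probability 0.10/step with calibers decayed by 0.80;
initial stroke radius 1.8 px at 128×128), a bright circular FOV (radius 0.95
of the half-side), a radially darkened orange background with low-frequency
texture, additive Gaussian pixel noise, and an optional bright central
reflex.  Default parameters were fixed once so that the vessel fraction of
the FOV falls in a band plausible for fundus vasculature (Monte-Carlo over 50
seeds: ≈ 0.08–0.14, inside the asserted 0.03–0.18 band).  Domain-shift
presets change exactly one field relative to `source`: `target_illumination`
(rim darkening 0.25 → 0.60), `target_od_centered` (vessel origin moved to
the image center), `target_lowres` (128² → 64²).  Appearance-only presets
share byte-identical labels because tree sampling and appearance use separate
seeded streams.

What it does *not* emulate: optic-disc/macula textures, lesions and
pathologies, camera vignetting models, inter-grader label noise, JPEG
artifacts, or realistic color distributions.  Passing the end-to-end tests
therefore shows the pipeline learns and evaluates correctly at desk scale,
not that it reaches photograph-level accuracy on clinical data.

## Desk-scale study sizes

The reference experiment trains the Little W-Net on 20 synthetic 128×128
source images (batch 4 → 250-step cycles, 500 gradient steps total, seed 0),
selects by pooled AUC on 4 validation images, calibrates the threshold on the
training split and evaluates on 4 held-out images.  The adaptation experiment
uses 8 source / 6 illumination-shifted target images at 64×64, 120 training
steps, flips-only augmentation, five seeds.  These sizes are the package's
default desk-scale study conditions; all larger protocol constants (4000
iterations, 50-epoch cycles) remain the library defaults.

## Known limitations

* Single-channel (binary) training only; multiclass heads build and forward
  (softmax) for architecture studies, but the training loop targets one
  class.
* The numpy engine is CPU-only and single-image-batch oriented; it is meant
  for little models, not for scaling up.
* Checkpoints store flat weight maps keyed by module paths; architectures are
  rebuilt from the stored (k, f₀, channels, classes) spec, so renaming
  modules breaks old checkpoints.
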