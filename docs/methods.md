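# Methods

## Problem

Retinal vessel segmentation assigns every pixel of a color fundus
photograph to vessel or background. Fundus imaging suffers from uneven
illumination, low vessel/background contrast and sensor noise, so the
method has two stages: an image-enhancement front end and a convolutional
encoder–decoder with reverse attention, trained on small patches and
applied with a sliding window.

## Enhancement front end (MSRCR)

A fundus image is modelled as reflectance times incident illumination,
`P_i(x,y) = R_i(x,y) · I_i(x,y)` per spectral band. Single-scale retinex
estimates log-reflectance as

    R_sigma = log(P + eps) − log(G_sigma ∗ P + eps)

with a unit-sum Gaussian surround `G_sigma`. Three scales are combined
with weights summing to one, and a color-restoration gain

    C_i = beta · [log(alpha · P_i + eps) − log(Σ_j P_j + eps)]

multiplies each band (MSRCR). The enhanced image is converted to gray by
`0.299 R + 0.587 G + 0.114 B`, standardised to zero mean / unit variance
with statistics pooled over the training split, and mapped to 0–255 by
min–max normalisation.

Parameter choices that the published recipe leaves open, fixed here as
package defaults:

* surround scales `sigmas = (15, 80, 250)` px with equal weights — the
  canonical small/medium/large triple from the retinex literature;
* color restoration `alpha = 125`, `beta = 46`, the customary constants;
* `eps = 1.0` inside every logarithm (the fundus background contains
  true zeros);
* log-domain output is mapped to 0–255 per channel by clipping at
  mean ± 2·std ("simplest color balance"); global min–max is selectable
  via `MSRCRConfig.rescale = "minmax"` but a single outlier pixel can
  crush the whole dynamic range under that policy;
* the Gaussian surround is a truncated separable kernel (half-width
  `int(3·sigma + 0.5)`) with edge-repeating reflective padding;
* Z-score statistics are population statistics over all pixels of the
  training split, frozen and re-applied to test images, so no test-set
  information leaks into the normalisation.

## Network

Input is a 48×48 grayscale patch on the [0, 1] scale. The architecture:

* **Side-input pyramid.** The patch is average-pooled to 48, 24, 12 and
  6 px; each level passes through a 3×3 convolution and is added to the
  features entering the matching encoder stage.
* **Residual encoders** (4 stages, channels 32/64/128/256 by default,
  doubling per stage). Each stage is conv3×3 → BN → ReLU → dilated
  conv3×3 (rate 2) → BN → ReLU plus a shortcut (1×1 projection when the
  channel count changes), followed by 2×2 max pooling. Feature sizes run
  48 → 24 → 12 → 6.
* **Reverse channel attention (RCAM)** on each of the three skip
  connections. The deeper scale is squeezed to one channel, upsampled by
  a 2×2 stride-2 transposed convolution, and converted to reverse
  weights `1 − sigmoid(logits)`, which emphasise exactly the regions the
  coarse prediction is least confident about (vessel edges, thin
  vessels). These gate the shallow features into "edge features"; global
  average- and max-pooled channel descriptors form an outer product
  whose softmax over the first index gives a column-stochastic
  channel-affinity matrix; after a sigmoid and a learnable per-channel
  scale (initialised to 1) this matrix remixes the edge features across
  channels, and the result is added back to the shallow features.
* **Decoders** (3 stages): 2×2 stride-2 transposed convolution,
  concatenation with the RCAM-refined skip, two 3×3 convolutions with
  ReLU.
* **Reverse spatial attention (RSAM)** between decoding stages: the
  deeper encoder features are squeezed and upsampled to the decoder
  resolution, summed with the decoder features, and turned into a pixel
  attention mask by 1×1 convolution + sigmoid; the mask gates the
  1×1-convolved decoder features, each channel is softmax-normalised
  over its spatial positions, and the result is added residually.
* **Head:** 1×1 convolution + sigmoid → per-pixel vessel probability.

Interpretation choices where the module descriptions are genuinely
open: the channel-affinity softmax normalises over the first index
(column-stochastic); the "parametric learning function" after the
sigmoid is a per-channel learnable scale; RCAM output replaces the plain
skip tensor; the side input is fused additively after a 3×3 convolution;
conv → BN → ReLU ordering inside residual blocks; He-uniform
initialisation controlled by `NetworkConfig.seed`. Channel widths are
configurable (`base_channels`); matching any particular total parameter
count is a non-goal.

The network runs on a small reverse-mode automatic-differentiation
engine over numpy arrays (`rfarn.nn`): taped tensors, im2col
convolutions, 2×2 stride-2 transposed convolution, max pooling with
first-maximum tie-break, batch normalisation, softmax, broadcasting
arithmetic, Adam, and a plateau learning-rate scheduler. Every
differentiable op is validated against central-difference gradients in
the test suite.

## Training and inference

Pixel-wise binary cross-entropy (predictions clamped to
`[1e-7, 1 − 1e-7]`), Adam with `beta1 = 0.9`, `beta2 = 0.999`,
`eps = 1e-8`, learning rate 0.001, L2 weight decay 0.0005, batches of 32
freshly sampled 48×48 patches, 200 epochs by default. Patches are drawn
uniformly over corner positions; corners whose patch overlaps the field
of view by less than half are rejected so training is not dominated by
the camera border. The learning rate decays by 0.5 after 10 epochs
without validation improvement (floor 1e-6); the validation signal is a
held-out 10% of each epoch's patches. `patches_per_epoch` defaults to
4096; the patience, factor and validation split are package choices not
fixed by the recipe.

At test time a 48×48 window slides with stride 5 (plus a final
flush-to-edge window per axis so no pixel depends on padding); pixels
beyond the image are zero-filled for the network input only, and
overlapping predictions are averaged. Binarisation uses a strict `>` at
threshold 0.49 on floating-point probabilities (8-bit quantisation of
probability maps would put 125/255 ≈ 0.4902 right at the threshold, so
probabilities are kept in float until binarisation).

## Evaluation

Confusion counts are restricted to FOV pixels. Reported metrics:
accuracy, sensitivity, specificity, precision, recall, F1, Matthews
correlation, and ROC/PR curves with trapezoidal AUC swept over the
distinct predicted probabilities. Ratios with zero denominators are
flagged NaN, never silently zero (a vessel-free tile would otherwise
inflate specificity averages). Across a test set, counts are summed for
micro-averaged headline metrics and a per-image mean/std table is also
produced; pooled AUC and per-image AUC are both available, pooled being
the headline.

## Synthetic data

The generator grows branching vessel trees by a random walk (angular
jitter sd 0.18 rad per unit step; children spawn with probability 0.05
per step, thin by ×0.7, and receive half the remaining step budget; four
trees rooted near a disc-like origin offset to one side) and renders
them into a reddish background (185/105/55 RGB) under a radial
illumination fall-off (centre-to-edge ratio 1.5), darkening the green
channel by 45 intensity units inside vessels (and red by half that),
with additive Gaussian noise of sd 8 and a circular FOV. Defaults were
chosen once to give a vessel density of roughly 4–15% of the FOV across
seeds — the density range of human fundus vasculature — and contrast and
noise levels that make the images visibly low-contrast but learnable.

What this emulates: green-channel dominant vessel contrast, uneven
illumination, sensor noise, a camera border. What it does not: vessel
central reflex, pathology (hemorrhages, exudates), optic-disc texture,
inter-image color variability, and real vessel-tree topology. Passing
the end-to-end tests therefore demonstrates that the implementation
learns and segments correctly under the modelled degradations; it does
not certify benchmark-level performance on real fundus photographs,
which additionally requires the full training budget on the public
datasets.

## Problem sizes in the shipped tests

The test suite trains a narrow network (`base_channels = 8`, ≈61k
parameters) rather than the full-width default: the single-patch
memorisation check runs 200 Adam steps, and the generalisation check
trains 5 epochs of 1280 patches (200 steps of batch 32) on eight
128×128 synthetic images and evaluates stride-5 sliding-window inference
on two held-out images. With the shipped seeds this reaches FOV-masked
F1 ≈ 0.94 and ROC-AUC ≈ 0.999 against the ≥ 0.70 / ≥ 0.90 bars. These
sizes are the package's desk-scale verification regime; the full-scale
recipe (width 32, 200 epochs, 4096 patches per epoch) remains the
configuration default.

## Known limitations

* CPU-only numpy execution: full-scale training on the public benchmarks
  is possible but slow; the engine exists to make the method exact and
  testable, not fast.
* BCE is computed on probabilities (after the sigmoid head) with
  clamping, not as a fused logit-space loss; gradients vanish for
  predictions saturated beyond the clamp.
* The STARE loader uses the first observer's (`ah`) labels; the second
  observer is not bundled.
* Sliding-window averaging slightly smooths probabilities at window
  seams relative to whole-image inference.
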