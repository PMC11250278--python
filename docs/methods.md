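# Methods

## Problem and model

Given an RGB field image with N annotated ear centres
P = {p₁, …, p_N} (continuous, 0-based pixel coordinates, x = column,
y = row), the supervision target is a density map

    H(x) = Σᵢ δ(x − pᵢ),      F(x) = H(x) ∗ G_σ(x),

where G_σ is a fixed-bandwidth Gaussian. F is non-negative and integrates
to N, so counting reduces to regressing F and summing. A binary attention
mask marks ear-bearing regions: Z = F ∗ G_σ (a second smoothing with the
same kernel), A(x) = 1 where Z ≥ th, else 0. The attention head is an
auxiliary supervised output; it does not gate the density path by default
(`attention_gating` flips that, since either wiring is defensible).

The network (see `earcount.network`) is a CSP convolutional backbone
(local detail) plus a pyramid-pooling transformer stage on the coarsest
grid (global context), fused top-down by AFF, decoded by parallel dilated
convolutions into a density head (abs activation; ReLU selectable) and an
attention head (sigmoid).

Assumptions worth stating: one point per ear (boxes are reduced to
centroids, which loses orientation/extent), a single σ for all ears
(no geometry-adaptive bandwidth), and approximate translation invariance
of appearance within an image.

## Ground-truth construction

* **Kernel**: unit-sum discrete Gaussian, radius ⌈3σ⌉ (truncates < 0.3 %
  of mass). Default σ = 8 px at the 1024-px image scale; the desk-scale
  preset uses σ = 1.5 px for 64-px images (scaled roughly with ear size).
* **Stamping**: each point is rounded half-up to a pixel; the kernel
  window is clipped to the grid and renormalised by its in-grid mass, so
  Σ F = N holds to 1e-6·N even for border/corner points. Points inside the
  half-open domain [0,W)×[0,H) are always accepted (a rounded index of W
  is clipped to W−1); points outside the domain raise.
* **Attention**: Z is computed by separable 1-D convolutions
  (zero-padded, same-size); threshold th = 0.001, inclusive (Z = th is
  active). Raising th never adds active pixels.
* **Resolution**: ground truth is built at crop resolution; if the head
  emits a coarser grid, `pool_to_stride` sums (not averages) cells so the
  count is conserved, and the binary mask is max-pooled.

Half-integer coordinates are a measure-zero caveat: round-half-up is not
symmetric under mirroring, so flip equivariance of the ground truth holds
exactly only away from exact .5 fractions.

## Losses

* `L_den`: mean over images of ‖P − G‖² / n_pixels (the per-image 1/N
  averaging is fixed; dividing by the pixel count keeps the magnitude
  resolution-independent).
* `L_c = 1 − SSIM`: local statistics use a window w (default the standard
  11×11 Gaussian, σ_w = 1.5; a uniform window is available), with
  μ = w∗x and second moments (w∗x² − μ²)·M/(M−1), M the window pixel
  count — for the uniform window this is exactly the 1/(M−1) sample
  estimator. C₁ = 1e-4, C₂ = 9e-4 (the 0.01²/0.03² convention on a unit
  dynamic range). SSIM(x,x) = 1 identically, independent of padding.
  SSIM is scale-sensitive; an optional `scale` multiplies both maps
  (default 1).
* `L_att`: mean binary cross-entropy with probabilities clamped at
  ε = 1e-7 for finiteness.
* Total: `L = L_den + L_c + α·L_att`, α = 0.1. Components are averaged
  (not summed) over the batch, consistently with L_den.

## Architecture defaults

| knob | default | note |
|---|---|---|
| stage channels | 64, 256, 512, 512 | stride-2/4/8/16 pyramid |
| CSP bottlenecks/stage | 1, 2, 2, 1 | split-path + shortcut, 1×1 mix |
| P2T | depth 2, 8 heads, FFN ×4 | LayerNorm after each residual |
| pyramid pooling | 1², 2², 3², 6² bins | 50 key/value tokens for a 32² query grid |
| decoder dilations | 1, 2, 3 | parallel, concatenated, 1×1 fused |
| output stride | 1 | nearest ×2 upsampling of the stride-2 head |
| head init | weights ×0.01 (density), ×0.1 (attention) | density values are ≪ 1; a He-scale head starts orders of magnitude too large and wastes the whole step budget shrinking |

The pooling "ratios" are implemented as adaptive output bin sizes (the
pyramid-pooling convention), which is what actually shortens the attended
sequence; ratio-style pooling including ratio 1 would make the key/value
set longer than the query set and defeat the point of pooling.

Normalisation is BatchNorm inside CBS blocks and LayerNorm inside the
transformer. Everything runs in float32 on the package's own reverse-mode
autograd engine (`earcount.network.autograd`); gradients of every primitive
are verified against central finite differences in float64.

## Training

Adam, initial learning rate 1e-4, batch size 4, 512-px random crops, hue
shift (±0.1 of the hue circle) and horizontal/vertical flips each with
probability 0.5. An epoch draws `crops_per_image` (default 4) random crops
from each image. Points are kept in a crop iff their centre lies inside it
(count stays integer-valued). All randomness flows through one seeded
generator; config + seed determine the log bit-for-bit on a single CPU.

The desk-scale preset (`smoke_config`) uses the reduced model
(16/32/64/64 channels, P2T depth 1), 64-px crops, σ = 1.5, 5 epochs and
learning rate 1e-3 — with ~160 k parameters and only a few hundred
updates, the full-scale rate would barely move the weights. Problem sizes
throughout the test suite are chosen at this desk scale (64–512 px inputs,
tens of images); they exercise every code path of the full recipe without
GPU-scale budgets.

## Synthetic data

`earcount.synthetic` emulates the statistical difficulties of field
imagery: K ~ Uniform(count range) bright, oriented, possibly overlapping
ellipses ("ears", with mild awn-like texture) over a darker low-frequency
clutter background with a random linear illumination gradient and additive
Gaussian noise, coloured into a wheat-like palette. Ellipse centres are the
exact ground truth. Presets: `desk` (256², 20–120 ears), `wedd_like`
(512², 82–245 ears, mirroring a high-density real split), `tiny` (64²,
5–20 ears).

What it does **not** emulate: genotype/maturity variation, perspective,
specular highlights, motion blur, annotation noise, or real ear morphology.
Passing tests therefore demonstrate that the pipeline is correct and can
learn the counting signal — not that the reported field-scale accuracies
of full-scale training transfer; those require the real datasets and
GPU-scale budgets, which are out of scope here.

## Numerical choices and edge cases

* Rounding is half-up; ties are the only asymmetry under flips.
* Boxes extending past the image are clipped before centroid computation
  (preserves the count; the alternative — dropping them — does not).
  How degenerate boxes were handled in the source datasets is not
  documented; clipping is this package's choice.
* A centroid exactly on the right/bottom edge is nudged one ULP inside the
  half-open domain.
* MAPE excludes zero-truth images with a warning rather than failing the
  whole evaluation (the realistic splits have min counts ≥ 4, so the case
  arises only in synthetic edge cases).
* Predicted counts are unrounded density integrals; rounding is left to
  callers.
* Non-finite training loss aborts with a diagnostic rather than continuing.
* Checkpoints store weights, BatchNorm running statistics, the model
  config, σ and th in one `.npz`.

## Known limitations

* CSP split ratios and block counts, P2T depth/heads, AFF reduction and
  decoder widths are conventions (exposed in `ModelConfig`), not
  canonically fixed values.
* The im2col convolutions favour clarity over peak speed; a full-scale
  512-px forward pass takes ~20 s on one CPU, so full-dataset training is
  out of reach here by design.
* Batch statistics make BatchNorm behave poorly at batch size 1 in
  training mode; use batch size ≥ 2 or eval mode.
* Evaluation runs on full images (reflect-padded to multiples of 16)
  without test-time tiling or augmentation.
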