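# Methods

`keratovae` is a self-contained testbed for a keratoconus-screening
pipeline built around generative image augmentation: synthetic color-coded
corneal topography maps stand in for clinical topographer exports, a
convolutional variational autoencoder (VAE) expands the labelled dataset,
and compact CNN classifiers are trained and evaluated with the diagnostic
metrics used in screening studies. This note documents the models, the
parameters that matter, the numerical choices, and what the synthetic data
can and cannot show.

## Synthetic topography maps

Clinical axial curvature maps are emulated by a four-parameter family of
dioptric fields on the unit disc:

    K(x, y) = AveK + (Cyl / 2) · cos 2(θ − axis) + A · exp(−d² / 2w²)

with `AveK` the average keratometry (D), `Cyl` the corneal cylinder (D)
producing the regular-astigmatism "bowtie", and a Gaussian cone of amplitude
`A` (D), width `w` and center offset both expressed in fractions of the
corneal radius. Four patterns are generated:

- **regular_astigmatism** (label `normal`): `A = 0`;
- **inferior_cone**: cone center offset 0.25–0.55 radii inferiorly
  (image convention: y increases downward, so inferior = larger y);
- **central_cone**: cone center within ~0.15 radii of the apex;
- **ab_srax** (asymmetric bowtie, skewed radial axis): a second lobe at 0.6×
  amplitude opposite the first, its radial axis rotated by a 10–35° skew.

Cohort sampling draws `AveK` and `Cyl` from per-class truncated Gaussians
with the study-population moments (keratoconus 48.68 ± 3.96 / 4.64 ± 2.53 D,
normal 44.15 ± 1.57 / 1.61 ± 1.48 D; `AveK` truncated to [30, 70] D, `Cyl`
to ≥ 0). Keratoconus pattern types follow a configurable mixture, default
0.6 / 0.2 / 0.2 (inferior / central / AB-SRAX). Cone amplitude is a
truncated Gaussian 5 ± 2 D on [1, 15] and width uniform on [0.15, 0.30]
radii — chosen once as values that keep the two classes overlapping in
color space (a mild keratoconic map with low `Cyl` can resemble a steep
normal), because a trivially separable cohort would make every downstream
comparison meaningless.

Rendering paints each in-disc pixel by its power bin on a 26-bin color
scale spanning [34, 52] D with the familiar blue→green→yellow→red
progression; out-of-range powers clamp to the end bins. The default canvas
is 300×300 px with a corneal radius of 0.35·min(H, W). The radius leaves
room for annotation clutter — near-gray text-like blocks emulating the
words and numbers on device printouts — which is placed outside a
1.1×radius **square** (Chebyshev) keep-out so that the disc's
bounding-square crop provably contains no clutter; a Euclidean ring would
let clutter leak into the crop's corners. Acquisition noise is modelled as
axis-aligned grid lines (default period 9 px, amplitude 40) plus
salt-and-pepper impulses (density 0.01), both removable by the preprocessing
chain by construction.

## Preprocessing

1. **Segmentation**: the map disc is the only saturated region, so an HSV
   mask (saturation ≥ 0.25, value ≥ 0.20) followed by
   largest-connected-component selection and a bounding-square crop
   recovers it to within 2 px of ground truth. Degenerate inputs raise
   `NoCorneaFound` (empty mask) or `SegmentationAmbiguous` (component
   touching all four borders).
2. **Denoising**: an iterated conditional median (a pixel is replaced by
   its 3×3 median only when it deviates from it by more than 25 gray
   levels, iterated to a fixed point) removes impulses and most line
   pixels without eroding intact content, making the operation nearly
   idempotent; a spectral notch then attenuates any coefficient on the two
   frequency axes exceeding 6× the axis median, outside a DC guard of 1/12
   of the axis length. The guard encodes the assumption that map content
   varies slower than ~12 px while grid artifacts are faster; a plain
   unconditional median + full-plane notch measurably damaged clean maps.
3. **Ordered grayscale**: each pixel is assigned its nearest scale color
   (Euclidean in RGB) and the intensity `bin / (n_bins − 1)`, then resized
   to 104×104. This conversion is order-isomorphic to the dioptric scale —
   sorting pixels by intensity equals sorting by power bin — which is the
   property a luminance-weighted grayscale destroys (adjacent hue bins do
   not have monotone luminance). Its exact inverse (intensity → bin →
   color) converts decoder outputs back to color space for the
   classifiers.
4. **Model inputs**: VAE 104×104×1 in [0, 1]; custom CNN 50×50×3 in
   [0, 1]; transfer backbones at their declared side (default 224) in
   [−1, 1] via x/127.5 − 1.

## The VAE

Encoder: three 3×3 stride-2 convolutions (64, 32, 16 filters, "same"
padding with ceiling division — the only convention under which
104 → 52 → 26 → 13 and the flatten width is 13·13·16 = 2704), a 128-unit
dense layer, and two heads emitting the posterior mean μ and log σ (σ is
exponentiated, guaranteeing positivity). The latent variable is scalar by
default (`latent_dim = 1`, i.e. two posterior parameters); larger latents
are configurable. Decoder: dense 2704 → reshape 13×13×16 → three 3×3
stride-2 transposed convolutions (16, 32, 64 filters), each implemented as
the exact adjoint of the encoder-style convolution, then a pointwise
sigmoid projection to one channel — the minimal closure of the stated
64-channel chain back to 104×104×1, and far cheaper than a spatial kernel
on a 104×104×64 tensor.

Training minimizes the negative ELBO: a per-pixel Bernoulli reconstruction
negative log-likelihood (MSE available via `recon_loss="mse"`) plus the
closed-form Gaussian KL to the N(0, 1) prior,
`KL = −½(1 + ln σ² − μ² − σ²)`, with the reparameterization
`z = μ + σ·ε`. Defaults follow the study protocol: RMSprop (ρ = 0.9),
learning rate 1e-4, 50 epochs, batch 32 (batch size is our choice; the
protocol does not state one), augmentation by random horizontal flip and
rotation up to 10% of a full turn (±36°). Reported losses are per-epoch
means of per-batch mean (recon + KL).

Generation paths:

- **latent grid**: decode an evenly spaced (μ, σ) grid — 30×30 = 900 cells
  at study scale — with one ε draw per cell, z = μ + σ·ε. Default ranges
  μ ∈ [−3, 3], σ ∈ [0.1, 2.0] (the protocol states that fixed ranges were
  used but not their values).
- **class-conditional augmentation** (`synthesize_to_target`): per class,
  encode randomly chosen originals, sample z from their posteriors, decode,
  and label the output with the source's label and `origin="synthesized"`,
  until each class reaches the target count. Posterior-conditioned sampling
  is the minimal rule consistent with training one unconditional VAE on
  both classes yet labelling its outputs.

## Classifiers

**Custom CNN** (50×50×3): three 3×3 stride-2 convolutions (64/32/16),
flatten (7·7·16 = 784), dense 128 → dropout 0.25 → dense 64 → single
sigmoid unit. Score 1 = keratoconus. Fivefold cross-validation with random
shuffling, 15 epochs per fold, RMSprop at 1e-4, binary cross-entropy. The
two fully-connected widths (128, 64) are our choice; the protocol fixes
their count but not their widths.

**Transfer recipe**: data-level augmentation (horizontal flip, 20%
rotation) → rescale [0, 255]→[−1, 1] → frozen backbone → global average
pooling → dense 512 → dropout 0.2 → sigmoid unit. Phase 1 trains the head
only for 15 epochs (Adam, 1e-4; backbone bit-identical before/after);
phase 2 unfreezes the top `finetune_unfrozen_layers` (default 3)
parameterized backbone layers for 10 more epochs. Backbones are a
pluggable interface declaring an input side and emitting a spatial feature
map; a deterministic random-weight `StubBackbone` exercises the protocol
so no external pretrained weights are ever required.

All networks run on a small numpy layer engine (`keratovae.nn`) written
for this package: im2col convolutions, adjoint-based transposed
convolutions, and RMSprop/Adam, with every gradient checked against
numerical differentiation in the test suite. Parameters serialize to
`.npz` plus a JSON architecture manifest and reload bit-exactly.

## Splitting and evaluation

Splits are stratified 80/20 per class with 10% of the training pool held
out for validation, and the test share is drawn **exclusively from
original images** — synthesized images may only ever appear in training.
In the paired augmentation experiment the originals-only and augmented
conditions share the identical test set.

Evaluation follows screening conventions: a 2×2 confusion matrix at a
score threshold (default 0.5); accuracy, sensitivity, specificity; PPV and
NPV either from raw counts or prevalence-adjusted by Bayes' rule (the
module records which mode was used — the two disagree whenever the assumed
prevalence differs from the test-set mix, so reports are explicit about
it); ROC by threshold sweep over the unique scores with a +∞ sentinel,
trapezoidal AUC (provably equal to pairwise concordance with ties counted
½); and the operating point closest to sensitivity = specificity, ties
broken by larger sensitivity + specificity then smaller threshold. Metrics
with an empty margin are returned as NaN and flagged rather than raised,
so one degenerate margin does not void a report.

Grad-CAM saliency weights the target convolutional layer's activations by
the spatial mean of the positive-class score gradient, rectifies, min-max
normalizes and upsamples; the map is invariant to positive rescaling of
downstream weights. Overlays blend `(1−α)·image + α·colorized(heat)`
through the same dioptric color scale used for rendering.

## Scales, runtimes and reproducibility

Two built-in experiment scales:

| scale | originals | target/class | VAE epochs | CNN epochs |
|-------|-----------|--------------|------------|------------|
| paper | 978 + 780 | 2000 | 50 | 15 |
| demo  | 100 + 100 | 200  | 3  | 6  |

The demo scale was sized once so that the full pipeline — synthesis,
preprocessing, VAE training, augmentation, paired classifier training and
evaluation — runs end-to-end on a single CPU in minutes. The acceptance
script smoke-trains the VAE (one epoch on a ~125-image subsample) before
the study-scale augmentation count, since dataset bookkeeping is exact
regardless of fit quality. Every stochastic stage receives a seed derived
from the global seed via `numpy.random.SeedSequence`; identical
(config, seed) reruns produce byte-identical CSV outputs on the same
build.

## What the synthetic cohort does and does not show

The generator reproduces the *geometry* of the four named topographic
patterns, the published per-class index distributions, device-style
annotation clutter and periodic acquisition noise. It does not model
Placido-ring optics, elevation or pachymetry maps, inter-device color
scales, eyelid/tear-film artifacts, or subclinical keratoconus. Passing
tests therefore demonstrate that the pipeline's machinery is correct and
that VAE augmentation helps *on data with these statistics*; they do not
certify clinical accuracy, and the package deliberately makes no claim to
reproduce the headline accuracies reported on proprietary clinical images.

## Known limitations

- A scalar latent makes decoded images lie near a one-dimensional image
  manifold; decoded samples are blurry class archetypes rather than sharp
  individual maps. This suffices for the directional augmentation claim
  but not for photorealistic synthesis.
- The numpy engine is single-threaded and CPU-bound; study-scale epoch
  counts (50/15/10) are practical but slow, which is why the demo scale
  exists.
- The notch denoiser assumes axis-aligned periodicity; rotated moiré
  patterns would require a full-plane notch with a content model.
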