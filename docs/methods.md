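# Methods

This note documents the models, the synthetic study conditions, the numerical
choices and the known limitations of the package. The worked numbers quoted in
the README are produced by `scripts/acceptance.py`; nothing here states a
result the test suite or that script does not itself compute.

## Problem setting

Screening mammography produces vastly more normal images than cancers, which
makes supervised lesion detection label-hungry. The unsupervised alternative
implemented here trains a generative model on lesion-free images only, so that
the generator's manifold covers normal anatomy but not lesions. A test image
is then *projected* onto that manifold (its latent code optimised so the
synthesised image matches it), and the residual between the image and its
reconstruction highlights whatever the generator could not reproduce — the
anomaly. A scalar anomaly score, a Youden-index threshold and standard
classification metrics complete the pipeline.

## Phantom simulator (the study conditions)

Clinical mammograms are not redistributable, so every stage is exercised on a
seeded phantom simulator whose records carry the same metadata a DICOM archive
would provide (12-bit pixels, window centre/width, laterality) plus
ground-truth lesion masks.

A phantom is a half-ellipse breast silhouette flush against the chest-wall
edge (craniocaudal-view geometry), filled with Gaussian-blurred white noise
rescaled to a 12-bit tissue intensity range, over a dark background. An
optional lesion adds a clipped-Gaussian bump (radially tapered, like a mass
with a dense core and soft margin) whose mask is recorded exactly.

Defaults, with the reasoning behind them:

| parameter | default | why |
|---|---|---|
| image size | 128 × 96 px | taller-than-wide, like clinical geometry (2294 × 1914) at desk scale; ~1 px ≈ 1 mm |
| breast semi-axes | (52, 72) px | silhouette fills most of the field, as in CC views |
| parenchyma smoothness σ | 10 px | fibroglandular structure on the centimetre scale; after the 4× downscale to 32 px structures still span multiple pixels. (Much smaller σ produces per-pixel noise that no generative model could reconstruct case-specifically, which would swamp any lesion signal in the residual — unrealistic for parenchyma and uninformative as a benchmark.) |
| tissue range | 1200–2600 (12-bit) | mid-range densities with full display contrast after windowing |
| background | 100 | near-black air region |
| lesion radius | 14 px (jittered 0.8–1.2×) | ~1.5 cm mass, T1/T2 scale |
| lesion contrast | +1400 (= tissue range width) | a conspicuous dense mass: the added density equals the full parenchymal dynamic range, so the core reads denser than the densest fibroglandular tissue and saturates under the tissue window, as dense masses do on a parenchyma-windowed display |
| window | centre (lo+hi)/2, width hi−lo | spans exactly the tissue range, so parenchyma uses the full 8-bit scale and denser-than-tissue structure clips to white |

Datasets derive per-record seeds as `base_seed + index`; breast semi-axes are
jittered ±10 % and lesion position/radius jittered inside the silhouette, so
records vary but are bit-reproducible. Two invariants are enforced by
construction and tested: lesions lie entirely inside the silhouette, and the
lesion region is brighter than the matched lesion-free region for any contrast
≥ 100.

What the phantoms do **not** model: anatomically realistic parenchymal
architecture, pectoral muscle, skin line, calcifications, benign masses that
mimic cancer, positioning/compression variability. Passing the end-to-end
tests therefore demonstrates that the pipeline's machinery works and that its
central premise holds for conspicuous masses on reconstructable backgrounds —
not that clinical performance would match.

## Preprocessing

The conditioning chain is: (1) windowing — the linear map of
[centre − width/2, centre + width/2] onto [0, 255], clamped, rounded half-up;
(2) laterality alignment — right-breast images are mirrored so all breasts
abut the left edge; (3) zero-padding on the right to a square; (4)
area-averaging downscale to the working resolution; (5) breast-mask
extraction. Every float→integer conversion rounds half-up (0.5 away from
zero), making the whole chain bit-exact; windowing is monotone, the 'R' flip
is an involution, padding never alters existing pixels, and a constant image
downscales to itself.

Decisions the source protocol leaves open, fixed here: the downscale kernel is
exact box (area) averaging implemented as a row-stochastic overlap matrix (so
non-integer ratios such as 2294→512 are handled exactly); the breast mask is
Otsu thresholding followed by largest-connected-component selection and hole
filling — the standard mammography heuristic; coordinates are row-major,
0-based, top-left origin. The default working resolution is 64 px
(configurable up to 512); the end-to-end experiments in this repository run at
32 px.

## Generative model

A reduced style-based GAN retaining the defining mechanisms of the
second-generation style architecture:

* **Mapping network** — pixel-normalised latent z (64-d standard normal) through
  an 8-layer leaky-ReLU MLP into W (64-d).
* **Weight-demodulated synthesis** — from a learned 4×4 constant, one 3×3
  modulated convolution per resolution (styles are affine images of w; weights
  are scaled per input channel and renormalised per output channel), nearest
  2× upsampling, and a per-resolution 1×1 "toRGB" skip accumulated across
  scales, with a final tanh pinning the output to [−1, 1]. Demodulation makes
  the per-channel output variance invariant to positive rescaling of the style
  vector, which is tested directly.
* **Noise injection** — per-pixel Gaussian noise scaled by a learned
  per-layer strength after each convolution (strength initialised at 0.1 so
  the mechanism is active from the start); seeded, so synthesis is
  bit-reproducible and ablatable.
* **Discriminator** — residual downsampling blocks mirroring the generator's
  widths, two dense layers to one logit.
* **Objective** — non-saturating logistic losses with R1 gradient penalty
  (γ = 10) on real batches; Adam (lr 0.001, batch 8, betas (0, 0.99)).
  Path-length regularisation, style mixing, truncation and progressive growth
  are omitted at this scale.

Because no deep-learning framework is assumed, the package carries a minimal
reverse-mode autodiff engine (`mammogan._autodiff`) whose backward rules are
themselves differentiable primitives — that is what makes the R1 penalty (a
gradient of a gradient) computable. Convolution is im2col + matmul; its
adjoint pair (im2col/col2im) gives exact higher-order gradients. All numeric
work is float32; gradient checks against central differences (including the
second-order R1 path) are part of the suite.

Channel widths halve per resolution doubling from 32 at 4×4 (clamped to
[8, 64]), so a 32×32 generator has ~60k parameters — deliberately small
enough that one CPU trains it in minutes.

**Snapshot selection.** Training records a parameter snapshot with a Fréchet
distance against a held-out real batch at step 0 and every fixed interval; the
model returned is the minimum-FID snapshot (ties → earliest). This is the
guard against late-training mode collapse: a collapsed generator scores worse
than an earlier healthy one, so continuing to train can only change which
snapshot wins, never degrade the selected model.

## Projection and anomaly scoring

Projection starts at w = mapping(z_seed) for each seed — seed diversity is the
point, so no average-latent initialisation — and runs Adam (lr 0.05) on a
single shared w (no per-layer w+ by default), minimising

    pixel-MSE + Σ_l MSE(f_l(x), f_l(target))

where f_l are three stride-2 leaky-ReLU feature layers of a fixed-seed random
convolutional pyramid. A random (untrained) feature stack is a valid
perceptual distance for optimisation purposes and keeps the package fully
offline and deterministic; a pretrained feature network can be plugged in via
the same interface. Synthesis noise is frozen at the projection seed, and the
best-loss iterate (not the last) is returned, so reported losses are monotone
in the step budget. Noise-buffer optimisation and learning-rate ramping are
deliberately omitted.

The anomaly score of a case is the sum of the absolute 8-bit difference
between the image and the mean of the per-seed reconstructions, restricted to
the breast mask, divided by the breast area. Absolute (unsigned) differences
are used because anomalies can be hyper- or hypo-intense; masking excludes
background generator artefacts; area normalisation makes scores comparable
across breast sizes. The operating threshold maximises the Youden J index
over candidates halfway between consecutive distinct scores (±∞ sentinels,
ties → lowest threshold), with score ≥ threshold ⇒ cancer. The threshold is
fitted on the same evaluation set it classifies (one test set, no calibration
split), so thresholded metrics are optimistic; AUC is threshold-free.

## Evaluation statistics

* **Fréchet distance** — ||μa−μb||² + Tr(Σa+Σb−2(ΣaΣb)^½) on embedding
  statistics; the matrix root is an eigendecomposition of the symmetrised
  product with negative eigenvalues clamped, εI (ε = 1e−6) regularisation for
  near-singular covariances, and the trace term averaged over both operand
  orders plus compensated summation so the distance is *exactly* symmetric.
* **FID / inception score** — computed against pluggable feature/classifier
  networks; packaged defaults are fixed-seed random convolutional networks, so
  absolute values are not comparable to pretrained-Inception numbers (which
  would require the original training data and network), but zeros, bounds,
  symmetry and closed-form limits are exact and tested. IS is always in
  [1, K].
* **MS-SSIM** — 11-tap Gaussian window (σ 1.5), K1/K2 = 0.01/0.03, the
  standard five-scale exponents (renormalised when image size only supports
  fewer scales), 2×2 average pooling between scales; contrast-structure terms
  are clamped at 0 before the fractional exponents. Single-scale values are
  cross-checked against scikit-image's SSIM.
* **PSNR** — 10·log10(max²/MSE), +∞ for identical images.
* **Confusion metrics** — exact rationals (via `fractions`) reported as
  percentages; zero-denominator metrics are NaN-flagged, never silently 0.
  Accuracy is checked to be the prevalence-weighted combination of
  sensitivity and specificity.
* **ROC/AUC** — scikit-learn's curve (trapezoidal, simultaneous steps for
  ties), verified in the suite against an O(n²) Mann–Whitney pair-counting
  oracle with half credit for ties.

## Scaled end-to-end experiment

The suite and the acceptance script run the full workflow at desk scale:
300 lesion-free phantoms, 32×32 working resolution, 1200 training steps with
snapshots every 200, then the 9-seed pipeline (projection budget 200
steps/seed) on 20 lesioned + 20 lesion-free held-out phantoms. These
problem sizes were chosen so the whole experiment completes in minutes on one
CPU while leaving the mechanism intact; they are two to three orders of
magnitude below a clinical training run, and the reported metric values are
properties of the phantom conditions, not reproductions of clinical numbers.

During development the residual decomposition (mean residual inside vs outside
the true lesion masks) was the diagnostic that drove the phantom defaults
above: lesions must be conspicuous relative to the *reconstructable* part of
the background, or no residual-based detector can see them — the same
condition under which the clinical method is expected to work.

## Known limitations

* The default perceptual distance and FID/IS embedders are untrained random
  networks: right mathematical structure, no semantic features. Absolute
  FID/IS/MS-SSIM/PSNR values are only comparable within this package.
* Projection optimises a single 64-d w; reconstruction fidelity is limited by
  design, and part of every lesion is absorbed into the reconstruction (the
  score separation rests on the unabsorbed remainder).
* Phantoms model one lesion phenotype (a bright mass). Benign-vs-malignant
  discrimination, calcifications, and architectural distortion are out of
  scope, as are MLO views and pectoral-muscle handling.
* Youden thresholding on the evaluation set itself mirrors a single-test-set
  protocol and inflates thresholded metrics relative to a held-out
  calibration split.
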