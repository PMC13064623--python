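# Methods

## Problem setting

Confocal microscopy resolves to ~200 nm; STED microscopy resolves the same
field of view several-fold finer at the cost of photobleaching,
phototoxicity and experimental complexity. The package learns the
confocal→STED (or confocal→deconvolved-STED) mapping from image pairs —
or, with CycleGAN, from *unpaired* image collections — and evaluates how
much of the resolution gap a generator closes. A second use is indirect
quality control: a generator trained only on high-quality data embodies a
standard of "what a good acquisition looks like", and pixel-wise deviation
maps between its predictions and new acquisitions flag bleaching, labeling
gaps or other degradation without any ground truth.

## Generator architectures and the parameter ladder

All generators are encoder/decoder U-Nets with stride-2 4×4 convolutions,
mirrored stride-2 transposed convolutions, skip connections, LeakyReLU(0.2)
/ ReLU activations and a tanh output. Two conventions keep the parameter
count exactly reproducible:

* **bias-free convolutions** everywhere in the generator, and
* **non-affine instance normalization** (no learnable scale/shift),

so every trainable scalar lives in a convolution kernel. With conv biases
the second ladder entry would round to 10.46 M instead of the published
10.45 M; bias-free weights reproduce all five doubling-family counts at
printed precision, which is why this convention is frozen.

**Doubling family** (Models 1–4, 6): 7 resolution levels for 128-px tiles
(1×1 bottleneck), widths `min(base·2ⁱ, 8·base)` for base 64/32/16/8/4.
Model 6 uses base 4 with a 32-channel bottleneck: that is the only base
width whose count (0.164 M ≈ 41.8/256) matches the published ladder, so
the base-4 reading is adopted where the alternative (base 8, 64-channel
bottleneck) is arithmetically inconsistent.

**Fixed family** (Models 5, 7–9): constant width 64/32/16/8 at every
level. Depth, kernel and skip mode are not quoted anywhere, so they are
**calibrated**: `generators.calibrate_fixed_family` exhaustively scores
depth ∈ {3..7} × kernel ∈ {3,4} × skip ∈ {concat, add} against the four
published counts (0.53 / 0.13 / 0.035 / 0.009 M). The winner —
**depth 4, kernel 4, concatenated skips** — reproduces 0.53, 0.13 and
0.009 exactly and lands at 0.0335 M (prints 0.034) where 0.035 M was
published. The search also shows *no* configuration in the space matches
all four jointly: the required quadratic width coefficients
(count/width²) are non-monotone across the four widths, so the published
quadruple is mutually inconsistent with any single architecture. The
0.034-vs-0.035 residual is therefore a documented finding, not a tuning
target; the frozen triple is the unique argmax of the calibration.

Dropout (p = 0.5, training only) is placed on the decoder levels at the
width cap in the doubling family, following Pix2Pix practice; the
fixed-channel variants train without dropout, following CycleGAN practice.
Dropout carries no parameters, so the ladder is unaffected.

## Discriminator

A PatchGAN: four 4×4 convolutions (widths 64-128-256-512, stride 2 except
the last two layers) followed by a 1-channel projection, emitting a 2-D
grid of patch logits (~70-px receptive fields). Pix2Pix uses the
conditional form (source ⊕ candidate concatenated on channels); CycleGAN
discriminators see the candidate alone. One discriminator configuration is
shared across all nine generator variants.

## Objectives and training

* Pix2Pix: non-saturating BCE adversarial loss + λ·L1, λ = 100.
* CycleGAN: least-squares adversarial loss, cycle weight λ_cyc = 10,
  identity weight λ_id = 5, and a 50-image seeded pool of historical fakes
  for discriminator updates.
* Adam (lr 2·10⁻⁴, β = 0.5/0.999), batch size 4, linear learning-rate
  decay to zero starting at epoch 100 of 200; checkpoints every 5 epochs,
  with the final epoch always checkpointed when off-cadence.
* Per-iteration augmentation samples one of the 8 dihedral transforms of
  the square uniformly and applies it identically to both pair members;
  no intensity augmentation.
* `seed_all(seed)` resets the package RNG; every stochastic component
  (weight init, batch order, augmentation, dropout, pool) draws from
  generators derived from explicit seeds, so a run is bit-reproducible on
  one machine.

The network stack is a pure-NumPy reverse-mode core: convolutions are
lowered to BLAS matrix products through an im2col gather (a loop over the
k² kernel offsets, vectorized over batch and space), transposed
convolutions are the exact adjoint (col2im scatter-add), and all layer
gradients are verified against central differences in float64 in the test
suite. Training arithmetic is float32.

## Image conventions and preprocessing

Images are single-channel 2-D grids, float throughout (integer TIFFs are
converted on read, never truncated), row-major with 0-based indices. Unit
range [0, 1] is the metric domain; the affine map v ↦ 2v − 1 moves images
into the tanh range for the networks. The preprocessing pipeline is:

1. **Contrast**: saturated-quantile linear stretch (default 0.35%
   saturated pixels, the ImageJ convention).
2. **Segment/crop**: Gaussian smoothing (σ = 1 px) of the *target*, Otsu
   threshold, largest connected component, bounding box + 8-px margin;
   the identical box crops both pair members. The operator choice
   (Gaussian + Otsu + largest component) is ours — it is parameter-free
   and reproducible.
3. **Pad**: zero-pad to 128×128 with floor-centered offsets. Oversize
   crops raise rather than resize: rescaling would distort morphology and
   apparent pixel size, so no operation in the pipeline interpolates.
4. **Normalize**: per-image min-max to [0, 1] (percentile clipping is
   available but off by default; whether normalization should be per image
   or per dataset is not externally specified — per image is the package's
   choice and is flagged in the config).

## Synthetic phantoms

The generator emulates cilia-like structures: 1–3 smooth random
curvilinear tracks (cubic splines through control points ordered along
their principal axis) rasterized with a Gaussian cross-section of 2.5 px
FWHM. Each emitter map is rendered as

```
image = Poisson(photon_scale · (emitters ⊛ Gaussian PSF)) / photon_scale
        + N(0, read_noise²)
```

with reflective boundary handling and a unit-sum PSF. Modalities differ
only in PSF width and noise — σ = 4.0 px (confocal), 1.0 px (STED),
0.7 px (dSTED); photon scales 500/200/800 — so renderings of one phantom
are co-registered by construction, and the resolution ordering
dSTED ≤ STED < confocal holds by design and is verified by FRC. The
emitter FWHM (2.5 px) sits between the STED and confocal PSF widths, which
produces the diagnostic two-peak vs single-peak cross-profiles across a
membrane pair. dSTED is emulated as a narrower-PSF, lower-noise render;
iterative maximum-likelihood deconvolution itself is out of scope.

Low-quality variants multiply row r by `exp(−bleach_rate·r)` (scan-order
bleaching, default 0.01/line), zero random disc-shaped patches of the
bright support (labeling gaps, fraction 0.3), and add extra Gaussian noise
(σ = 0.05). These magnitudes are free parameters — no quantitative
description of sub-optimal acquisition conditions exists to copy — and
were chosen once so that the high/low classes separate under the
non-reference metrics (Otsu-SNR drops by several-fold).

What the phantoms do **not** model: vectorial/aberrated PSFs, depletion
photophysics, 3-D structure, sample drift, detector artifacts. Tests
passing on phantoms therefore certify the pipeline's mechanics and
relative orderings (resolution ladder, quality separation, baseline
improvement), not absolute performance on experimental data.

## Metrics

* **SSIM**: standard Gaussian-window form (11×11, σ = 1.5, K1 = 0.01,
  K2 = 0.03), via scikit-image.
* **PSNR**: 10·log10(range²/MSE), +∞ on identical images.
* **Normalized PSNR**: min(PSNR/cap, 1) with cap 40 dB (config-exposed);
  the self-comparison maps to 1 by convention. The normalization is
  under-specified externally; this capped-ratio definition is the
  package's reconstruction, consistent with the (1.0, 1.0) self-reference
  point.
* **FRC**: per-ring normalized cross-spectral correlation over 1-px rings,
  Hann apodization on by default. Resolution uses the fixed 1/7 threshold
  with linear interpolation of the crossing; never-crossing curves are
  Nyquist-limited (2 px, flagged). Curve smoothing before the crossing
  search is available (`smooth_window`) but off by default so that the
  crossing is exactly the interpolated threshold intersection.
  High-frequency disagreement is 1 − mean FRC over the upper half of the
  Nyquist band (the band is not externally specified; upper half is the
  package default).
* **Non-reference**: Otsu split SNR `(mean_fg − mean_bg)/sd_bg` and
  Laplacian-variance edge preservation (Tenengrad optional) on [0, 255]
  rescaled data. These formulas are reconstructions; only *orderings*
  (high vs low quality, sharp vs blurred) are asserted, never absolute
  values.

## Statistics

5-fold cross-validation at the image-pair level (sizes differing by ≤ 1,
fixed master seed, no stratification); each pair validates exactly once.
Per-image metrics are pooled across folds before model comparison (stated
here because per-fold testing is the alternative reading). The model
effect is tested with a closed-form one-way within-subjects ANOVA,
F = MS_model / MS_(model×subject), df (m−1), (m−1)(n−1); no sphericity
correction by default, Greenhouse–Geisser available. Pairwise
localization uses paired t-tests on per-image differences with Holm's
step-down adjustment (via statsmodels). The ANOVA's type-I error under an
i.i.d. null (100 subjects × 5 models) is verified at α = 0.05 within
[0.035, 0.065] over 1000 replicates.

## Desk-scale problem sizes

CPU-scale defaults used by the test suite: training smoke runs use 64×64
phantom tiles (the phantom default remains 128), 64 pairs, batch 4,
30 epochs, Model 9, and a held-out set of 16 pairs. At this scale the
unpaired CycleGAN run drops its cycle loss ~6.5-fold and beats the
confocal baseline's held-out SSIM; these sizes are the package's choice of
a minimal convincing experiment, and larger runs only require changing the
config. Checkpoints serialize weights + config echo; checkpoint file
*size* is serialization-format dependent and deliberately not a tested
quantity.

## Known limitations

* The NumPy core is single-device, float32, CPU-oriented; it is built for
  the small fixed-channel models, and the 41.8 M-parameter Model 1 trains
  only slowly (it is instantiated and counted, not smoke-trained, in the
  tests).
* Registration of real (non-synthetic) pairs is out of scope; synthetic
  pairs are born registered and the pipeline assumes registered inputs.
* Absolute agreement with externally reported SSIM/PSNR/FRC values on
  experimental cilia or mitochondria data is not claimed anywhere; the
  phantom-scale experiments establish orderings and mechanics only.
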