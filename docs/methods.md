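# Methods

This note documents the models, parameter choices and numerical
decisions behind `rdisc`, and what the synthetic-data tests do and do
not establish about real spectra.

## Signal model

A measured single-cell Raman spectrum is modelled as

    y(x) = Σₖ hₖ·L(x; xₖ, wₖ)  +  B(x)  +  ε(x),    x in cm⁻¹,

where `L` is a Lorentzian line of height `hₖ` and FWHM `wₖ` (the
standard line shape for Raman bands), `B` is a broad, smooth,
non-negative autofluorescence background varying on scales of hundreds
of cm⁻¹, and `ε` is additive white Gaussian detector noise. The QC
chain assumes exactly this separation of scales: noise lives in the
finest wavelet detail bands, Raman bands at 10–30 cm⁻¹ widths, and the
background below that in frequency.

## Quality control

**Denoising.** Discrete wavelet transform, Daubechies-4, 3 decomposition
levels, symmetric boundary extension (output truncated to the input
length). Soft thresholding at the universal threshold `σ̂√(2 ln n)`
with the median-absolute-deviation estimate `σ̂ = MAD(d₁)/0.6745` from
the finest detail band. By default **all** detail levels are
thresholded: shrinking only the finest level leaves mid-frequency noise
whose curvature is of the same order as weak marker bands, which defeats
the curvature gate downstream (measured on the simulator: 16 spurious
peaks per spectrum with finest-only shrinkage vs 0.08 with all-level
shrinkage at the default λ). `QCConfig.shrink_levels` restores any
other choice. A zero threshold (noise-free input) skips shrinkage
entirely.

**Baseline.** Troughs are strict minima of a ±`trough_window` (default
25) channel window; both endpoints are always anchors so the piecewise
baseline covers the grid. Adjacent troughs are joined by a straight
line by default (`baseline_order=1`), which is continuous, exact at the
troughs and cannot overshoot; an optional quadratic per segment
(through the two troughs and the interior minimum) is available for
strongly curved backgrounds. Subtraction floors at 0 by default
(physical non-negativity). Because troughs sit at the bottom of noise
excursions, the corrected off-peak level is a small positive residual,
not exactly zero — denoising before baseline estimation keeps this bias
at the residual-noise scale.

**Normalization.** Min-max to [0, 1], exact at both ends. A spectrum
whose range is zero up to a relative 1e-12 is rejected as degenerate
(covers both truly constant input and a flat trace after the wavelet
round trip).

## Discretization

Three conjunctive gates on the normalized spectrum (half-window
M = 20 channels):

1. strict local maximum over ±M (truncated at boundaries);
2. curvature κ = |f″|/(1+f′²)^(3/2) > λ, central differences with
   **unit channel spacing**, so λ is grid-independent; multiply by the
   squared channel spacing to reason in cm⁻¹ units;
3. intensity above the noise level: the mean of the minimum-mean window
   among all width-M windows whose variance is at most the median
   window variance (parameter-free selection of quiescent regions, with
   a relative 1e-12 slack so near-constant windows tie with constant
   ones).

**Calibration of λ.** The threshold separates three curvature
populations measured on the simulator at its default settings
(2,048 channels over 400–3,200 cm⁻¹, so 1.37 cm⁻¹/channel):

| population                               | apex curvature |
|------------------------------------------|----------------|
| broad flat bump (≥200 cm⁻¹ wide, h=0.1)  | ≈ 4e-5         |
| residual denoised noise wiggles (p90)    | ≈ 1.2e-3       |
| weakest marker band (h≈0.2, FWHM 30)     | ≥ 2.5e-3       |

The default λ = 2e-3 sits between the second and third: it rejects
background bumps and noise while passing every marker population, giving
95.8% planted-peak recall and 0.08 spurious peaks per spectrum at the
default noise level. λ is deliberately the only tuned constant in the
pipeline and is exposed on the CLI (`--curvature-min`).

A consequence of min-max normalization worth knowing: a spectrum with
*no* structure at all is rescaled so its largest noise bump becomes 1.0,
and the gates then retain a few dozen of its 2,048 channels. Absolute
spurious-peak bounds are therefore only meaningful when real bands are
present (the normalization anchor); the recovery tests plant them.

## Similarity

Peak matching is a one-to-one maximum-cardinality matching under the
|Δposition| ≤ δ (default 10 cm⁻¹) constraint, ties broken by minimal
total distance. Because both position lists are sorted and
compatibility is an interval condition, an optimal matching is always
non-crossing, so an O(n·m) dynamic program over the two sorted lists is
exact; the test suite verifies it against exhaustive search over all
matchings up to 8 peaks per side. The DP is symmetric in its arguments,
making all three scores order-independent.

Score conventions: `s1 = |matches|/(n_a + n_b − |matches|)` (0 when both
spectra are empty); `s2` is the Pearson correlation of matched
intensities, defined 0 for fewer than 2 matches or a constant matched
vector (extending the no-common-peaks convention); the combined score is
`√s1 · s2`.

## Classification

- **k-NN**: default k = 1 (exposed as a flag); similarity ties broken
  by earlier dataset order via a stable sort, vote ties by the nearest
  neighbour's label — both rules are deterministic.
- **Vocabulary**: training peak positions pooled, sorted and
  single-linkage merged (adjacent gap ≤ δ joins a cluster), cluster
  mean as the reference position. Merged clusters are provably > δ
  apart. Vectorization takes, per reference position, the intensity of
  the nearest peak within δ, else 0.
- **LDA**: multi-class Fisher discriminant, pooled within-class
  covariance with denominator (n − C), regularized as `S + ridge·I`
  (default ridge 1e-3), equal priors, Cholesky solve. The ridge is
  required for full spectra, where p > 1,000 exceeds n; on
  well-conditioned data the classifier's predictions agree with
  scikit-learn's LDA (checked in the tests, where sklearn serves as an
  independent oracle, not as the implementation).
- **Evaluation**: stratified per-class 60/40 random splits (plain random
  splitting would occasionally empty a small class), repeated 10 times;
  seeds spawn from one master `SeedSequence`, so reports are
  bit-reproducible. The vocabulary and LDA parameters are refitted per
  repeat on the training side only.

## Simulator

Class templates combine 8–14 Lorentzian markers: a subset of ten common
biomolecule bands (785, 1003, 1095, 1260, 1340, 1450, 1580, 1660, 2880,
2935 cm⁻¹) shared across classes, plus 3–5 class-unique bands rejection-
sampled to lie ≥ 25 cm⁻¹ from every other class's markers. Defaults,
chosen once as representative of well-acquired single-cell spectra:

| parameter     | default | meaning                                          |
|---------------|---------|--------------------------------------------------|
| n_shifts      | 2048    | channels over 400–3,200 cm⁻¹                     |
| FWHM          | 10–30 cm⁻¹ | marker width range                            |
| heights       | 0.2–1.0 | relative band heights (max anchored at 1)        |
| baseline_amp  | 1.5     | fluorescence amplitude, relative to tallest band |
| noise_sigma   | 0.01    | additive noise σ → weakest-band SNR 20           |
| jitter_sigma  | 1.5 cm⁻¹| per-cell band position jitter                    |
| height_cv     | 0.1     | per-cell multiplicative height scatter           |

plus a per-cell lognormal global intensity scale (σ = 0.1 in log space)
mimicking exposure variation. The background is a sum of 2–3 Gaussians
of width ≥ 500 cm⁻¹; intensities are floored at 0.

**What the simulator does not emulate**: cosmic-ray spikes, detector
response curves, wavenumber miscalibration between instruments,
band-shape asymmetry, and — most importantly — the spectral *closeness*
of real congeneric species. The synthetic classes are separable by
construction, so perfect classification accuracy here demonstrates that
discretization *preserves* the discriminative information present, not
that any particular accuracy would be reached on real organisms.

## Problem sizes

The evaluation scale used throughout the tests and the acceptance
script — 5 classes × 40 cells × 2,048 channels, 10 split repeats, 100
spectra for condensation/recovery statistics — was chosen as the
smallest scale at which class structure, stratified splitting and the
median statistics are all meaningfully exercised; the full chain runs
in about a minute on one core.

## Known limitations

- The trough-anchored linear baseline under-corrects backgrounds that
  curve sharply *within* a single inter-trough segment; `baseline_order=2`
  helps but can dip below the signal between anchors.
- Peaks closer than one half-window M (≈ 27 cm⁻¹ at the default grid)
  cannot both survive the local-maximum gate; the taller wins. This is
  by design (it is what keeps the record small) but bounds recall when
  true bands overlap.
- The noise-level gate uses the *mean* of the quietest window; after
  clipping, noise maxima exceed this mean, so the curvature gate — not
  the noise gate — is what actually rejects most noise bumps.
- Curvature is computed on the channel grid; comparing λ across grids
  of very different channel densities requires rescaling.
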