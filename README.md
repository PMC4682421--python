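# rdisc

Quality control and discretization of single-cell Raman spectra, with
discrete-spectrum similarity scoring and phenotype classification.

A single-cell Raman spectrum is a molecular fingerprint of one cell:
more than 1,000 intensity readings over a grid of Raman shifts
(wavenumber differences, cm⁻¹), reflecting its nucleic acids, proteins,
carbohydrates and lipids. The raw signal is buried under an intense,
slowly-varying autofluorescence background and instrument noise, and its
continuous form is bulky to store, slow to compare, and opaque to
interpret — no individual channel is a named feature.

`rdisc` condenses such a spectrum into a short record of
**representative peaks** — typically 8–15, always far fewer than 20 —
each stored as (position, intensity, curvature). The discrete record
needs under 1% of the full spectrum's storage, supports fast
peak-set similarity scoring, and classifies cells by species as
accurately as the full spectrum. Intended users are microbiologists
and spectroscopists doing single-cell phenotyping: species
identification, cell sorting, biomarker band discovery.

## Method

**Quality control** (three steps, in order):

1. *Wavelet denoising* — discrete wavelet transform (Daubechies-4,
   3 levels), soft thresholding of detail coefficients at the universal
   threshold `σ̂·√(2 ln n)`, with `σ̂ = MAD/0.6745` estimated from the
   finest detail band.
2. *Baseline correction* — spectrum troughs (strict minima of a ±25
   channel window, endpoints forced) anchor a piecewise linear baseline,
   which is subtracted; negative residuals are clipped to 0.
3. *Normalization* — min-max scaling `yᵢ ← (yᵢ − min Y)/(max Y − min Y)`.

**Discretization.** Channel *i* of the quality-controlled spectrum is a
representative peak iff all three gates hold:

    pᵢ > max(pᵢ₋M, …, pᵢ₊M)      — strict local maximum over ±M (M = 20)
    κ(i) > λ                      — curvature |f″|/(1+f′²)^{3/2} above threshold
    pᵢ > noise                    — above the mean of the quietest window

where *noise* is the mean intensity of the minimum-mean window among the
below-median-variance windows of width M.

**Similarity** of two discrete spectra, with peaks matched one-to-one
when their positions differ by at most δ = 10 cm⁻¹:

- `s1 = |matched| / |union|` — position Jaccard,
- `s2` — Pearson correlation of matched peak intensities (0 if < 2
  matches),
- `s = √s1 · s2` — the combined score used for k-NN.

**Classification.** k-NN (default k = 1; Pearson correlation on full
spectra, combined score on discrete spectra) and multi-class Fisher LDA
(ridge-regularized pooled covariance; discrete spectra are vectorized
over a peak vocabulary merged from the training set), evaluated by
stratified 60/40 train/test splits repeated 10 times.

Because public single-cell Raman collections are not bundled, the
package ships a simulator (`rdisc.simulate`) generating labeled spectra
from class templates — shared and class-unique Lorentzian marker bands
on a broad fluorescence background with additive noise — with exact
ground truth for every spectrum.

## Worked example

```python
from rdisc import (default_templates, simulate_dataset, qc_pipeline,
                   discretize, LabeledDataset, evaluate)

templates = default_templates(5, seed=42)            # 5 synthetic species
items, truths = simulate_dataset(templates, per_class=40, seed=42)

spectrum, label = items[0]                            # 2,048 channels
peaks = discretize(qc_pipeline(spectrum))
print(len(peaks), "peaks from", peaks.n_source_shifts, "channels")
for p in peaks.peaks[:3]:
    print(f"{p.position:7.1f} cm-1  intensity {p.intensity:.3f}  curvature {p.curvature:.4f}")
```

prints

```
8 peaks from 2048 channels
  743.3 cm-1  intensity 0.472  curvature 0.0275
  835.0 cm-1  intensity 0.427  curvature 0.0093
 1261.7 cm-1  intensity 1.000  curvature 0.0365
```

— the cell's spectrum reduced to its 8 marker bands; intensities are on
the normalized [0, 1] scale and the curvature column records each
band's sharpness. Evaluating classifiers on the whole 200-cell dataset:

```python
disc = LabeledDataset([(discretize(qc_pipeline(s)), lab) for s, lab in items],
                      "discrete")
report = evaluate(disc, method="knn", split=0.6, repeats=10, seed=42)
print(report.mean_accuracy)                           # 1.0
```

Discrete k-NN, discrete LDA, full-spectrum k-NN and full-spectrum LDA
all reach mean accuracy 1.000 on these well-separated synthetic classes
— the discrete record loses nothing for classification at 1/200th the
size.

The same operations are available from the shell:

```
rdisc simulate --classes 5 --per-class 40 --seed 42 --out data/
rdisc peaks data/class_0/class_0_0.txt cell0.rdisc
rdisc sim cell0.rdisc cell0.rdisc          # prints 1.0
rdisc classify --dataset data/ --method knn --representation discrete
```

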