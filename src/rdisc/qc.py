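"""Quality control of raw single-cell Raman spectra.

The chain has three steps, applied in this order:

1. **Wavelet denoising** — the spectrum is decomposed with a discrete
   wavelet transform (default: Daubechies-4, 3 levels, symmetric
   extension) and the detail coefficients of selected levels are
   soft-thresholded with the universal threshold
   ``sigma_hat * sqrt(2 ln n)``, where ``sigma_hat`` is the
   median-absolute-deviation noise estimate from the finest detail band
   (MAD / 0.6745).

2. **Baseline correction** — autofluorescence produces a broad, intense,
   slowly-varying background under the Raman bands.  Spectrum troughs
   (strict minima of a sliding window) are detected and used as anchor
   points; each adjacent trough pair is joined by a low-order curve and
   the segments are concatenated into a piecewise baseline, which is
   subtracted.  Negative residuals are clipped to zero by default
   (physical intensities are non-negative).

3. **Normalization** — min-max scaling ``(y - min) / (max - min)`` so
   every quality-controlled spectrum lies in [0, 1] with min exactly 0
   and max exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .errors import ConfigError, DataError, DegenerateInputError, RdiscError, StageError
from .spectra_io import RamanSpectrum

__all__ = [
    "QCConfig",
    "Baseline",
    "denoise_wavelet",
    "detect_troughs",
    "estimate_baseline",
    "correct_baseline",
    "normalize",
    "qc_pipeline",
]


@dataclass
class QCConfig:
    """Parameters of the three-step QC chain.

    Attributes
    ----------
    wavelet_levels
        Decomposition depth of the discrete wavelet transform (>= 1).
    wavelet_family
        Name of an orthogonal compactly-supported wavelet (PyWavelets name).
    shrink_levels
        Detail levels to soft-threshold; level 1 is the finest.  Default
        ``None`` thresholds every detail level (classical universal-
        threshold shrinkage), which suppresses the mid-frequency noise
        that survives finest-level-only shrinkage.
    trough_window
        Half-width, in channels, of the strict-minimum window used for
        trough detection (>= 2).
    baseline_order
        Polynomial order of each baseline segment: 1 (linear, default)
        or 2 (quadratic).
    clip_negative
        Floor baseline-corrected intensities at zero.
    """

    wavelet_levels: int = 3
    wavelet_family: str = "db4"
    shrink_levels: frozenset[int] | None = None
    trough_window: int = 25
    baseline_order: int = 1
    clip_negative: bool = True

    def __post_init__(self) -> None:
        if self.wavelet_levels < 1:
            raise ConfigError("wavelet_levels must be >= 1")
        if self.trough_window < 2:
            raise ConfigError("trough_window must be >= 2")
        if self.baseline_order not in (1, 2):
            raise ConfigError("baseline_order must be 1 or 2")
        if self.shrink_levels is not None:
            self.shrink_levels = frozenset(self.shrink_levels)
            if any(l < 1 or l > self.wavelet_levels for l in self.shrink_levels):
                raise ConfigError("shrink_levels must lie in [1, wavelet_levels]")

    @property
    def effective_shrink_levels(self) -> frozenset[int]:
        if self.shrink_levels is None:
            return frozenset(range(1, self.wavelet_levels + 1))
        return self.shrink_levels


@dataclass
class Baseline:
    """A piecewise-fitted baseline on the same grid as its source spectrum."""

    values: np.ndarray
    trough_positions: list[int]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise DataError("non-finite baseline value")


def denoise_wavelet(s: RamanSpectrum, cfg: QCConfig | None = None) -> RamanSpectrum:
    """Soft-threshold wavelet shrinkage of the intensity trace.

    The noise scale is estimated from the finest detail band as
    ``MAD / 0.6745`` and the universal threshold ``sigma * sqrt(2 ln n)``
    is applied (soft) to the detail levels in ``cfg.shrink_levels``.
    The output is reconstructed on the same shift grid (symmetric
    boundary extension, truncated to the input length).
    """
    cfg = cfg or QCConfig()
    y = s.intensities
    n = len(y)
    if n < 2 ** cfg.wavelet_levels:
        raise ConfigError(
            f"spectrum of length {n} too short for {cfg.wavelet_levels} wavelet levels"
        )
    coeffs = pywt.wavedec(y, cfg.wavelet_family, level=cfg.wavelet_levels, mode="symmetric")
    # coeffs = [cA_L, cD_L, ..., cD_1]; coeffs[-1] is the finest detail band
    finest = coeffs[-1]
    sigma = np.median(np.abs(finest - np.median(finest))) / 0.6745
    threshold = sigma * np.sqrt(2.0 * np.log(n))
    if threshold > 0:
        for level in cfg.effective_shrink_levels:
            idx = len(coeffs) - level  # level 1 (finest) -> last entry
            coeffs[idx] = pywt.threshold(coeffs[idx], threshold, mode="soft")
    rec = pywt.waverec(coeffs, cfg.wavelet_family, mode="symmetric")[:n]
    return s.replace(rec, stage="denoised")


def detect_troughs(s: RamanSpectrum, trough_window: int = 25) -> list[int]:
    """Channels that are the strict minimum of their +/- ``trough_window`` window.

    The first and last channels are always included as anchor points so a
    piecewise baseline can cover the whole grid.  Windows are truncated at
    the boundaries.  Returned indices are strictly increasing.
    """
    if trough_window < 2:
        raise ConfigError("trough_window must be >= 2")
    y = s.intensities
    n = len(y)
    troughs = [0]
    for i in range(1, n - 1):
        lo = max(0, i - trough_window)
        hi = min(n, i + trough_window + 1)
        window = y[lo:hi]
        # strict minimum: y[i] smaller than every other value in the window
        if y[i] < np.min(np.delete(window, i - lo)):
            troughs.append(i)
    if troughs[-1] != n - 1:
        troughs.append(n - 1)
    return troughs


def _fit_segment(x: np.ndarray, y: np.ndarray, i0: int, i1: int, order: int) -> np.ndarray:
    """Baseline values on channels [i0, i1] from an order-``order`` fit.

    Order 1: the straight line through the two trough points (exact).
    Order 2: a quadratic through the two troughs and the minimum-intensity
    channel strictly between them (falls back to linear when the segment
    has no interior channel).
    """
    xs = x[i0 : i1 + 1]
    if order == 1 or i1 - i0 < 2:
        slope = (y[i1] - y[i0]) / (x[i1] - x[i0])
        return y[i0] + slope * (xs - x[i0])
    interior = np.argmin(y[i0 + 1 : i1]) + i0 + 1
    pts_x = np.array([x[i0], x[interior], x[i1]])
    pts_y = np.array([y[i0], y[interior], y[i1]])
    if len(np.unique(pts_x)) < 3:
        slope = (y[i1] - y[i0]) / (x[i1] - x[i0])
        return y[i0] + slope * (xs - x[i0])
    coef = np.polyfit(pts_x - x[i0], pts_y, 2)
    return np.polyval(coef, xs - x[i0])


def estimate_baseline(s: RamanSpectrum, troughs: list[int], cfg: QCConfig | None = None) -> Baseline:
    """Piecewise low-order baseline anchored at the trough channels.

    Each adjacent trough pair is fitted by an order-``cfg.baseline_order``
    curve; the segments are concatenated into one continuous baseline over
    the whole grid.  With the default linear order the baseline passes
    through every trough's intensity exactly.
    """
    cfg = cfg or QCConfig()
    if len(troughs) < 2:
        raise DataError(f"need >= 2 trough indices, got {len(troughs)}")
    troughs = sorted(troughs)
    x, y = s.shifts, s.intensities
    values = np.empty(len(s), dtype=float)
    for i0, i1 in zip(troughs, troughs[1:]):
        values[i0 : i1 + 1] = _fit_segment(x, y, i0, i1, cfg.baseline_order)
    # channels before the first / after the last trough (only when callers
    # pass custom troughs without the forced endpoints): extend flat
    values[: troughs[0]] = values[troughs[0]]
    values[troughs[-1] + 1 :] = values[troughs[-1]]
    return Baseline(values, list(troughs))


def correct_baseline(s: RamanSpectrum, b: Baseline, cfg: QCConfig | None = None) -> RamanSpectrum:
    """Subtract the baseline; floor at zero unless ``cfg.clip_negative`` is off."""
    cfg = cfg or QCConfig()
    if len(b.values) != len(s):
        raise DataError(f"baseline length {len(b.values)} != spectrum length {len(s)}")
    y = s.intensities - b.values
    if cfg.clip_negative:
        y = np.maximum(y, 0.0)
    return s.replace(y, stage="baseline-corrected")


def normalize(s: RamanSpectrum) -> RamanSpectrum:
    """Min-max normalization: ``(y - min(Y)) / (max(Y) - min(Y))``.

    The output has min exactly 0 and max exactly 1.  A constant spectrum
    (max == min) is degenerate and raises.
    """
    y = s.intensities
    lo, hi = np.min(y), np.max(y)
    # relative tolerance: spectra constant up to float roundoff (e.g. after
    # wavelet round trip of a flat trace) are degenerate too
    if hi - lo <= 1e-12 * max(1.0, abs(hi), abs(lo)):
        raise DegenerateInputError("constant spectrum: max(Y) == min(Y)")
    return s.replace((y - lo) / (hi - lo), stage="normalized")


def qc_pipeline(s: RamanSpectrum, cfg: QCConfig | None = None) -> RamanSpectrum:
    """Full QC chain: denoise -> troughs -> baseline -> subtract -> normalize.

    Errors raised by any stage are re-raised as :class:`StageError` with the
    stage name attached.  The output carries ``meta['stage'] == 'qc'``.
    """
    cfg = cfg or QCConfig()

    def run(stage: str, fn, *args):
        try:
            return fn(*args)
        except RdiscError as exc:
            raise StageError(stage, exc) from exc

    out = run("denoise", denoise_wavelet, s, cfg)
    troughs = run("detect_troughs", detect_troughs, out, cfg.trough_window)
    baseline = run("estimate_baseline", estimate_baseline, out, troughs, cfg)
    out = run("correct_baseline", correct_baseline, out, baseline, cfg)
    out = run("normalize", normalize, out)
    out.meta["stage"] = "qc"
    return out
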