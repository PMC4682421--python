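"""Synthetic single-cell Raman spectra with known ground truth.

Emulates a multi-species single-cell Raman collection: each class
(species) is defined by a template of Lorentzian marker bands — some
shared across classes (common biomolecule bands: phenylalanine ring
breathing near 1003 cm^-1, CH2 deformation near 1450 cm^-1, amide I
near 1660 cm^-1, CH stretch near 2935 cm^-1, ...) and at least three
unique to the class — superimposed on a broad, smooth autofluorescence
background (a sum of wide Gaussians) plus additive Gaussian detector
noise and per-cell variation (peak-position jitter, multiplicative
height scatter, global intensity scaling).

Every generated spectrum carries a :class:`GroundTruth` with the
realized (post-jitter) peak positions and heights, the baseline array
and the noise seed, so recovery rates of the downstream pipeline can be
scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError
from .spectra_io import RamanSpectrum

__all__ = [
    "ClassTemplate",
    "GroundTruth",
    "default_templates",
    "simulate_spectrum",
    "simulate_dataset",
    "GRID_MIN",
    "GRID_MAX",
]

GRID_MIN = 400.0  # cm^-1
GRID_MAX = 3200.0  # cm^-1

# Common biomolecule Raman bands (cm^-1) shared across class templates.
SHARED_BAND_POOL = [
    785.0,   # nucleic acid backbone
    1003.0,  # phenylalanine ring breathing
    1095.0,  # DNA PO2- stretch
    1260.0,  # amide III
    1340.0,  # CH deformation / adenine
    1450.0,  # CH2 scissoring
    1580.0,  # guanine/adenine ring
    1660.0,  # amide I
    2880.0,  # CH2 symmetric stretch
    2935.0,  # CH3 stretch
]


@dataclass
class ClassTemplate:
    """Ground-truth recipe for one class (species) of synthetic spectra.

    Heights are relative (the tallest marker is ~1); ``baseline_amp`` and
    ``noise_sigma`` are expressed on that same relative scale.
    """

    label: str
    marker_positions: list[float]
    marker_heights: list[float]
    marker_widths: list[float]  # FWHM, cm^-1
    baseline_amp: float = 1.5
    noise_sigma: float = 0.01
    jitter_sigma: float = 1.5  # cm^-1
    height_cv: float = 0.1

    def __post_init__(self) -> None:
        k = len(self.marker_positions)
        if not (len(self.marker_heights) == len(self.marker_widths) == k):
            raise ConfigError("marker position/height/width lists must have equal length")
        if any(not GRID_MIN <= p <= GRID_MAX for p in self.marker_positions):
            raise ConfigError("marker position outside the shift grid")
        if any(w <= 0 for w in self.marker_widths):
            raise ConfigError("marker widths must be > 0")
        if any(h <= 0 for h in self.marker_heights):
            raise ConfigError("marker heights must be > 0")
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be >= 0")


@dataclass
class GroundTruth:
    """Realized per-spectrum truth: what was actually planted."""

    label: str
    positions: np.ndarray  # post-jitter apex positions, cm^-1
    heights: np.ndarray  # post-variation heights, relative units
    widths: np.ndarray
    baseline: np.ndarray  # baseline values on the full grid
    seed: int  # noise realization seed

    def reconstruct_signal(self, shifts: np.ndarray) -> np.ndarray:
        """Noise-free signal (Lorentzians + baseline) on ``shifts``."""
        return _lorentzian_sum(shifts, self.positions, self.heights, self.widths) + self.baseline


def _lorentzian_sum(x: np.ndarray, pos: np.ndarray, height: np.ndarray, fwhm: np.ndarray) -> np.ndarray:
    hw = np.asarray(fwhm, float)[:, None] / 2.0
    num = hw**2
    return np.sum(
        np.asarray(height, float)[:, None] * num / ((x[None, :] - np.asarray(pos, float)[:, None]) ** 2 + num),
        axis=0,
    ) if len(pos) else np.zeros_like(x)


def default_templates(n_classes: int, seed: int = 0, **overrides) -> list[ClassTemplate]:
    """Reproducible class templates with shared and class-unique markers.

    Each class receives 8-14 Lorentzian markers: a subset of the common
    biomolecule band pool plus at least 3 class-unique bands placed at
    least 25 cm^-1 from every other class's markers.  FWHM is drawn from
    10-30 cm^-1, relative heights from 0.2-1.0.  ``overrides`` are passed
    through to every :class:`ClassTemplate` (e.g. ``noise_sigma=0``).
    """
    if n_classes < 1:
        raise ConfigError("n_classes must be >= 1")
    rng = np.random.default_rng(seed)
    taken: list[float] = []  # all marker positions assigned so far
    templates: list[ClassTemplate] = []
    margin = 100.0  # keep markers away from grid edges
    for c in range(n_classes):
        n_total = int(rng.integers(8, 15))
        n_unique = int(rng.integers(3, 6))
        n_shared = min(n_total - n_unique, len(SHARED_BAND_POOL))
        shared = sorted(rng.choice(SHARED_BAND_POOL, size=n_shared, replace=False))
        uniques: list[float] = []
        while len(uniques) < n_unique:
            cand = float(rng.uniform(GRID_MIN + margin, GRID_MAX - margin))
            others = taken + uniques + SHARED_BAND_POOL
            if all(abs(cand - p) >= 25.0 for p in others):
                uniques.append(cand)
        positions = sorted(list(shared) + uniques)
        heights = rng.uniform(0.2, 1.0, size=len(positions))
        heights[np.argmax(heights)] = 1.0  # anchor the relative scale
        widths = rng.uniform(10.0, 30.0, size=len(positions))
        taken.extend(positions)
        templates.append(
            ClassTemplate(
                label=f"class_{c}",
                marker_positions=[float(p) for p in positions],
                marker_heights=[float(h) for h in heights],
                marker_widths=[float(w) for w in widths],
                **overrides,
            )
        )
    return templates


def simulate_spectrum(
    t: ClassTemplate, n_shifts: int = 2048, seed: int = 0
) -> tuple[RamanSpectrum, GroundTruth]:
    """One synthetic cell spectrum from a class template.

    intensity = sum of jittered Lorentzian markers
              + broad smooth fluorescence baseline (2-3 Gaussians,
                width >= 500 cm^-1, amplitude ``baseline_amp``)
              + N(0, noise_sigma) detector noise,
    floored at 0 (physical non-negativity), then globally scaled by a
    per-cell factor (instrument/exposure variation).
    """
    if n_shifts < 256:
        raise ConfigError("n_shifts must be >= 256")
    rng = np.random.default_rng(seed)
    x = np.linspace(GRID_MIN, GRID_MAX, n_shifts)
    pos = np.asarray(t.marker_positions) + rng.normal(0.0, t.jitter_sigma, len(t.marker_positions))
    heights = np.asarray(t.marker_heights) * np.maximum(
        1.0 + rng.normal(0.0, t.height_cv, len(t.marker_heights)), 0.05
    )
    widths = np.asarray(t.marker_widths, float)
    signal = _lorentzian_sum(x, pos, heights, widths)

    n_bg = int(rng.integers(2, 4))
    centers = rng.uniform(GRID_MIN, GRID_MAX, n_bg)
    bg_widths = rng.uniform(500.0, 1200.0, n_bg)
    bg_amps = t.baseline_amp * rng.uniform(0.3, 1.0, n_bg)
    baseline = np.sum(
        bg_amps[:, None] * np.exp(-0.5 * ((x[None, :] - centers[:, None]) / bg_widths[:, None]) ** 2),
        axis=0,
    )

    noise = rng.normal(0.0, t.noise_sigma, n_shifts) if t.noise_sigma > 0 else 0.0
    scale = float(np.exp(rng.normal(0.0, 0.1)))  # per-cell intensity scaling
    y = np.maximum(signal + baseline + noise, 0.0) * scale
    spec = RamanSpectrum(x, y, {"label": t.label, "seed": str(seed), "stage": "raw"})
    truth = GroundTruth(t.label, pos, heights * scale, widths, baseline * scale, seed)
    return spec, truth


def simulate_dataset(
    templates: list[ClassTemplate],
    per_class: int = 40,
    n_shifts: int = 2048,
    seed: int = 0,
) -> tuple[list[tuple[RamanSpectrum, str]], list[GroundTruth]]:
    """``per_class`` labeled spectra per template, reproducible from ``seed``.

    Per-spectrum seeds are spawned deterministically from the master seed.
    Returns (labeled spectra, ground truths) in matching order.
    """
    if per_class < 2:
        raise ConfigError("per_class must be >= 2")
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(len(templates) * per_class) % (2**31)
    items: list[tuple[RamanSpectrum, str]] = []
    truths: list[GroundTruth] = []
    k = 0
    for t in templates:
        for _ in range(per_class):
            spec, truth = simulate_spectrum(t, n_shifts, int(child_seeds[k]))
            spec.meta["cell_id"] = f"{t.label}_{k}"
            items.append((spec, t.label))
            truths.append(truth)
            k += 1
    return items, truths
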