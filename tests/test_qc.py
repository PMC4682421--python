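"""Tests of the QC chain: denoising, baseline correction, normalization."""

import numpy as np
import pytest

from rdisc import (
    Baseline,
    ConfigError,
    DataError,
    DegenerateInputError,
    QCConfig,
    RamanSpectrum,
    StageError,
    correct_baseline,
    denoise_wavelet,
    detect_troughs,
    estimate_baseline,
    normalize,
    qc_pipeline,
    simulate_spectrum,
    default_templates,
)


def brute_troughs(y: np.ndarray, w: int) -> list[int]:
    """Exhaustive strict-window-minimum scan, endpoints forced."""
    n = len(y)
    out = [0]
    for i in range(1, n - 1):
        window = [y[j] for j in range(max(0, i - w), min(n, i + w + 1)) if j != i]
        if y[i] < min(window):
            out.append(i)
    if out[-1] != n - 1:
        out.append(n - 1)
    return out


class TestDenoise:
    def test_noiseless_smooth_nearly_unchanged(self, simple_spectrum):
        out = denoise_wavelet(simple_spectrum)
        rng_ = np.ptp(simple_spectrum.intensities)
        rmse = np.sqrt(np.mean((out.intensities - simple_spectrum.intensities) ** 2))
        assert rmse <= 0.01 * rng_

    def test_noise_variance_halved(self, simple_spectrum, rng):
        truth = simple_spectrum.intensities
        noisy = simple_spectrum.replace(truth + rng.normal(0, 0.05, len(truth)))
        out = denoise_wavelet(noisy)
        var_in = np.var(noisy.intensities - truth)
        var_out = np.var(out.intensities - truth)
        assert var_out <= 0.5 * var_in

    def test_constant_spectrum_unchanged(self):
        s = RamanSpectrum(np.arange(64.0), np.full(64, 3.7))
        out = denoise_wavelet(s)
        np.testing.assert_allclose(out.intensities, 3.7, atol=1e-10)

    def test_same_grid(self, simple_spectrum):
        out = denoise_wavelet(simple_spectrum)
        np.testing.assert_array_equal(out.shifts, simple_spectrum.shifts)

    def test_too_short_for_depth(self):
        s = RamanSpectrum(np.arange(6.0), np.arange(6.0))
        with pytest.raises(ConfigError):
            denoise_wavelet(s, QCConfig(wavelet_levels=3))

    def test_idempotent_within_tolerance(self, simple_spectrum, rng):
        noisy = simple_spectrum.replace(
            simple_spectrum.intensities + rng.normal(0, 0.05, len(simple_spectrum))
        )
        once = denoise_wavelet(noisy)
        twice = denoise_wavelet(once)
        change1 = np.sqrt(np.mean((once.intensities - noisy.intensities) ** 2))
        change2 = np.sqrt(np.mean((twice.intensities - once.intensities) ** 2))
        assert change2 < 0.1 * change1


class TestTroughs:
    def test_v_shape_single_interior_trough(self):
        y = np.concatenate([np.linspace(1, 0, 50), np.linspace(0, 1, 51)[1:]])
        s = RamanSpectrum(np.arange(100.0), y)
        assert detect_troughs(s, 10) == [0, 49, 99]

    def test_monotone_endpoints_only(self):
        s = RamanSpectrum(np.arange(50.0), np.linspace(0, 1, 50))
        assert detect_troughs(s, 5) == [0, 49]

    def test_two_valley_recovery(self):
        x = np.arange(200.0)
        y = 1.0 - np.exp(-0.5 * ((x - 60) / 10) ** 2) - np.exp(-0.5 * ((x - 150) / 8) ** 2)
        s = RamanSpectrum(x, y)
        got = detect_troughs(s, 25)
        assert 60 in got and 150 in got
        assert got == brute_troughs(y, 25)

    def test_matches_brute_force_on_random(self, rng):
        for _ in range(25):
            n = int(rng.integers(10, 512))
            w = int(rng.integers(2, 40))
            y = rng.normal(size=n)
            s = RamanSpectrum(np.arange(float(n)), y)
            assert detect_troughs(s, w) == brute_troughs(y, w)


class TestBaseline:
    def test_line_recovered_exactly(self):
        x = np.arange(100.0)
        y = 0.3 * x + 2.0
        s = RamanSpectrum(x, y)
        b = estimate_baseline(s, [0, 99])
        assert np.max(np.abs(b.values - y)) < 1e-9

    def test_ramp_under_peaks(self, rng):
        x = np.linspace(400, 3200, 1024)
        ramp = 0.001 * (x - 400) + 0.5
        peaks = np.exp(-0.5 * ((x - 1200) / 8) ** 2) + np.exp(-0.5 * ((x - 2400) / 8) ** 2)
        s = RamanSpectrum(x, ramp + peaks)
        troughs = detect_troughs(s, 25)
        b = estimate_baseline(s, troughs)
        off_peak = (np.abs(x - 1200) > 100) & (np.abs(x - 2400) > 100)
        rel = np.abs(b.values[off_peak] - ramp[off_peak]) / np.ptp(ramp)
        assert np.max(rel) < 0.02

    def test_flat_zero_spectrum(self):
        s = RamanSpectrum(np.arange(50.0), np.zeros(50))
        b = estimate_baseline(s, [0, 49])
        np.testing.assert_allclose(b.values, 0.0, atol=1e-12)

    def test_passes_through_troughs_linear(self, rng):
        y = rng.normal(size=300)
        s = RamanSpectrum(np.arange(300.0), y)
        troughs = detect_troughs(s, 20)
        b = estimate_baseline(s, troughs)
        for t in troughs:
            assert abs(b.values[t] - y[t]) < 1e-9

    def test_needs_two_troughs(self, simple_spectrum):
        with pytest.raises(DataError):
            estimate_baseline(simple_spectrum, [0])

    def test_quadratic_order_continuous(self, rng):
        y = np.abs(rng.normal(size=400)) + np.sin(np.arange(400) / 30)
        s = RamanSpectrum(np.arange(400.0), y)
        troughs = detect_troughs(s, 25)
        b = estimate_baseline(s, troughs, QCConfig(baseline_order=2))
        assert np.all(np.isfinite(b.values))
        # continuity: no jumps larger than the local data scale
        assert np.max(np.abs(np.diff(b.values))) < np.ptp(y)


class TestCorrectBaseline:
    def test_self_subtraction_zero(self, simple_spectrum):
        b = Baseline(simple_spectrum.intensities.copy(), [0, len(simple_spectrum) - 1])
        out = correct_baseline(simple_spectrum, b)
        np.testing.assert_allclose(out.intensities, 0.0, atol=1e-12)

    def test_peak_heights_recovered(self):
        x = np.linspace(400, 3200, 1024)
        ramp = 0.0005 * (x - 400)
        apex = [1200.0, 2400.0]
        heights = [1.0, 0.7]
        y = ramp + sum(
            h * np.exp(-0.5 * ((x - p) / 8) ** 2) for p, h in zip(apex, heights)
        )
        s = RamanSpectrum(x, y)
        b = estimate_baseline(s, detect_troughs(s, 25))
        out = correct_baseline(s, b)
        for p, h in zip(apex, heights):
            got = out.intensities[np.argmin(np.abs(x - p))]
            assert abs(got - h) / h < 0.05

    def test_clip_negative_off_keeps_negatives(self, rng):
        s = RamanSpectrum(np.arange(100.0), rng.normal(size=100))
        b = Baseline(np.full(100, 10.0), [0, 99])
        out = correct_baseline(s, b, QCConfig(clip_negative=False))
        assert np.any(out.intensities < 0)

    def test_never_increases_intensity(self, rng):
        s = RamanSpectrum(np.arange(100.0), np.abs(rng.normal(size=100)))
        b = Baseline(np.abs(rng.normal(size=100)), [0, 99])
        out = correct_baseline(s, b)
        assert np.all(out.intensities <= s.intensities + 1e-12)

    def test_grid_mismatch(self, simple_spectrum):
        with pytest.raises(DataError):
            correct_baseline(simple_spectrum, Baseline(np.zeros(5), [0, 4]))


class TestNormalize:
    def test_worked_example(self):
        s = RamanSpectrum([1.0, 2.0, 3.0], [2.0, 4.0, 6.0])
        out = normalize(s)
        np.testing.assert_allclose(out.intensities, [0.0, 0.5, 1.0])

    def test_already_normalized_unchanged(self, rng):
        y = rng.uniform(size=100)
        y[0], y[1] = 0.0, 1.0
        s = RamanSpectrum(np.arange(100.0), y)
        np.testing.assert_allclose(normalize(s).intensities, y)

    def test_constant_is_degenerate(self):
        s = RamanSpectrum(np.arange(10.0), np.full(10, 2.0))
        with pytest.raises(DegenerateInputError):
            normalize(s)

    def test_exact_bounds(self, rng):
        s = RamanSpectrum(np.arange(64.0), rng.normal(size=64))
        out = normalize(s)
        assert out.intensities.min() == 0.0
        assert out.intensities.max() == 1.0


class TestPipeline:
    def test_simulator_output_in_unit_interval(self):
        t = default_templates(1, seed=7)[0]
        s, truth = simulate_spectrum(t, 2048, seed=3)
        out = qc_pipeline(s)
        assert out.intensities.min() == 0.0
        assert out.intensities.max() == 1.0
        assert out.meta["stage"] == "qc"
        # off-peak region should be driven near zero
        off = np.ones(len(s), bool)
        for p in truth.positions:
            off &= np.abs(s.shifts - p) > 50
        assert np.median(out.intensities[off]) < 0.1

    def test_apex_rank_preserved_noiseless(self):
        x = np.linspace(400, 3200, 1024)
        apex = [800.0, 1500.0, 2500.0]
        heights = [0.4, 1.0, 0.7]
        y = sum(h * np.exp(-0.5 * ((x - p) / 10) ** 2) for p, h in zip(apex, heights))
        s = RamanSpectrum(x, y + 1e-6)
        out = qc_pipeline(s)
        got = [out.intensities[np.argmin(np.abs(x - p))] for p in apex]
        assert np.argsort(got).tolist() == np.argsort(heights).tolist()

    def test_degenerate_input_names_stage(self):
        s = RamanSpectrum(np.arange(64.0), np.full(64, 1.0))
        with pytest.raises(StageError) as exc:
            qc_pipeline(s)
        assert exc.value.stage == "normalize"
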