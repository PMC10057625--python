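"""Filter, upsampling, baseline-removal and peak-detection tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppglucose.preprocessing import (
    detect_peaks_troughs,
    extract_ac,
    extract_dc,
    preprocess,
    remove_baseline,
    upsample,
)


def butterworth_lowpass_gain(f, cutoff, order):
    """Analytic single-pass Butterworth low-pass magnitude."""
    return 1.0 / np.sqrt(1.0 + (f / cutoff) ** (2 * order))


def butterworth_bandpass_gain(f, lo, hi, order):
    """Analytic single-pass Butterworth band-pass magnitude.

    ``order`` is the overall band-pass order (2N poles with N = order/2
    low-pass prototype poles), via the standard low-pass -> band-pass
    transform x = (f^2 - lo*hi) / (f * (hi - lo)).
    """
    x = (f**2 - lo * hi) / (f * (hi - lo))
    return 1.0 / np.sqrt(1.0 + x ** (2 * order))


def measured_gain(filter_fn, freq, fs, n_periods=12):
    """Empirical amplitude ratio for a sinusoid at `freq` Hz."""
    duration = n_periods / freq
    t = np.arange(int(duration * fs)) / fs
    x = np.sin(2 * np.pi * freq * t)
    y = filter_fn(x, fs)
    # project the central half onto the probe quadrature pair
    sl = slice(len(t) // 4, 3 * len(t) // 4)
    basis = np.column_stack([np.sin(2 * np.pi * freq * t[sl]),
                             np.cos(2 * np.pi * freq * t[sl])])
    coef, *_ = np.linalg.lstsq(basis, y[sl], rcond=None)
    return float(np.hypot(*coef))


class TestExtractDc:
    def test_constant_passthrough(self):
        c = 7.3
        out = extract_dc(np.full(5000, c), 100.0)
        assert np.max(np.abs(out - c)) < 1e-6 * abs(c)

    # the 0.01 Hz filter settles over ~1000 s, so steady-state attenuation
    # is assessed on the central window of a long probe signal (the edge
    # transient of the reflect-padded zero-phase pass decays into the ends)
    def test_1hz_sinusoid_blocked(self):
        t = np.arange(240000) / 100.0
        out = extract_dc(np.sin(2 * np.pi * t), 100.0)
        # analytic single-pass attenuation at 100x cutoff exceeds 300 dB
        assert butterworth_lowpass_gain(1.0, 0.01, 10) < 1e-15
        n = len(out)
        assert np.max(np.abs(out[n // 2 - 5000 : n // 2 + 5000])) < 1e-6

    def test_superposition(self):
        t = np.arange(240000) / 100.0
        out = extract_dc(4.2 + np.sin(2 * np.pi * t), 100.0)
        n = len(out)
        assert np.max(np.abs(out[n // 2 - 5000 : n // 2 + 5000] - 4.2)) < 1e-5

    def test_rejects_short_signal(self):
        with pytest.raises(ValueError, match="too short"):
            extract_dc(np.ones(10), 100.0)


class TestExtractAc:
    def test_constant_blocked(self):
        out = extract_ac(np.full(4000, 5.0), 100.0)
        assert np.max(np.abs(out)) < 1e-6

    def test_1hz_passband(self):
        gain = measured_gain(extract_ac, 1.0, 100.0)
        # zero-phase double pass: amplitude ratio = |H|^2
        expected = butterworth_bandpass_gain(1.0, 0.3, 10.0, 8) ** 2
        assert gain == pytest.approx(expected, rel=0.02)
        assert gain == pytest.approx(1.0, abs=0.02)

    def test_001hz_stopband(self):
        gain = measured_gain(extract_ac, 0.01, 50.0, n_periods=6)
        assert gain < 0.01

    def test_rejects_low_rate(self):
        with pytest.raises(ValueError):
            extract_ac(np.ones(1000), 20.0)


class TestFilterOracle:
    """Empirical gains match the squared analytic Butterworth magnitude."""

    PROBES = (0.001, 0.01, 0.3, 1.0, 5.0, 10.0, 20.0)

    @pytest.mark.parametrize("freq", PROBES)
    def test_dc_filter(self, freq):
        expected = butterworth_lowpass_gain(freq, 0.01, 10) ** 2
        if expected <= 0.01:
            pytest.skip("gain below comparison floor")
        fs = max(4 * freq, 1.0)
        gain = measured_gain(extract_dc, freq, fs, n_periods=8)
        assert gain == pytest.approx(expected, rel=0.05)

    @pytest.mark.parametrize("freq", PROBES)
    def test_ac_filter(self, freq):
        expected = butterworth_bandpass_gain(freq, 0.3, 10.0, 8) ** 2
        if expected <= 0.01:
            pytest.skip("gain below comparison floor")
        gain = measured_gain(extract_ac, freq, 100.0, n_periods=15)
        assert gain == pytest.approx(expected, rel=0.05)


class TestUpsample:
    def test_midpoint(self):
        assert np.allclose(upsample(np.array([0.0, 2.0]), 2), [0.0, 1.0, 2.0])

    def test_identity(self):
        x = np.array([1.0, 5.0, 2.0])
        assert np.allclose(upsample(x, 1), x)

    def test_rejects_bad_factor(self):
        with pytest.raises(ValueError):
            upsample(np.arange(5.0), 0)

    @given(
        st.lists(st.floats(min_value=-100, max_value=100), min_size=2, max_size=40),
        st.integers(min_value=1, max_value=8),
    )
    @settings(max_examples=50, deadline=None)
    def test_sample_preservation(self, values, factor):
        x = np.asarray(values)
        y = upsample(x, factor)
        assert len(y) == (len(x) - 1) * factor + 1
        assert np.allclose(y[::factor], x)


class TestRemoveBaseline:
    def test_periodic_constant_minima(self):
        t = np.arange(4000) / 100.0
        x = 1.0 + np.abs(np.sin(2 * np.pi * 1.0 * t))
        corrected, envelope = remove_baseline(x, 100.0)
        interior = slice(200, -200)
        assert np.max(np.abs(envelope[interior] - 1.0)) < 1e-3
        assert np.min(corrected[interior]) > -1e-3

    def test_zero_at_knots(self):
        rng = np.random.default_rng(0)
        t = np.arange(3000) / 100.0
        x = np.abs(np.sin(2 * np.pi * t)) + 0.05 * rng.normal(size=len(t))
        corrected, envelope = remove_baseline(x, 100.0)
        knots = np.flatnonzero(corrected == 0.0)
        assert len(knots) >= 4  # every spline knot is an exact zero

    def test_linear_drift_removed(self):
        t = np.arange(6000) / 100.0
        base = np.abs(np.sin(2 * np.pi * 1.0 * t)) ** 3
        drift = 0.5 * t / t[-1]
        c0, _ = remove_baseline(base, 100.0)
        c1, _ = remove_baseline(base + drift, 100.0)
        interior = slice(400, -400)
        rms_diff = np.sqrt(np.mean((c0[interior] - c1[interior]) ** 2))
        rms = np.sqrt(np.mean(c0[interior] ** 2))
        assert rms_diff < 0.01 * rms + 1e-3

    def test_rejects_too_few_minima(self):
        with pytest.raises(ValueError, match="local minima"):
            remove_baseline(np.linspace(0, 1, 500), 100.0)


class TestDetectPeaksTroughs:
    def test_clean_train_count(self, clean_processed):
        # 120 s at 60 bpm: one peak per beat; up to 2 edge peaks are pruned
        # when the recording starts/ends mid-cycle (no genuine boundary
        # trough exists there)
        assert 118 <= len(clean_processed.peak_indices) <= 121

    def test_constant_signal_rejected(self):
        with pytest.raises(ValueError, match="no peaks"):
            detect_peaks_troughs(np.zeros(1000), 100.0)

    def test_alternation(self, clean_processed):
        peaks = clean_processed.peak_indices
        troughs = clean_processed.trough_indices
        merged = sorted(
            [(p, "p") for p in peaks] + [(t, "t") for t in troughs]
        )
        kinds = "".join(k for _, k in merged)
        assert "pp" not in kinds and "tt" not in kinds
        assert kinds.startswith("t") and kinds.endswith("t")


class TestPreprocessPipeline:
    def test_deterministic(self, clean_recording):
        a = preprocess(clean_recording)
        b = preprocess(clean_recording)
        assert np.array_equal(a.ac_series, b.ac_series)
        assert np.array_equal(a.peak_indices, b.peak_indices)

    def test_amplitude_equivariance(self, clean_recording):
        import copy

        a = preprocess(clean_recording)
        scaled = copy.copy(clean_recording)
        scaled.samples = clean_recording.samples * 3.0
        b = preprocess(scaled)
        assert np.array_equal(a.peak_indices, b.peak_indices)
        assert np.array_equal(a.trough_indices, b.trough_indices)
        assert np.allclose(b.ac_series, 3.0 * a.ac_series, atol=1e-8)
        assert np.allclose(b.dc_series, 3.0 * a.dc_series, rtol=1e-9)

    def test_upsampled_rate_and_dc(self, clean_processed, clean_recording):
        assert clean_processed.upsampled_rate == 4 * clean_recording.sampling_rate
        assert clean_processed.dc_value == pytest.approx(
            np.mean(clean_processed.dc_series)
        )

    def test_trough_values_near_zero(self, clean_processed):
        vals = clean_processed.ac_series[clean_processed.trough_indices]
        span = np.ptp(clean_processed.ac_series)
        assert np.all(vals < 0.05 * span)
        assert np.all(vals > -0.05 * span)
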