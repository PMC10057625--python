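"""Cycle segmentation, template QC and feature extraction tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppglucose.cycles import (
    FEATURE_NAMES,
    PpgCycle,
    build_template,
    extract_features,
    filter_cycles,
    middle_ten_indices,
    resample_cycle,
    segment_cycles,
    tkeo,
)


def make_cycle(samples, rate=100.0, dc=10.0, bgl=90.0):
    samples = np.asarray(samples, dtype=float)
    return PpgCycle(
        samples=samples,
        peak_offset=int(np.argmax(samples)),
        dc_value=dc,
        sampling_rate=rate,
        recording_ref="t",
        bgl_label=bgl,
    )


def triangle_cycle(rate=100.0, rise_s=0.5, fall_s=0.5, peak=1.0):
    """Symmetric triangle: troughs at 0, apex at `peak`."""
    up = np.linspace(0.0, peak, int(rise_s * rate) + 1)
    down = np.linspace(peak, 0.0, int(fall_s * rate) + 1)[1:]
    return make_cycle(np.concatenate([up, down]), rate=rate)


class TestTkeo:
    def test_constant_is_zero(self):
        assert np.allclose(tkeo([3.0, 3.0, 3.0, 3.0]), [0.0, 0.0])

    def test_ramp_is_one(self):
        n = np.arange(20.0)
        assert np.allclose(tkeo(n), 1.0)

    def test_sinusoid_closed_form(self):
        omega = 0.2
        x = np.sin(omega * np.arange(200))
        e = tkeo(x)
        assert np.max(np.abs(e - np.sin(omega) ** 2)) < 1e-9

    def test_output_length(self):
        assert len(tkeo(np.arange(10.0))) == 8

    def test_rejects_short(self):
        with pytest.raises(ValueError):
            tkeo([1.0, 2.0])

    @given(st.floats(min_value=0.01, max_value=2.0),
           st.floats(min_value=0.01, max_value=3.0))
    @settings(max_examples=30, deadline=None)
    def test_sinusoid_amplitude_scaling(self, amp, omega):
        x = amp * np.sin(omega * np.arange(100))
        e = tkeo(x)
        assert np.max(np.abs(e - amp**2 * np.sin(omega) ** 2)) < 1e-7


class TestMiddleTen:
    def test_n30_is_10_to_19(self):
        assert list(middle_ten_indices(30)) == list(range(10, 20))

    def test_fewer_than_ten_uses_all(self):
        assert list(middle_ten_indices(5)) == [0, 1, 2, 3, 4]

    @pytest.mark.parametrize("n", [10, 11, 17, 24, 30, 101, 144])
    def test_matches_closest_to_center_oracle(self, n):
        # brute force: the ten indices closest to the center (n-1)/2,
        # ties broken toward the lower index
        center = (n - 1) / 2.0
        order = sorted(range(n), key=lambda i: (abs(i - center), i))
        expected = sorted(order[:10])
        assert list(middle_ten_indices(n)) == expected


class TestBuildTemplate:
    def test_identical_cycles(self):
        base = triangle_cycle()
        cycles = [make_cycle(base.samples) for _ in range(20)]
        template = build_template(cycles, length=100)
        assert template.n_source_cycles == 10
        expected = resample_cycle(base.samples, 100)
        assert np.max(np.abs(template.waveform - expected)) < 1e-9

    def test_fallback_below_ten(self):
        cycles = [triangle_cycle() for _ in range(5)]
        with pytest.warns(UserWarning):
            template = build_template(cycles)
        assert template.n_source_cycles == 5

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            build_template([])


class TestFilterCycles:
    def test_identical_cycles_all_pass(self):
        cycles = [triangle_cycle() for _ in range(12)]
        template = build_template(cycles)
        valid, rejected, r = filter_cycles(cycles, template)
        assert len(valid) == 12 and len(rejected) == 0
        assert np.allclose(r, 1.0)

    def test_noise_cycle_rejected(self):
        rng = np.random.default_rng(0)
        cycles = [triangle_cycle() for _ in range(12)]
        noise_samples = np.abs(rng.normal(0, 1, 101))
        noise_samples[50] = noise_samples.max() + 1.0
        noise = make_cycle(noise_samples, rate=100.0)
        cycles.append(noise)
        template = build_template(cycles[:12])
        valid, rejected, r = filter_cycles(cycles, template)
        assert noise in rejected
        assert abs(r[-1]) < 0.5

    def test_zero_variance_cycle_gets_r_zero(self):
        flat = PpgCycle(
            samples=np.full(50, 2.0), peak_offset=25, dc_value=10.0,
            sampling_rate=100.0,
        )
        cycles = [triangle_cycle() for _ in range(10)] + [flat]
        template = build_template(cycles[:10])
        valid, rejected, r = filter_cycles(cycles, template)
        assert r[-1] == 0.0
        assert flat in rejected

    def test_agrees_with_bruteforce_pearson(self):
        rng = np.random.default_rng(1)
        base = triangle_cycle().samples
        cycles = [
            make_cycle(base + rng.normal(0, 0.2, len(base))) for _ in range(100)
        ]
        template = build_template(cycles)
        _, _, r = filter_cycles(cycles, template)
        for cyc, r_impl in zip(cycles, r):
            a = resample_cycle(cyc.samples, len(template.waveform))
            b = template.waveform
            am, bm = a - a.mean(), b - b.mean()
            r_brute = float(np.sum(am * bm) / np.sqrt(np.sum(am**2) * np.sum(bm**2)))
            assert r_impl == pytest.approx(r_brute, abs=1e-12)


class TestExtractFeatures:
    def test_feature_count_is_18(self):
        fv = extract_features(triangle_cycle())
        assert len(FEATURE_NAMES) == 18
        assert len(fv.as_array()) == 18
        assert np.all(np.isfinite(fv.as_array()))

    def test_triangle_geometry(self):
        fv = extract_features(triangle_cycle())
        assert fv.delta_ac == pytest.approx(1.0)
        assert fv.rise_time == pytest.approx(0.5)
        assert fv.fall_time == pytest.approx(0.5)
        assert fv.rise_slope == pytest.approx(2.0)
        assert fv.fall_slope == pytest.approx(-2.0)
        assert fv.base_width == pytest.approx(1.0)
        assert fv.width_quarter == pytest.approx(0.75)
        assert fv.width_three_quarter == pytest.approx(0.25)
        assert fv.area == pytest.approx(0.5)

    def test_optical_density_closed_forms(self):
        # delta_ac == dc_value -> log10(2)
        cyc = triangle_cycle()
        cyc.dc_value = 1.0
        fv = extract_features(cyc)
        assert fv.optical_density == pytest.approx(np.log10(2.0))

    def test_base_width_identity_and_tkeo_std(self):
        rng = np.random.default_rng(2)
        samples = np.concatenate([[0.0], np.abs(rng.normal(1, 0.2, 60)), [0.0]])
        samples[30] = 3.0  # definite interior peak
        fv = extract_features(make_cycle(samples))
        assert fv.base_width == pytest.approx(fv.rise_time + fv.fall_time)
        assert fv.tkeo_std**2 == pytest.approx(fv.tkeo_variance)

    def test_tkeo_kurtosis_is_raw_convention(self):
        # large near-normal TKEO sample: raw kurtosis near 3, not 0
        rng = np.random.default_rng(3)
        samples = np.cumsum(rng.normal(0, 1, 5000))
        samples[2500] = samples.max() + 10
        fv = extract_features(make_cycle(samples, rate=1000.0))
        assert fv.tkeo_kurtosis > 1.0

    def test_rejects_nonpositive_dc(self):
        cyc = triangle_cycle()
        cyc.dc_value = 0.0
        with pytest.raises(ValueError):
            extract_features(cyc)

    @given(st.floats(min_value=0.1, max_value=50.0))
    @settings(max_examples=25, deadline=None)
    def test_amplitude_scaling(self, alpha):
        base = triangle_cycle()
        scaled = make_cycle(base.samples * alpha)
        f0 = extract_features(base)
        f1 = extract_features(scaled)
        for name in ("delta_ac", "peak_value", "fall_level", "rise_slope",
                     "fall_slope", "area"):
            assert getattr(f1, name) == pytest.approx(
                alpha * getattr(f0, name), rel=1e-9
            )
        for name in ("rise_time", "fall_time", "width_quarter",
                     "width_three_quarter", "base_width"):
            assert getattr(f1, name) == pytest.approx(getattr(f0, name), rel=1e-9)


class TestSegmentCycles:
    def test_clean_recording_counts(self, clean_processed):
        cycles = segment_cycles(clean_processed)
        assert 118 <= len(cycles) <= 120  # 120 beats, edge peaks may drop

    def test_shared_troughs(self, clean_processed):
        cycles = segment_cycles(clean_processed)
        for a, b in zip(cycles[:-1], cycles[1:]):
            assert a.samples[-1] == pytest.approx(b.samples[0])

    def test_cycle_invariants(self, clean_processed):
        for cyc in segment_cycles(clean_processed):
            assert cyc.duration > 0
            assert 0 < cyc.peak_offset < len(cyc.samples) - 1
            assert cyc.peak_value >= max(cyc.left_trough_value, cyc.right_trough_value)

    def test_clean_cycles_mutually_correlated(self, clean_processed):
        cycles = segment_cycles(clean_processed)
        ref = resample_cycle(cycles[5].samples, 100)
        for cyc in cycles[1:-1]:
            r = np.corrcoef(resample_cycle(cyc.samples, 100), ref)[0, 1]
            assert r > 0.99
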