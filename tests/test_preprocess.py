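import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grfcast.preprocess import (FilterSpec, butterworth_gain, clip_negative,
                                downsample, lowpass, make_windows,
                                normalize_bw, preprocess_trial)
from .conftest import make_trace


class TestDownsample:
    def test_frame_count_2000_to_500(self):
        trace = make_trace(np.random.default_rng(0).random(10000), rate=2000.0)
        out = downsample(trace, 500.0)
        assert len(out) == 2500
        assert out.rate == 500.0

    def test_constant_preserved(self):
        trace = make_trace(np.full(4000, 3.7), rate=2000.0)
        out = downsample(trace, 500.0)
        np.testing.assert_allclose(out.samples, 3.7, atol=1e-9)

    def test_sine_amplitude(self):
        # oracle: analytically resampled 10 Hz unit sine
        t = np.arange(8000) / 2000.0
        trace = make_trace(np.sin(2 * np.pi * 10 * t), rate=2000.0)
        out = downsample(trace, 500.0)
        expected = np.sin(2 * np.pi * 10 * np.arange(2000) / 500.0)
        core = slice(50, -50)  # edges excluded
        assert np.abs(out.samples[core] - expected[core]).max() < 0.01

    def test_non_integer_ratio_rejected(self):
        trace = make_trace(np.zeros(100), rate=2000.0)
        with pytest.raises(ValueError, match="2000.*600|600.*2000"):
            downsample(trace, 600.0)

    @given(n=st.integers(min_value=4, max_value=500))
    @settings(max_examples=30, deadline=None)
    def test_output_length_ceil(self, n):
        trace = make_trace(np.ones(n), rate=2000.0)
        assert len(downsample(trace, 500.0)) == int(np.ceil(n / 4))


class TestLowpass:
    def test_dc_gain_unity(self):
        trace = make_trace(np.full(1000, 3.0), rate=500.0)
        out = lowpass(trace, FilterSpec(20.0))
        np.testing.assert_allclose(out.samples, 3.0, atol=1e-9)

    def test_stopband_attenuation(self):
        # oracle: analytic |H|^2 of the zero-phase 4th-order design at 100 Hz
        t = np.arange(5000) / 500.0
        trace = make_trace(np.sin(2 * np.pi * 100 * t), rate=500.0)
        out = lowpass(trace, FilterSpec(20.0))
        gain = butterworth_gain(FilterSpec(20.0), 500.0, 100.0)
        rms_ratio = np.std(out.samples[500:-500]) / np.std(trace.samples)
        assert rms_ratio < 0.05
        assert rms_ratio == pytest.approx(gain, abs=5e-3)

    def test_passband_preserved(self):
        t = np.arange(5000) / 500.0
        trace = make_trace(np.sin(2 * np.pi * 5 * t), rate=500.0)
        out = lowpass(trace, FilterSpec(20.0))
        rms_ratio = np.std(out.samples[500:-500]) / np.std(trace.samples[500:-500])
        assert rms_ratio == pytest.approx(1.0, abs=0.02)

    def test_cutoff_above_nyquist_rejected(self):
        trace = make_trace(np.zeros(100), rate=500.0)
        with pytest.raises(ValueError, match="Nyquist"):
            lowpass(trace, FilterSpec(300.0))

    def test_length_and_rate_preserved(self):
        trace = make_trace(np.random.default_rng(1).random(777), rate=500.0)
        out = lowpass(trace, FilterSpec(20.0))
        assert len(out) == 777 and out.rate == 500.0


class TestNormalizeBW:
    def test_981N_100kg(self):
        trace = make_trace([981.0], rate=500.0, units="N")
        assert normalize_bw(trace, 100.0).samples[0] == pytest.approx(1.0)

    def test_zero(self):
        trace = make_trace([0.0, 0.0], rate=500.0, units="N")
        np.testing.assert_array_equal(normalize_bw(trace, 70.0).samples, 0.0)

    def test_cohort_mean_mass(self):
        trace = make_trace([1668.0], rate=500.0, units="N")
        out = normalize_bw(trace, 68.1)
        assert out.samples[0] == pytest.approx(1668.0 / (68.1 * 9.81))
        assert out.samples[0] == pytest.approx(2.497, abs=5e-4)
        assert out.units == "BW"

    def test_nonpositive_mass(self):
        trace = make_trace([1.0], units="N")
        with pytest.raises(ValueError):
            normalize_bw(trace, 0.0)


class TestClipNegative:
    def test_basic(self):
        trace = make_trace([-1.2, 0.0, 3.4], axis="acc_vertical", units="m/s2")
        np.testing.assert_array_equal(clip_negative(trace).samples,
                                      [0.0, 0.0, 3.4])

    def test_positive_unchanged(self):
        trace = make_trace([0.1, 2.0], axis="acc_vertical", units="m/s2")
        np.testing.assert_array_equal(clip_negative(trace).samples, [0.1, 2.0])

    def test_idempotent(self, rng):
        trace = make_trace(rng.standard_normal(100), axis="acc_vertical",
                           units="m/s2")
        once = clip_negative(trace)
        twice = clip_negative(once)
        np.testing.assert_array_equal(once.samples, twice.samples)

    def test_aerial_phase_clips_to_zero(self, noiseless_trial):
        # generator oracle: aerial vertical acceleration is -g*cos(slope) < 0
        grf = noiseless_trial.grf.samples
        aerial = grf == 0.0
        acc = noiseless_trial.acc_v.samples
        assert np.all(acc[aerial] < 0)
        clipped = clip_negative(noiseless_trial.acc_v)
        assert np.all(clipped.samples[aerial] == 0.0)


class TestWindows:
    def test_count_equals_frames(self):
        v = make_trace(np.arange(2500.0), axis="acc_vertical", units="m/s2")
        ap = make_trace(np.arange(2500.0), axis="acc_anteroposterior",
                        units="m/s2")
        w = make_windows(v, ap)
        assert w.n_windows == 2500
        assert w.windows.shape == (2500, 6, 2)

    def test_first_window_padding(self):
        x = np.array([10.0, 11.0, 12.0, 13.0, 14.0])
        v = make_trace(x, axis="acc_vertical", units="m/s2")
        ap = make_trace(x, axis="acc_anteroposterior", units="m/s2")
        w = make_windows(v, ap)
        np.testing.assert_array_equal(w.windows[0, :, 0],
                                      [10, 10, 10, 10, 11, 12])

    def test_last_window_padding(self):
        x = np.array([10.0, 11.0, 12.0, 13.0, 14.0])
        v = make_trace(x, axis="acc_vertical", units="m/s2")
        ap = make_trace(x, axis="acc_anteroposterior", units="m/s2")
        w = make_windows(v, ap)
        np.testing.assert_array_equal(w.windows[4, :, 0],
                                      [11, 12, 13, 14, 14, 14])

    def test_window_centering(self):
        x = np.arange(20.0)
        v = make_trace(x, axis="acc_vertical", units="m/s2")
        ap = make_trace(x, axis="acc_anteroposterior", units="m/s2")
        w = make_windows(v, ap)
        # window t spans source frames t-3 .. t+2
        np.testing.assert_array_equal(w.windows[10, :, 0], x[7:13])

    @given(n=st.integers(min_value=1, max_value=300))
    @settings(max_examples=30, deadline=None)
    def test_count_property(self, n):
        x = np.random.default_rng(n).random(n)
        v = make_trace(x, axis="acc_vertical", units="m/s2")
        ap = make_trace(x, axis="acc_anteroposterior", units="m/s2")
        assert make_windows(v, ap).n_windows == n


class TestPipeline:
    def test_commutation_property(self):
        # downsample->lowpass ~ lowpass at target rate for band-limited input
        t = np.arange(10000) / 2000.0
        sig = np.sin(2 * np.pi * 3 * t) + 0.5 * np.sin(2 * np.pi * 11 * t)
        trace = make_trace(sig, rate=2000.0, axis="acc_vertical", units="m/s2")
        a = lowpass(downsample(trace, 500.0), FilterSpec(20.0))
        b = downsample(lowpass(trace, FilterSpec(20.0)), 500.0)
        core = slice(100, -100)  # edge transients excluded
        rms = np.sqrt(np.mean((a.samples[core] - b.samples[core]) ** 2))
        assert rms < 1e-2

    def test_preprocess_trial_shapes(self, noiseless_trial):
        prepped, windows = preprocess_trial(noiseless_trial)
        assert prepped.n_frames == 2500
        assert prepped.grf.rate == 500.0
        assert windows.n_windows == 2500
        assert np.all(prepped.acc_v.samples >= 0)  # clipped
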