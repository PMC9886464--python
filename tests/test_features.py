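import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pcgkit._core import DegenerateInputError, ValidationError
from pcgkit.features import (FEATURE_NAMES, FeatureVector, extract_features, mel,
                             mfcc_features, spectral_quality_features,
                             time_domain_features)
from pcgkit.io import Signal, zscore_normalize
from pcgkit.synth import synth_recording


def make_signal(x, rate=8000.0):
    return Signal(np.asarray(x, dtype=float), rate)


class TestTimeDomain:
    def test_sine_closed_forms(self):
        # 1 Hz over a full second: dense sampling makes the Riemann sums tight
        t = np.arange(8000) / 8000.0
        td = time_domain_features(make_signal(np.sin(2 * np.pi * t)))
        assert td["crest_factor"] == pytest.approx(np.sqrt(2), rel=1e-6)
        assert td["shape_factor"] == pytest.approx(np.pi / (2 * np.sqrt(2)), rel=1e-6)
        assert td["mean"] == pytest.approx(0.0, abs=1e-9)
        assert td["skewness"] == pytest.approx(0.0, abs=1e-9)

    def test_square_wave_hand_values(self):
        td = time_domain_features(make_signal([1.0, -1.0, 1.0, -1.0]))
        assert td["rms"] == pytest.approx(1.0)
        assert td["peak"] == pytest.approx(1.0)
        assert td["crest_factor"] == pytest.approx(1.0)
        assert td["kurtosis"] == pytest.approx(1.0)

    def test_gaussian_moments_monte_carlo(self, rng):
        td = time_domain_features(make_signal(rng.standard_normal(1_000_000)))
        assert td["kurtosis"] == pytest.approx(3.0, abs=0.05)
        assert td["skewness"] == pytest.approx(0.0, abs=0.05)

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateInputError):
            time_domain_features(make_signal(np.zeros(100)))
        with pytest.raises(DegenerateInputError):
            time_domain_features(make_signal(np.full(100, 2.5)))

    def test_ratio_identity_crest_equals_impulse_over_shape(self, rng):
        for _ in range(20):
            td = time_domain_features(make_signal(rng.standard_normal(256)))
            assert td["crest_factor"] == pytest.approx(
                td["impulse_factor"] / td["shape_factor"], rel=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(gain=st.floats(0.01, 100.0))
    def test_gain_scaling_and_invariance(self, gain):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(512)
        base = time_domain_features(make_signal(x))
        scaled = time_domain_features(make_signal(gain * x))
        for name in ("rms", "peak", "std", "mean"):
            assert scaled[name] == pytest.approx(gain * base[name], rel=1e-9)
        for name in ("shape_factor", "crest_factor", "impulse_factor",
                     "clearance_factor", "skewness", "kurtosis"):
            assert scaled[name] == pytest.approx(base[name], rel=1e-9)


class TestSpectralQuality:
    def test_pure_sine_has_no_harmonic_energy(self, sine_100hz):
        m = spectral_quality_features(sine_100hz)
        assert m["thd_db"] < -60

    def test_snr_of_constructed_noise_mixture(self, rng, sine_100hz):
        s = sine_100hz.samples
        p_signal = np.mean(s**2)
        noise = rng.standard_normal(s.size)
        noise *= np.sqrt(p_signal / 100.0 / np.mean(noise**2))  # 20 dB below
        m = spectral_quality_features(make_signal(s + noise))
        assert m["snr_db"] == pytest.approx(20.0, abs=1.0)

    def test_thd_of_two_tone_construction(self):
        t = np.arange(8000) / 8000.0
        x = np.sin(2 * np.pi * 100 * t) + 0.1 * np.sin(2 * np.pi * 200 * t)
        m = spectral_quality_features(make_signal(x))
        assert m["thd_db"] == pytest.approx(-20.0, abs=0.5)

    def test_sinad_combines_noise_and_distortion(self, sine_100hz):
        m = spectral_quality_features(sine_100hz)
        assert m["sinad_db"] <= m["snr_db"] + 1e-9

    def test_short_or_flat_input_rejected(self):
        with pytest.raises(ValidationError):
            spectral_quality_features(make_signal(np.ones(32)))
        with pytest.raises(DegenerateInputError):
            spectral_quality_features(make_signal(np.zeros(128)))


class TestMFCC:
    def test_mel_scale_values(self):
        assert mel(0) == 0.0
        assert mel(700) == pytest.approx(2595 * np.log10(2))

    def test_gain_shifts_only_zeroth_coefficient(self, rng):
        x = rng.standard_normal(4000)
        base = mfcc_features(make_signal(x))
        scaled = mfcc_features(make_signal(10.0 * x))
        np.testing.assert_allclose(scaled[1:], base[1:], atol=1e-6)
        # log-power shift 2*ln(10) enters only the DCT constant basis
        expected_shift = 2 * np.log(10.0) * np.sqrt(26)
        assert scaled[0] - base[0] == pytest.approx(expected_shift, rel=1e-6)

    def test_excluding_zeroth_coefficient(self, rng):
        x = rng.standard_normal(4000)
        with_zero = mfcc_features(make_signal(x), include_zeroth=True)
        without = mfcc_features(make_signal(x), include_zeroth=False)
        np.testing.assert_allclose(without[:-1], with_zero[1:], atol=1e-12)

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValidationError):
            mfcc_features(make_signal(np.ones(100)))  # < one 200-sample frame


class TestExtract:
    def test_shape_and_determinism(self, rng):
        sig = make_signal(rng.standard_normal(8000))
        fv = extract_features(sig)
        assert fv.values.shape == (26,)
        assert np.all(np.isfinite(fv.values))
        assert fv.names == FEATURE_NAMES
        fv2 = extract_features(make_signal(sig.samples.copy()))
        np.testing.assert_array_equal(fv.values, fv2.values)

    def test_ms_and_as_recordings_differ(self):
        ms = zscore_normalize(synth_recording("MS", 3.0, 8000, seed=11))
        as_ = zscore_normalize(synth_recording("AS", 3.0, 8000, seed=11))
        diff = np.abs(extract_features(ms).values - extract_features(as_).values)
        assert np.max(diff) > 1e-3

    def test_feature_vector_validation(self):
        with pytest.raises(ValidationError):
            FeatureVector(np.ones(25))
        with pytest.raises(ValidationError):
            FeatureVector(np.full(26, np.inf))
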