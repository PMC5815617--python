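"""Signal conditioning: filtering, normalization, differentiation."""

import numpy as np
import pytest

from crossslope.gait_data import ConfigurationError, EventError
from crossslope.preprocess import (
    FilterSpec,
    GRAVITY,
    SwingReference,
    butterworth_gain,
    butterworth_lowpass,
    differentiate,
    normalize_ankle_to_swing,
    normalize_to_bodyweight,
)

FS = 120.0


def analytic_lowpass_gain(f: float, fc: float, fs: float, order: int, passes: int) -> float:
    """Independent oracle: magnitude of a digital (bilinear-transform)
    Butterworth low-pass at frequency f, raised to the number of passes."""
    ratio = np.tan(np.pi * f / fs) / np.tan(np.pi * fc / fs)
    return (1.0 / np.sqrt(1.0 + ratio ** (2 * order))) ** passes


class TestButterworth:
    def test_dc_gain_is_one(self):
        x = np.full(400, 3.7)
        np.testing.assert_allclose(butterworth_lowpass(x, FS), x, rtol=1e-9)

    @pytest.mark.parametrize("freq", [30.0, 40.0, 50.0])
    def test_stopband_matches_analytic_two_pass_magnitude(self, freq):
        spec = FilterSpec(order=4, cutoff=6.0, zero_phase=True)
        expected = analytic_lowpass_gain(freq, 6.0, FS, 4, passes=2)
        realized = butterworth_gain(freq, FS, spec)[0]
        assert realized == pytest.approx(expected, rel=0.01)

    def test_50hz_sinusoid_attenuated_below_1pct(self):
        t = np.arange(2400) / FS
        y = butterworth_lowpass(np.sin(2 * np.pi * 50 * t), FS)
        # look away from the edges where filtfilt transients live
        assert np.abs(y[300:-300]).max() < 0.01

    def test_passband_component_preserved(self):
        t = np.arange(2400) / FS
        x = np.sin(2 * np.pi * 1.0 * t) + np.sin(2 * np.pi * 40.0 * t)
        y = butterworth_lowpass(x, FS)
        core = slice(300, -300)
        ref = np.sin(2 * np.pi * 1.0 * t)[core]
        amp = np.vdot(ref, y[core]) / np.vdot(ref, ref)  # least-squares amplitude
        assert amp == pytest.approx(1.0, rel=0.02)

    def test_linearity(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=300), rng.normal(size=300)
        lhs = butterworth_lowpass(2.5 * x - 1.5 * y, FS)
        rhs = 2.5 * butterworth_lowpass(x, FS) - 1.5 * butterworth_lowpass(y, FS)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ConfigurationError, match="Nyquist"):
            butterworth_lowpass(np.zeros(100), FS, FilterSpec(cutoff=60.0))

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            butterworth_lowpass(np.zeros(10), FS)

    def test_odd_order_rejected(self):
        with pytest.raises(ConfigurationError):
            FilterSpec(order=3)


class TestBodyweight:
    def test_one_bodyweight(self):
        # 81.55 kg × 9.81 m/s² ≈ 800 N
        out = normalize_to_bodyweight(np.full(5, 800.0), 81.55)
        np.testing.assert_allclose(out, 800.0 / (81.55 * GRAVITY))
        assert out[0] == pytest.approx(1.0, rel=1e-3)

    def test_zero_and_linearity(self):
        x = np.array([1.0, -2.0, 3.0])
        np.testing.assert_array_equal(normalize_to_bodyweight(np.zeros(4), 70.0), 0.0)
        np.testing.assert_allclose(
            normalize_to_bodyweight(2 * x, 70.0), 2 * normalize_to_bodyweight(x, 70.0)
        )

    def test_missing_mass_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            normalize_to_bodyweight(np.ones(3), None)


class TestSwingNormalization:
    def test_constant_series_becomes_zero(self):
        out = normalize_ankle_to_swing(np.full(120, 7.0), FS, 0.8)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_reference_mean_subtracted_and_zeroed(self):
        rng = np.random.default_rng(3)
        x = rng.normal(3.2, 1.0, size=120)
        ref = SwingReference()
        out = normalize_ankle_to_swing(x, FS, 0.8, ref)
        i0 = int(round((0.8 + ref.start_s) * FS))
        i1 = int(round((0.8 + ref.end_s) * FS))
        np.testing.assert_allclose(out, x - x[i0:i1].mean())
        assert abs(out[i0:i1].mean()) < 1e-9

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=120)
        once = normalize_ankle_to_swing(x, FS, 0.8)
        twice = normalize_ankle_to_swing(once, FS, 0.8)
        np.testing.assert_allclose(once, twice, atol=1e-12)

    def test_interval_outside_recording(self):
        with pytest.raises(EventError):
            normalize_ankle_to_swing(np.zeros(50), FS, 0.3)

    def test_interval_must_precede_heel_strike(self):
        with pytest.raises(ConfigurationError):
            SwingReference(start_s=-0.1, end_s=0.1)


class TestDifferentiate:
    def test_linear_ramp(self):
        t = np.arange(60) / FS
        d = differentiate(4.2 * t, FS, order=1)
        np.testing.assert_allclose(d, 4.2, atol=1e-9)

    def test_quadratic_second_derivative(self):
        t = np.arange(60) / FS
        d2 = differentiate(2.5 * t**2, FS, order=2)
        np.testing.assert_allclose(d2[1:-1], 5.0, atol=1e-6)

    def test_sine_derivative_matches_analytic(self):
        f = 1.0
        t = np.arange(240) / FS
        d = differentiate(np.sin(2 * np.pi * f * t), FS, order=1)
        exact = 2 * np.pi * f * np.cos(2 * np.pi * f * t)
        assert np.abs(d[1:-1] - exact[1:-1]).max() < 1e-3 * (2 * np.pi * f)

    def test_offset_invariance(self):
        # differentiating a swing-normalized angle = differentiating the raw
        rng = np.random.default_rng(5)
        x = rng.normal(size=120)
        shifted = normalize_ankle_to_swing(x, FS, 0.8)
        np.testing.assert_allclose(
            differentiate(x, FS), differentiate(shifted, FS), atol=1e-9
        )

    def test_bad_order(self):
        with pytest.raises(ValueError):
            differentiate(np.zeros(10), FS, order=3)
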