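"""Forward-model operations: window, impulse response, timing maps, synthesis."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pulsedecon.model import (
    BaselineDrift,
    PulseShape,
    PulseTiming,
    WaveformObservation,
    anchor_index,
    baseline,
    clean_signal,
    impulse_response,
    impulse_response_deriv,
    interval_map,
    intervals_of,
    synthesize,
    times_from_intervals,
    window,
)


def make_shape(**kw):
    base = dict(a=1.0, w=np.zeros(4), f_h=0.5, g1=10.0, g2=0.0, g3=10.0, g4=1.0)
    base.update(kw)
    return PulseShape(**base)


class TestWindow:
    def test_half_at_left_center(self):
        # at t = g2 the first sigmoid is exactly 1/2 and the second ~1
        shape = make_shape(g1=10.0, g2=0.0, g3=10.0, g4=5.0)
        assert window(np.array([0.0]), shape)[0] == pytest.approx(0.5, abs=1e-6)

    def test_steep_limit_is_indicator(self):
        shape = make_shape(g1=1e6, g3=1e6, g2=0.2, g4=0.8)
        t = np.array([0.1, 0.5, 0.9])
        np.testing.assert_allclose(window(t, shape), [0.0, 1.0, 0.0], atol=1e-12)

    def test_scalar_value_against_sigmoid(self):
        # gamma(0.5) = sigmoid(5)^2 for g1=g3=10, g2=0, g4=1
        shape = make_shape()
        expected = (1.0 / (1.0 + np.exp(-5.0))) ** 2
        assert window(np.array([0.5]), shape)[0] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.9866, abs=1e-4)

    def test_open_unit_interval(self):
        shape = make_shape()
        vals = window(np.linspace(-5, 5, 101), shape)
        assert np.all(vals > 0) and np.all(vals < 1)

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            window(np.array([np.nan]), make_shape())


class TestImpulseResponse:
    def test_zero_weights_reduce_to_window(self):
        shape = make_shape(a=2.0)
        t = np.linspace(-1, 2, 50)
        np.testing.assert_allclose(impulse_response(t, shape),
                                   2.0 * window(t, shape), rtol=1e-12)

    def test_zero_amplitude(self):
        shape = make_shape(a=0.0, w=np.array([1.0, -2.0]))
        assert np.all(impulse_response(np.linspace(0, 1, 9), shape) == 0)

    def test_hand_evaluated_scalar(self):
        # a=1, w=(0.5, 0), f_h=1 Hz, saturated window, t=0.25 -> 1.5
        shape = PulseShape(a=1.0, w=np.array([0.5, 0.0]), f_h=1.0,
                           g1=1e9, g2=-100.0, g3=1e9, g4=100.0)
        val = impulse_response(np.array([0.25]), shape)[0]
        expected = 0.5 * np.sin(np.pi / 2) + 0.0 * np.cos(np.pi / 2) + 1.0
        assert val == pytest.approx(expected, rel=1e-9)
        assert val == pytest.approx(1.5, rel=1e-9)

    def test_weight_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            PulseShape(a=1.0, w=np.zeros(3), f_h=0.5, g1=1, g2=0, g3=1, g4=1)

    def test_analytic_derivative_matches_finite_difference(self):
        shape = make_shape(w=np.array([0.3, -0.2, 0.1, 0.05]))
        t = np.linspace(-0.5, 1.5, 41)
        eps = 1e-6
        fd = (impulse_response(t + eps, shape) - impulse_response(t - eps, shape)) / (2 * eps)
        np.testing.assert_allclose(impulse_response_deriv(t, shape), fd,
                                   rtol=1e-6, atol=1e-8)


class TestBaseline:
    def test_zero_weights(self):
        drift = BaselineDrift(b=np.zeros(6), f_b=0.1)
        assert np.all(baseline(np.linspace(0, 10, 11), drift) == 0)

    def test_constant_term(self):
        drift = BaselineDrift(b=np.array([3.5, 0, 0, 0]), f_b=0.1)
        np.testing.assert_allclose(baseline(np.linspace(0, 10, 11), drift), 3.5)

    def test_linear_term(self):
        drift = BaselineDrift(b=np.array([0.0, 1.0, 0.0]), f_b=0.1)
        assert baseline(np.array([2.5]), drift)[0] == pytest.approx(2.5)

    def test_harmonic_terms_match_direct_trig(self):
        b = np.array([0.5, -0.1, 1.0, 2.0, -3.0, 0.7])
        drift = BaselineDrift(b=b, f_b=0.25)
        t = np.linspace(0, 8, 33)
        expected = (b[0] + b[1] * t
                    + b[2] * np.sin(2 * np.pi * 0.25 * t)
                    + b[3] * np.cos(2 * np.pi * 0.25 * t)
                    + b[4] * np.sin(4 * np.pi * 0.25 * t)
                    + b[5] * np.cos(4 * np.pi * 0.25 * t))
        np.testing.assert_allclose(baseline(t, drift), expected, rtol=1e-12)


class TestIntervalMap:
    def test_forced_example(self):
        z = times_from_intervals([0.8, 1.0, 1.2], z_m=10.0, m=2)
        np.testing.assert_allclose(z, [9.2, 10.0, 11.0, 12.2])

    def test_matrix_agrees_with_fast_path(self):
        zp = np.array([0.8, 1.0, 1.2])
        D = interval_map(4, 2)
        np.testing.assert_allclose(zp @ D + 10.0,
                                   times_from_intervals(zp, 10.0, 2))

    def test_single_pulse(self):
        np.testing.assert_allclose(times_from_intervals([], 3.0, 1), [3.0])
        assert interval_map(1, 1).shape == (0, 1)

    def test_m_out_of_range(self):
        with pytest.raises(ValueError):
            interval_map(4, 5)
        with pytest.raises(ValueError):
            times_from_intervals([1.0], 0.0, 3)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(min_value=1, max_value=50), st.integers(min_value=0, max_value=10**6))
    def test_round_trip_exact(self, M, raw_seed):
        rng = np.random.default_rng(raw_seed)
        zp = rng.uniform(0.3, 2.0, size=M - 1)
        m = anchor_index(M)
        z = times_from_intervals(zp, 5.0, m)
        np.testing.assert_array_equal(intervals_of(z), np.diff(z))
        np.testing.assert_allclose(np.diff(z), zp, rtol=0, atol=1e-12)
        assert z[m - 1] == 5.0


class TestCleanSignal:
    def test_single_pulse_identity(self):
        shape = make_shape(w=np.array([0.2, -0.1, 0.0, 0.3]))
        timing = PulseTiming(z=np.array([0.0]), t0=0.0, m=1)
        t = np.linspace(-1, 2, 64)
        np.testing.assert_allclose(clean_signal(t, timing, shape),
                                   impulse_response(t, shape), rtol=1e-12)

    def test_linear_in_amplitude(self):
        timing = PulseTiming(z=np.array([0.0, 0.9, 1.7]), t0=0.95, m=2)
        t = np.linspace(0, 2.5, 100)
        y1 = clean_signal(t, timing, make_shape(a=1.0))
        y2 = clean_signal(t, timing, make_shape(a=2.0))
        np.testing.assert_allclose(y2, 2 * y1, rtol=1e-12)

    def test_overlapping_pulses_equal_brute_force_sum(self):
        shape = make_shape(w=np.array([0.4, 0.1, -0.2, 0.0]), g4=1.5)
        z = np.array([0.0, 0.6, 1.1, 2.0])
        timing = PulseTiming(z=z, t0=0.7, m=2)
        t = np.linspace(-0.5, 3.5, 200)
        brute = np.zeros_like(t)
        for zi in z:  # independent loop-summation oracle
            brute += impulse_response(t - zi, shape)
        np.testing.assert_allclose(clean_signal(t, timing, shape), brute,
                                   rtol=1e-10, atol=1e-12)


class TestSynthesize:
    def test_zero_noise_exact(self):
        shape = make_shape()
        timing = PulseTiming(z=np.array([0.2, 1.1]), t0=0.5, m=1)
        drift = BaselineDrift(b=np.array([1.0, 0.1]), f_b=0.2)
        t = np.linspace(0, 2, 65)
        y = synthesize(t, timing, shape, drift, sigma_eps=0.0, seed=1)
        np.testing.assert_array_equal(
            y, clean_signal(t, timing, shape) + baseline(t, drift))

    def test_seed_determinism(self):
        shape = make_shape()
        timing = PulseTiming(z=np.array([0.2, 1.1]), t0=0.5, m=1)
        t = np.linspace(0, 2, 65)
        y1 = synthesize(t, timing, shape, sigma_eps=0.3, seed=42)
        y2 = synthesize(t, timing, shape, sigma_eps=0.3, seed=42)
        np.testing.assert_array_equal(y1, y2)

    def test_negative_sigma_rejected(self):
        shape = make_shape()
        timing = PulseTiming(z=np.array([0.0]), t0=0.0, m=1)
        with pytest.raises(ValueError):
            synthesize(np.linspace(0, 1, 10), timing, shape, sigma_eps=-1.0)

    def test_noise_variance_calibration(self):
        # empirical variance within 3 standard errors of sigma^2 at n=1e5
        shape = make_shape()
        timing = PulseTiming(z=np.array([0.5]), t0=0.4, m=1)
        n = 100_000
        t = np.linspace(0, 1000, n)
        sigma = 0.7
        resid = (synthesize(t, timing, shape, sigma_eps=sigma, seed=5)
                 - clean_signal(t, timing, shape))
        se = sigma**2 * np.sqrt(2.0 / n)
        assert abs(np.var(resid) - sigma**2) < 3 * se


class TestObservationValidation:
    def test_rejects_decreasing_time(self):
        with pytest.raises(ValueError):
            WaveformObservation(t=np.array([0.0, 1.0, 0.5]), y=np.zeros(3))

    def test_rejects_nan(self):
        with pytest.raises(ValueError):
            WaveformObservation(t=np.array([0.0, 1.0]), y=np.array([0.0, np.nan]))

    def test_rejects_length_mismatch(self):
        with pytest.raises(ValueError):
            WaveformObservation(t=np.array([0.0, 1.0, 2.0]), y=np.zeros(2))
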