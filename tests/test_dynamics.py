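"""Leaky integrators, phasic transform, threshold gate and noise."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vtanet.dynamics import (
    PhasicFilter,
    UnitState,
    draw_noise,
    euler_membrane,
    threshold_gate,
    weighted_sum,
)


class TestWeightedSum:
    @pytest.mark.parametrize("w, r, expected", [
        ([1.0, 0.5], [0.2, 0.4], 0.4),
        ([], [], 0.0),
        ([1, 1, 1], [1 / 3, 1 / 3, 1 / 3], 1.0),
    ])
    def test_examples(self, w, r, expected):
        assert weighted_sum(w, r) == pytest.approx(expected)

    def test_length_mismatch_is_fatal(self):
        with pytest.raises(ValueError, match="mismatch"):
            weighted_sum([1.0, 2.0], [1.0])


class TestThresholdGate:
    @pytest.mark.parametrize("x, gamma, expected", [
        (0.05, 0.1, 0.0),
        (0.1, 0.1, 1.0),   # equality counts as exceeding
        (2.0, 0.1, 1.0),
    ])
    def test_examples(self, x, gamma, expected):
        assert threshold_gate(x, gamma) == expected

    @given(st.floats(-5, 5), st.floats(-5, 5), st.floats(-2, 2))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_in_x(self, a, b, gamma):
        lo, hi = min(a, b), max(a, b)
        assert threshold_gate(lo, gamma) <= threshold_gate(hi, gamma)

    def test_vectorized(self):
        out = threshold_gate(np.array([0.0, 0.1, 0.5]), 0.1)
        assert out.tolist() == [0.0, 1.0, 1.0]


class TestPhasicFilter:
    def test_constant_input_fixed_point(self):
        # with constant x the output converges to x * (1 - k)
        for k in (0.0, 0.5, 0.8, 1.0):
            f = PhasicFilter(tau=50.0, k=k)
            y = 0.0
            for _ in range(5000):
                y = f.step(0.7)
            assert y == pytest.approx(0.7 * (1 - k), abs=1e-6)

    def test_k1_output_vanishes_under_constant_input(self):
        f = PhasicFilter(tau=50.0, k=1.0)
        for _ in range(20 * 50):
            y = f.step(1.0)
        assert abs(y) < 1e-6

    def test_zero_input_zero_output(self):
        f = PhasicFilter(tau=50.0, k=1.0)
        assert all(f.step(0.0) == 0.0 for _ in range(100))

    def test_running_average_converges_to_input(self):
        f = PhasicFilter(tau=20.0, k=1.0)
        for _ in range(2000):
            f.step(0.4)
        assert f.xbar == pytest.approx(0.4, abs=1e-6)

    def test_direct_form_step_response_decays_from_onset(self):
        # step input, k=1: transient is maximal at onset, then decays
        f = PhasicFilter(tau=50.0, k=1.0)
        ys = [f.step(1.0) for _ in range(300)]
        assert ys[0] == pytest.approx(1.0, abs=0.05)
        assert all(a >= b for a, b in zip(ys, ys[1:]))

    def test_cascade_form_bump_peaks_at_tau(self):
        # step input, k=1, cascade: a smooth bump with its maximum at t=tau
        tau = 50.0
        f = PhasicFilter(tau=tau, k=1.0, cascade=True)
        ys = np.array([f.step(1.0) for _ in range(1000)])
        assert abs(int(np.argmax(ys)) - tau) <= 3
        assert ys[-1] < 0.01 * ys.max()

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            PhasicFilter(tau=0.0, k=0.5)
        with pytest.raises(ValueError):
            PhasicFilter(tau=10.0, k=1.5)


class TestUnitDynamics:
    def test_one_euler_step_arithmetic(self):
        u = UnitState(m=0.0, tau=10.0, B=0.2, noise_amp=0.0)
        u.step(drive=0.0)
        assert u.m == pytest.approx(0.02)

    def test_relaxes_to_baseline(self):
        u = UnitState(m=0.7, tau=10.0, B=0.2, noise_amp=0.0)
        for _ in range(500):
            u.step(drive=0.0)
        assert u.r == pytest.approx(0.2, abs=1e-6)

    def test_negative_drive_rectifies(self):
        u = UnitState(m=0.0, tau=10.0, B=0.0, noise_amp=0.0)
        for _ in range(500):
            u.step(drive=-1.0)
        assert u.m == pytest.approx(-1.0, abs=1e-6)
        assert u.r == 0.0

    @pytest.mark.parametrize("tau", [10.0, 50.0, 450.0])
    def test_euler_matches_closed_form(self, tau):
        # tau dm/dt + m = c  =>  m(t) = c + (m0 - c) exp(-t / tau).
        # Forward Euler's worst-case deviation from the exponential is
        # first-order: about dt/(2 tau) of the step amplitude.
        c, m0, dt = 0.8, 0.1, 1.0
        tol = max(1e-3, 0.6 * dt / tau * abs(m0 - c))
        m = m0
        for i in range(1, 2001):
            m = euler_membrane(m, c, tau, dt)
            exact = c + (m0 - c) * np.exp(-i * dt / tau)
            assert abs(m - exact) < tol

    def test_nonfinite_drive_raises(self):
        with pytest.raises(FloatingPointError):
            euler_membrane(0.0, np.nan, 10.0)


class TestNoise:
    def test_zero_amplitude(self, rng):
        assert np.all(draw_noise(rng, 100, 0.0) == 0.0)

    def test_range_and_mean(self):
        rng = np.random.default_rng(7)
        x = draw_noise(rng, 200_000, 0.1)
        assert x.min() >= -0.1 and x.max() <= 0.1
        assert abs(x.mean()) < 1e-3

    def test_seeded_reproducibility(self):
        a = draw_noise(np.random.default_rng(5), 64, 0.1)
        b = draw_noise(np.random.default_rng(5), 64, 0.1)
        np.testing.assert_array_equal(a, b)

    def test_negative_amplitude_rejected(self, rng):
        with pytest.raises(ValueError):
            draw_noise(rng, 10, -0.1)
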