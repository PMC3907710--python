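"""Plasticity rules: worked examples, bounds, and invariances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vtanet.learning import (
    PlasticityParams,
    RegularizerState,
    covariance_update,
    da_covariance_update,
    hebbian_threshold_update,
    modulated_transfer_update,
    or_product,
    regularizer_step,
)


def W1(value=0.0):
    return np.array([[value]])


class TestHebbianThreshold:
    def test_direct_arithmetic(self):
        p = PlasticityParams(eps=100.0, theta_pre=0.0, theta_post=0.5,
                             w_min=0.0, w_max=2.0)
        W = hebbian_threshold_update(W1(), np.array([0.8]), np.array([0.8]), p)
        assert W[0, 0] == pytest.approx(0.0024)

    def test_subthreshold_post_no_change(self):
        p = PlasticityParams(eps=100.0, theta_post=0.5)
        W = hebbian_threshold_update(W1(0.3), np.array([1.0]), np.array([0.4]), p)
        assert W[0, 0] == 0.3

    def test_upper_bound_holds(self):
        p = PlasticityParams(eps=1.0, w_min=0.0, w_max=2.0)
        W = W1(2.0)
        for _ in range(10):
            hebbian_threshold_update(W, np.array([1.0]), np.array([1.0]), p)
        assert W[0, 0] == 2.0


class TestCovariance:
    def test_identical_rates_no_learning(self):
        p = PlasticityParams(eps=100.0)
        r = np.full(5, 0.4)
        W = np.zeros((5, 5))
        covariance_update(W, r, r, r.mean(), r.mean(), p)
        assert np.all(W == 0.0)

    def test_direct_arithmetic(self):
        p = PlasticityParams(eps=100.0)
        W = covariance_update(W1(), np.array([1.0]), np.array([1.0]), 0.2, 0.2, p)
        assert W[0, 0] == pytest.approx(0.0064)

    def test_pre_below_mean_no_change(self):
        p = PlasticityParams(eps=100.0)
        W = covariance_update(W1(0.1), np.array([0.1]), np.array([1.0]), 0.5, 0.2, p)
        assert W[0, 0] == 0.1


class TestOrProduct:
    def test_both_negative_is_zero(self):
        assert or_product(-0.1, -0.2) == 0.0

    def test_one_positive_gives_ltd(self):
        assert or_product(0.3, -0.2) == pytest.approx(-0.06)

    def test_both_positive_gives_ltp(self):
        assert or_product(0.3, 0.2) == pytest.approx(0.06)


class TestDaCovariance:
    def p(self, **kw):
        kw.setdefault("eps", 100.0)
        kw.setdefault("K", 10.0)
        kw.setdefault("w_min", 0.0)
        kw.setdefault("w_max", 2.0)
        return PlasticityParams(**kw)

    def test_no_dopamine_no_alpha_no_change(self):
        W = W1(0.5)
        reg = RegularizerState.zeros(1)
        da_covariance_update(W, np.array([1.0]), np.array([1.0]), 0.2, 0.2,
                             0.0, reg, self.p())
        assert W[0, 0] == 0.5

    def test_silent_pair_never_potentiates(self):
        W = W1(0.5)
        reg = RegularizerState.zeros(1)
        da_covariance_update(W, np.array([0.1]), np.array([0.0]), 0.2, 0.2,
                             1.0, reg, self.p())
        assert W[0, 0] == 0.5  # OR(-0.1, -0.2) = 0

    def test_dopamine_floor_gates_weak_transients(self):
        W = W1(0.5)
        reg = RegularizerState.zeros(1)
        da_covariance_update(W, np.array([1.0]), np.array([1.0]), 0.2, 0.2,
                             0.04, reg, self.p(theta_dopa=0.05))
        assert W[0, 0] == 0.5

    def test_overactive_post_drives_weights_down(self):
        # pinned postsynaptic rate above r_max with no dopamine: the
        # regularization trace grows and monotonically shrinks the weight
        p = self.p(tau_alpha=5.0)
        W = W1(1.5)
        reg = RegularizerState.zeros(1)
        post = np.array([1.4])
        last = W[0, 0]
        for _ in range(800):
            regularizer_step(reg, post, p)
            da_covariance_update(W, np.array([0.0]), post, 0.0, 0.0, 0.0, reg, p)
            assert W[0, 0] <= last
            last = W[0, 0]
        assert W[0, 0] < 0.1
        assert reg.alpha[0] == pytest.approx(0.4, abs=1e-3)

    def test_replay_reproduces_weights(self):
        # the rule is pure: identical input streams give identical weights
        rng = np.random.default_rng(0)
        stream = [(rng.uniform(0, 1, 4), rng.uniform(0, 1, 3), rng.uniform(0, 1))
                  for _ in range(50)]

        def run():
            W = np.full((3, 4), 0.2)
            reg = RegularizerState.zeros(3)
            p = self.p()
            for pre, post, da in stream:
                regularizer_step(reg, post, p)
                da_covariance_update(W, pre, post, pre.mean(), post.mean(),
                                     da, reg, p)
            return W

        np.testing.assert_array_equal(run(), run())


class TestRegularizer:
    def test_fixed_point(self):
        p = PlasticityParams(eps=1.0, tau_alpha=10.0)
        reg = RegularizerState.zeros(1)
        for _ in range(500):
            regularizer_step(reg, np.array([1.2]), p)
        assert reg.alpha[0] == pytest.approx(0.2, abs=1e-6)

    def test_one_step_arithmetic(self):
        p = PlasticityParams(eps=1.0, tau_alpha=1.0)
        reg = RegularizerState.zeros(1)
        regularizer_step(reg, np.array([1.5]), p)
        assert reg.alpha[0] == pytest.approx(0.5)

    def test_decays_to_zero_below_rmax(self):
        p = PlasticityParams(eps=1.0, tau_alpha=5.0)
        reg = RegularizerState(alpha=np.array([0.3]))
        for _ in range(500):
            regularizer_step(reg, np.array([0.8]), p)
        assert reg.alpha[0] == 0.0


class TestModulatedTransfer:
    def p(self):
        return PlasticityParams(eps=300.0, w_min=-np.inf, w_max=np.inf,
                                gamma_dopa=0.3)

    def test_gate_closed_below_dopamine_threshold(self):
        W = W1(0.2)
        modulated_transfer_update(W, np.array([1.0]), np.array([1.0]),
                                  0.1, 0.1, 0.2, np.array([0.8]),
                                  np.array([0.2]), self.p())
        assert W[0, 0] == 0.2

    def test_no_headroom_no_learning(self):
        W = W1(0.2)
        modulated_transfer_update(W, np.array([1.0]), np.array([1.0]),
                                  0.1, 0.1, 1.0, np.array([0.2]),
                                  np.array([0.8]), self.p())
        assert W[0, 0] == 0.2

    def test_direct_arithmetic(self):
        W = W1()
        modulated_transfer_update(W, np.array([1.0]), np.array([1.0]),
                                  0.1, 0.1, 1.0, np.array([0.8]),
                                  np.array([0.2]), self.p())
        assert W[0, 0] == pytest.approx(0.00162)


@given(
    n_pre=st.integers(1, 6), n_post=st.integers(1, 6),
    w_min=st.floats(-0.5, 0.0), w_max=st.floats(0.1, 2.0),
    seed=st.integers(0, 2**31 - 1),
)
@settings(max_examples=40, deadline=None, derandomize=True)
def test_all_rules_respect_weight_bounds(n_pre, n_post, w_min, w_max, seed):
    rng = np.random.default_rng(seed)
    p = PlasticityParams(eps=5.0, w_min=w_min, w_max=w_max, K=10.0,
                         theta_post=0.2)
    W = rng.uniform(w_min, w_max, size=(n_post, n_pre))
    reg = RegularizerState(alpha=rng.uniform(0, 0.5, n_post))
    for _ in range(5):
        pre = rng.uniform(0, 1.5, n_pre)
        post = rng.uniform(0, 1.5, n_post)
        hebbian_threshold_update(W, pre, post, p)
        covariance_update(W, pre, post, pre.mean(), post.mean(), p)
        da_covariance_update(W, pre, post, pre.mean(), post.mean(),
                             rng.uniform(0, 1), reg, p)
        modulated_transfer_update(W, pre, post, pre.mean(), post.mean(),
                                  rng.uniform(0, 1), rng.uniform(0, 1, n_post),
                                  rng.uniform(0, 1, n_post), p)
        assert np.all(W >= w_min - 1e-12)
        assert np.all(W <= w_max + 1e-12)
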