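"""Network assembly, baselines, state machine and oscillator banks."""

import numpy as np
import pytest

from vtanet import build_network
from vtanet.network import NetworkConfig

from conftest import settle


class TestAssembly:
    def test_population_sizes(self, net):
        assert net.m_it.shape == (9,)
        assert net.m_lh.shape == (4,)
        assert net.m_bla.shape == (36,)
        assert net.m_pptn.shape == (2,)
        assert net.m_pfc.shape == (150,)      # 3 banks of 50 oscillators
        assert net.m_nacc.shape == (36,)

    def test_fixed_weights_from_table(self, net):
        assert net.w_pptn_pptn == 2.0
        assert net.w_pptn_vta == 1.5
        assert net.w_vp_lhb == 3.0
        assert net.w_lhb_rmtg == 1.5
        assert net.w_it_pfc == 0.3
        assert net.w_vta_nacc == 0.5

    def test_initial_learnable_weights(self, net):
        assert net.W_lh_bla.min() >= 0.1 and net.W_lh_bla.max() <= 0.5
        assert np.all(net.W_it_bla == 0.0)
        assert np.all(net.W_pfc_nacc == 0.0)
        assert np.all(net.w_nacc_vp == 0.0)
        # lateral inhibition starts at 0.5 with an empty diagonal
        off = ~np.eye(36, dtype=bool)
        assert np.all(net.W_bla_bla[off] == 1.0)
        assert np.all(np.diag(net.W_bla_bla) == 0.0)

    def test_oscillator_parameters_drawn_once(self):
        a = build_network(rng=9)
        b = build_network(rng=9)
        np.testing.assert_array_equal(a.osc_freq, b.osc_freq)
        np.testing.assert_array_equal(a.osc_phase, b.osc_phase)
        np.testing.assert_array_equal(a.W_lh_bla, b.W_lh_bla)
        assert a.osc_freq.min() >= 2.0 and a.osc_freq.max() <= 8.0
        assert a.osc_phase.min() >= 0.0 and a.osc_phase.max() <= np.pi


class TestBaselines:
    def test_resting_rates(self, net):
        vta = settle(net, 1500)
        assert abs(vta[:1000].mean() - 0.2) < 0.02     # dopaminergic baseline
        assert abs(net.r_vp - 0.5) < 0.15              # pallidal baseline
        assert net.r_lhb == 0.0                        # silenced by VP
        assert net.r_rmtg < 0.15
        assert net.r_bla.max() < 0.15
        assert net.r_it.max() < 0.15

    def test_rates_never_negative_and_nacc_clamped(self, net):
        cs = np.array([1.0, 0.0, 0.0])
        us = np.array([1.0, 1.0, 0.0, 0.0])
        for i in range(800):
            net.step(cs if i > 200 else np.zeros(3),
                     us if i > 500 else np.zeros(4), 1.0, True)
            for r in (net.r_it, net.r_lh, net.r_bla, net.r_pptn, net.r_pfc,
                      net.r_nacc):
                assert np.all(r >= 0.0)
            assert np.all(net.r_nacc <= 1.1)
            assert set(np.unique(net.s)) <= {-0.9, -0.4}


class TestSensoryDrive:
    def test_cs_activates_its_cluster_only(self, net):
        cs = np.array([1.0, 0.0, 0.0])
        for _ in range(300):
            net.step(cs, np.zeros(4), 0.0)
        assert np.all(net.r_it[:3] > 0.8)
        assert np.all(net.r_it[3:] < 0.2)

    def test_lh_encodes_taste_times_magnitude(self, net):
        us = np.array([1.0, 1.0, 0.0, 0.0])
        for _ in range(300):
            net.step(np.zeros(3), us, 0.8)
        assert np.allclose(net.r_lh[:2], 0.8, atol=0.15)
        assert np.all(net.r_lh[2:] < 0.2)


class TestOscillatorBanks:
    def drive(self, net, cs, n):
        for _ in range(n):
            net.step(cs, np.zeros(4), 0.0)

    def test_bank_activates_on_its_cs_and_stores_t0(self, net):
        self.drive(net, np.array([0.0, 1.0, 0.0]), 200)
        assert net.bank_active.tolist() == [False, True, False]
        assert 0 < net.bank_t0[1] < 200
        assert net.r_pfc[50:100].max() > 0.5
        assert net.r_pfc[:50].max() == 0.0

    def test_bank_silenced_when_cs_removed(self, net):
        self.drive(net, np.array([0.0, 1.0, 0.0]), 200)
        self.drive(net, np.zeros(3), 200)
        assert not net.bank_active.any()
        assert np.all(net.m_pfc == 0.0)

    def test_t0_not_refreshed_while_active(self, net):
        self.drive(net, np.array([1.0, 0.0, 0.0]), 150)
        t0 = net.bank_t0[0]
        self.drive(net, np.array([1.0, 0.0, 0.0]), 500)
        assert net.bank_t0[0] == t0

    def test_oscillator_rates_bounded(self, net):
        self.drive(net, np.array([1.0, 0.0, 0.0]), 1000)
        assert net.r_pfc[:50].min() >= 0.0
        assert net.r_pfc[:50].max() <= 1.0 + 1e-9


class TestNAccStateMachine:
    def test_dopamine_burst_forces_up_state(self, net):
        net.r_vta = 0.35
        net._nacc_transitions(np.zeros(36))
        assert net.nacc_up.all()
        assert np.all(net.s == -0.4)

    def test_massive_glutamate_forces_up_state(self, net):
        net.r_vta = 0.0
        net.s_time[:] = -0.6
        net.nacc_up[:] = False
        glut = np.zeros(36)
        glut[3] = 1.2
        net._nacc_transitions(glut)
        assert net.nacc_up[3]
        assert not net.nacc_up[4]

    def test_relaxation_mode_oscillates_spontaneously(self):
        cfg = NetworkConfig(nacc_state_mode="relaxation", noise_amp=0.0)
        net = build_network(cfg, rng=0)
        ups = []
        for _ in range(4000):
            net.step(np.zeros(3), np.zeros(4), 0.0)
            ups.append(net.nacc_up[0])
        flips = int(np.sum(np.diff(np.asarray(ups, dtype=int)) != 0))
        # ~2 s period (delta band) over 4 s -> a handful of transitions
        assert 2 <= flips <= 10

    def test_latched_mode_never_returns_down(self):
        cfg = NetworkConfig(nacc_state_mode="latched", noise_amp=0.0)
        net = build_network(cfg, rng=0)
        # drive s_time above the up threshold once, then remove all input
        net.s_time[:] = -0.3
        for _ in range(3000):
            net.step(np.zeros(3), np.zeros(4), 0.0)
        assert net.nacc_up.all()


class TestPallidalShunt:
    @pytest.mark.parametrize("printed, expect_inhibited", [
        (False, True),   # corrected form: NAcc reaches VP when PPTN silent
        (True, False),   # printed form: inhibition gated on by PPTN drive
    ])
    def test_gating_polarity(self, printed, expect_inhibited):
        cfg = NetworkConfig(vp_gating_printed=printed, noise_amp=0.0)
        net = build_network(cfg, rng=0)
        net.w_nacc_vp[:] = 2.0
        net.r_nacc[:5] = 1.0       # accumbens active, PPTN silent
        for _ in range(200):
            net.step(np.zeros(3), np.zeros(4), 0.0)
            net.r_nacc[:5] = 1.0   # hold the accumbens drive
        if expect_inhibited:
            assert net.r_vp < 0.05
        else:
            assert net.r_vp > 0.4

    def test_disconnect_unknown_projection_rejected(self, net):
        with pytest.raises(KeyError):
            net.disconnect("IT", "VTA")
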