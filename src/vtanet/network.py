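"""The conditioning circuit: populations, projections and the full network.

The model is a rate-coded network of the afferents to the ventral tegmental
area (VTA) engaged by appetitive delay conditioning:

* IT (inferotemporal cortex, 9 units in 3 clusters) encodes the visual cue
  (CS); LH (lateral hypothalamus, 4 units) encodes the taste components of
  the reward (US), scaled by its magnitude.
* BLA (basolateral amygdala, 36 units) associates CS and US under
  dopamine-modulated plasticity and relays through CE (central amygdala).
* PPTN (pedunculopontine nucleus, 2 mutually inhibiting units) converts US
  (from LH) and CS (from CE) events into phasic glutamatergic drive on VTA.
* vmPFC holds 3 banks of 50 oscillators (2-8 Hz) synchronized at CS onset;
  NAcc (nucleus accumbens, 36 bistable units) learns to detect the
  oscillator configuration at the moment of reward - a striatal-beat-
  frequency timer.
* VP, LHb and RMTg (ventral pallidum, lateral habenula, rostromedial
  tegmental nucleus) form the disinhibition chain that silences VTA when a
  predicted reward is omitted.

All populations advance synchronously on a 1-ms Euler grid: typed input
sums are computed from the rates at time t, then phasic filters, then all
membrane potentials, then rates, then the NAcc state machine, then (when
enabled) plasticity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import DT, NOISE_AMP, PhasicFilter, threshold_gate
from .learning import (
    PlasticityParams,
    RegularizerState,
    covariance_update,
    da_covariance_update,
    hebbian_threshold_update,
    modulated_transfer_update,
    regularizer_step,
)

__all__ = [
    "ProjectionRow",
    "NetworkConfig",
    "Network",
    "default_projection_rows",
    "build_network",
]

_INF = float("inf")


@dataclass
class ProjectionRow:
    """One row of the connectivity table."""

    pre: str
    post: str
    syn_type: str           # exc | inh | mod | dopa
    pattern: str            # one-to-one | one-to-many | many-to-many | all-to-all | all-to-one
    weight: float           # fixed weight, or mean initial weight if learnable
    weight_spread: float = 0.0   # half-width of the uniform initial distribution
    rule: str = "fixed"     # fixed | hebb | cov | da_cov | transfer
    w_min: float = -_INF
    w_max: float = _INF
    eps: float = 1.0
    theta_pre: float = 0.0
    theta_post: float = 0.0
    K: float = 0.0
    tau_dopa: float = 1.0
    k_dopa: float = 1.0
    tau_alpha: float = 1.0
    theta_dopa: float = 0.0

    def params(self) -> PlasticityParams:
        return PlasticityParams(
            eps=self.eps, w_min=self.w_min, w_max=self.w_max,
            theta_pre=self.theta_pre, theta_post=self.theta_post,
            K=self.K, tau_dopa=self.tau_dopa, k_dopa=self.k_dopa,
            tau_alpha=self.tau_alpha, theta_dopa=self.theta_dopa,
        )


def default_projection_rows() -> list[ProjectionRow]:
    """The full connectivity table of the model.

    The VTA->BLA dopaminergic synapse carries a fixed unit weight: it is
    consumed by the amygdalar learning rules rather than by the membrane
    equation.  The VTA->NAcc dopaminergic weight is 0.5.
    """
    R = ProjectionRow
    return [
        R("VIS", "IT", "exc", "one-to-many", 1.0),
        R("GUS", "LH", "exc", "one-to-one", 1.0),
        R("LH", "BLA", "exc", "all-to-all", 0.3, weight_spread=0.2,
          rule="da_cov", w_min=0.0, w_max=0.5, eps=1000.0, K=10.0,
          tau_dopa=100.0, k_dopa=1.0, tau_alpha=1.0, theta_dopa=0.05),
        R("IT", "BLA", "mod", "all-to-all", 0.0, rule="transfer", eps=1000.0),
        R("BLA", "BLA", "inh", "all-to-all", 1.0, rule="cov",
          w_min=0.0, w_max=3.0, eps=30.0),
        R("BLA", "CE", "exc", "all-to-all", 1.0),
        R("CE", "PPTN", "exc", "all-to-one", 1.5),
        R("LH", "PPTN", "exc", "all-to-one", 0.75),
        R("PPTN", "PPTN", "inh", "all-to-all", 2.0),
        R("PPTN", "VTA", "exc", "all-to-all", 1.5),
        R("PPTN", "VP", "exc", "all-to-all", 0.5),
        R("VP", "RMTg", "inh", "all-to-all", 1.0),
        R("VP", "LHb", "inh", "all-to-all", 3.0),
        R("LHb", "RMTg", "exc", "all-to-all", 1.5),
        R("RMTg", "VTA", "inh", "all-to-all", 1.0),
        R("IT", "vmPFC", "exc", "many-to-many", 0.3),
        R("vmPFC", "NAcc", "mod", "all-to-all", 0.0, rule="da_cov",
          w_min=-0.2, eps=50.0, K=5.0, tau_dopa=10.0, k_dopa=1.0,
          tau_alpha=10.0, theta_dopa=0.03),
        R("BLA", "NAcc", "exc", "one-to-one", 0.3),
        R("VTA", "NAcc", "dopa", "all-to-all", 0.5),
        R("NAcc", "NAcc", "inh", "all-to-all", 0.5, rule="cov",
          w_min=0.0, w_max=1.0, eps=1000.0),
        R("NAcc", "VP", "inh", "all-to-all", 0.0, rule="hebb",
          w_min=0.0, w_max=2.0, eps=100.0, theta_pre=0.0, theta_post=0.5),
        R("NAcc", "VTA", "inh", "all-to-all", 0.0, rule="hebb",
          w_min=0.0, w_max=2.0, eps=500.0, theta_pre=0.0, theta_post=0.0),
        R("VTA", "BLA", "dopa", "all-to-all", 1.0),
    ]


#: (pre, post) keys that must appear exactly once in any configuration.
REQUIRED_PROJECTIONS = {(r.pre, r.post) for r in default_projection_rows()}


@dataclass
class NetworkConfig:
    """Structural and dynamical parameters of the network."""

    n_it: int = 9
    n_lh: int = 4
    n_bla: int = 36
    n_pptn: int = 2
    n_banks: int = 3
    bank_size: int = 50
    n_nacc: int = 36

    dt: float = DT
    noise_amp: float = NOISE_AMP

    # membrane time constants (ms) and baselines
    tau_m: float = 10.0
    vp_baseline: float = 0.5
    lhb_baseline: float = 1.0
    vta_baseline: float = 0.2

    # BLA input filtering
    bla_tau_exc: float = 500.0
    bla_tau_mod: float = 500.0
    bla_k: float = 0.8
    bla_gamma: float = 0.1

    # PPTN input filtering
    pptn_tau_exc: float = 50.0
    pptn_k: float = 1.0

    # vmPFC oscillators
    f_range: tuple[float, float] = (2.0, 8.0)
    phase_range: tuple[float, float] = (0.0, np.pi)
    t_start: float = 0.8
    t_stop: float = 0.2
    pfc_tau: float = 1.0

    # NAcc state machine
    s_down: float = -0.9
    s_up: float = -0.4
    tau_s: float = 450.0
    gamma_dopa: float = 0.3
    gamma_glut: float = 1.0
    gamma_up: float = -0.45
    gamma_down: float = -0.85
    nacc_rate_max: float = 1.1
    # "relaxation": spontaneous delta-band up/down alternation driven by the
    # s_time trace; "latched": the transition lists taken literally, under
    # which a unit that has once crossed gamma_up can never come back down.
    nacc_state_mode: str = "relaxation"

    # VP shunting polarity.  False (default): accumbens inhibition reaches
    # VP only when PPTN excitation is absent, the form consistent with the
    # narrated omission behavior.  True: the literal printed form, where the
    # inhibition is gated *on* by PPTN excitation.
    vp_gating_printed: bool = False
    vp_gamma: float = 0.1

    # VTA input filtering
    vta_tau_mod: float = 300.0
    vta_tau_inh: float = 30.0
    vta_k: float = 1.0
    vta_gamma: float = 0.1

    # Phasic transform shape per filter group: the direct form (x - k*xbar)+
    # responds instantly at input onset; the cascade form (xbar - k*xbar2)+
    # produces a smooth bump peaking near t = tau.
    bla_phasic_cascade: bool = False
    pptn_phasic_cascade: bool = False
    vta_phasic_cascade: bool = False
    da_phasic_cascade: bool = False

    projections: list[ProjectionRow] = field(default_factory=default_projection_rows)

    def __post_init__(self) -> None:
        # YAML round-trips turn tuples into lists; normalize
        self.f_range = tuple(float(x) for x in self.f_range)
        self.phase_range = tuple(float(x) for x in self.phase_range)
        keys = [(r.pre, r.post) for r in self.projections]
        if len(keys) != len(set(keys)):
            dup = sorted({k for k in keys if keys.count(k) > 1})
            raise ValueError(f"duplicate projection rows: {dup}")
        missing = REQUIRED_PROJECTIONS - set(keys)
        extra = set(keys) - REQUIRED_PROJECTIONS
        if missing or extra:
            msg = []
            if missing:
                msg.append("missing projection rows: "
                           + ", ".join(f"{a}->{b}" for a, b in sorted(missing)))
            if extra:
                msg.append("unknown projection rows: "
                           + ", ".join(f"{a}->{b}" for a, b in sorted(extra)))
            raise ValueError("; ".join(msg))
        if self.n_it != self.n_banks * 3:
            raise ValueError("IT must hold one 3-unit cluster per CS")
        if self.nacc_state_mode not in ("relaxation", "latched"):
            raise ValueError("nacc_state_mode must be 'relaxation' or 'latched'")

    def row(self, pre: str, post: str) -> ProjectionRow:
        for r in self.projections:
            if (r.pre, r.post) == (pre, post):
                return r
        raise KeyError(f"no projection row {pre}->{post}")

    @property
    def n_pfc(self) -> int:
        return self.n_banks * self.bank_size


class Network:
    """Mutable simulation state of the full circuit.

    Build with :func:`build_network`; advance with :meth:`step`.  All
    single-unit populations (CE, VP, LHb, RMTg, VTA) are held as scalars.
    """

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng
        self.t = 0.0  # simulated time, ms

        n_bla, n_nacc, n_pfc = cfg.n_bla, cfg.n_nacc, cfg.n_pfc

        # --- membrane potentials -----------------------------------------
        self.m_it = np.zeros(cfg.n_it)
        self.m_lh = np.zeros(cfg.n_lh)
        self.m_bla = np.zeros(n_bla)
        self.m_ce = 0.0
        self.m_pptn = np.zeros(cfg.n_pptn)
        self.m_pfc = np.zeros(n_pfc)
        self.m_nacc = np.zeros(n_nacc)
        self.m_vp = 0.0
        self.m_lhb = 0.0
        self.m_rmtg = 0.0
        self.m_vta = 0.0

        # --- firing rates -------------------------------------------------
        self.r_it = np.zeros(cfg.n_it)
        self.r_lh = np.zeros(cfg.n_lh)
        self.r_bla = np.zeros(n_bla)
        self.r_ce = 0.0
        self.r_pptn = np.zeros(cfg.n_pptn)
        self.r_pfc = np.zeros(n_pfc)
        self.r_nacc = np.zeros(n_nacc)
        self.r_vp = 0.0
        self.r_lhb = 0.0
        self.r_rmtg = 0.0
        self.r_vta = 0.0

        # --- phasic filter states ------------------------------------------
        self.phi_bla_exc = PhasicFilter(cfg.bla_tau_exc, cfg.bla_k, np.zeros(n_bla),
                                        cfg.bla_phasic_cascade, np.zeros(n_bla))
        self.phi_bla_mod = PhasicFilter(cfg.bla_tau_mod, cfg.bla_k, np.zeros(n_bla),
                                        cfg.bla_phasic_cascade, np.zeros(n_bla))
        self.phi_pptn = PhasicFilter(cfg.pptn_tau_exc, cfg.pptn_k, np.zeros(cfg.n_pptn),
                                     cfg.pptn_phasic_cascade, np.zeros(cfg.n_pptn))
        self.phi_vta_mod = PhasicFilter(cfg.vta_tau_mod, cfg.vta_k, 0.0,
                                        cfg.vta_phasic_cascade, 0.0)
        self.phi_vta_inh = PhasicFilter(cfg.vta_tau_inh, cfg.vta_k, 0.0,
                                        cfg.vta_phasic_cascade, 0.0)

        # --- weights --------------------------------------------------------
        row = cfg.row
        r_lh_bla = row("LH", "BLA")
        lo = r_lh_bla.weight - r_lh_bla.weight_spread
        hi = r_lh_bla.weight + r_lh_bla.weight_spread
        self.W_lh_bla = rng.uniform(lo, hi, size=(n_bla, cfg.n_lh))
        self.W_it_bla = np.full((n_bla, cfg.n_it), row("IT", "BLA").weight)
        self.W_bla_bla = np.full((n_bla, n_bla), row("BLA", "BLA").weight)
        np.fill_diagonal(self.W_bla_bla, 0.0)
        self.W_pfc_nacc = np.full((n_nacc, n_pfc), row("vmPFC", "NAcc").weight)
        self.W_nacc_nacc = np.full((n_nacc, n_nacc), row("NAcc", "NAcc").weight)
        np.fill_diagonal(self.W_nacc_nacc, 0.0)
        self.w_nacc_vp = np.full(n_nacc, row("NAcc", "VP").weight)
        self.w_nacc_vta = np.full(n_nacc, row("NAcc", "VTA").weight)

        self.w_vis_it = row("VIS", "IT").weight
        self.w_gus_lh = row("GUS", "LH").weight
        self.w_bla_ce = row("BLA", "CE").weight
        self.w_ce_pptn = row("CE", "PPTN").weight
        self.w_lh_pptn = row("LH", "PPTN").weight
        self.w_pptn_pptn = row("PPTN", "PPTN").weight
        self.w_pptn_vta = row("PPTN", "VTA").weight
        self.w_pptn_vp = row("PPTN", "VP").weight
        self.w_vp_rmtg = row("VP", "RMTg").weight
        self.w_vp_lhb = row("VP", "LHb").weight
        self.w_lhb_rmtg = row("LHb", "RMTg").weight
        self.w_rmtg_vta = row("RMTg", "VTA").weight
        self.w_it_pfc = row("IT", "vmPFC").weight
        self.w_bla_nacc = row("BLA", "NAcc").weight
        self.w_vta_nacc = row("VTA", "NAcc").weight
        self.w_vta_bla = row("VTA", "BLA").weight

        # --- plasticity ----------------------------------------------------
        self.p_lh_bla = r_lh_bla.params()
        self.p_it_bla = row("IT", "BLA").params()
        self.p_bla_bla = row("BLA", "BLA").params()
        self.p_pfc_nacc = row("vmPFC", "NAcc").params()
        self.p_nacc_nacc = row("NAcc", "NAcc").params()
        self.p_nacc_vp = row("NAcc", "VP").params()
        self.p_nacc_vta = row("NAcc", "VTA").params()
        self.reg_lh_bla = RegularizerState.zeros(n_bla)
        self.reg_pfc_nacc = RegularizerState.zeros(n_nacc)
        # phasic filters on the dopaminergic input of the modulated rules
        self.phi_da_bla = PhasicFilter(self.p_lh_bla.tau_dopa,
                                       self.p_lh_bla.k_dopa, 0.0,
                                       cfg.da_phasic_cascade, 0.0)
        self.phi_da_nacc = PhasicFilter(self.p_pfc_nacc.tau_dopa,
                                        self.p_pfc_nacc.k_dopa, 0.0,
                                        cfg.da_phasic_cascade, 0.0)

        # --- vmPFC oscillator banks ----------------------------------------
        self.osc_freq = rng.uniform(*cfg.f_range, size=cfg.n_pfc)     # Hz
        self.osc_phase = rng.uniform(*cfg.phase_range, size=cfg.n_pfc)  # rad
        self.bank_active = np.zeros(cfg.n_banks, dtype=bool)
        self.bank_t0 = np.zeros(cfg.n_banks)

        # --- NAcc up/down state machine ------------------------------------
        # s_time starts spread over its post-burn-in range so spontaneous
        # delta-band alternation is desynchronized across units.
        self.nacc_up = np.zeros(n_nacc, dtype=bool)
        self.s = np.full(n_nacc, cfg.s_down)
        self.s_time = rng.uniform(cfg.s_down, cfg.s_up, size=n_nacc)

        # IT cluster membership: cluster c = units [3c, 3c+3)
        self._clusters = [slice(3 * c, 3 * c + 3) for c in range(cfg.n_banks)]
        self._banks = [slice(cfg.bank_size * b, cfg.bank_size * (b + 1))
                       for b in range(cfg.n_banks)]
        self._n_noise = (cfg.n_it + cfg.n_lh + n_bla + 1 + cfg.n_pptn
                         + n_nacc + 4)
        self._post_buf = np.empty(1)
        self._w_nacc_vp_2d = self.w_nacc_vp[None, :]
        self._w_nacc_vta_2d = self.w_nacc_vta[None, :]

    # ------------------------------------------------------------------
    def set_conditioning_phase(self, conditioning: bool,
                               slowdown: float = 100.0) -> None:
        """Switch the LH->BLA learning-rate divisor at the phase boundary.

        During conditioning the formation of reward representations in the
        amygdala is a far slower process than the conditioning session, so
        the divisor rises by two orders of magnitude relative to its
        configured sensitization value.
        """
        base = self.cfg.row("LH", "BLA").eps
        self.p_lh_bla.eps = base * slowdown if conditioning else base

    def disconnect(self, pre: str, post: str) -> None:
        """Zero the weight of a projection (virtual lesion)."""
        attr = {
            ("CE", "PPTN"): "w_ce_pptn",
            ("LHb", "RMTg"): "w_lhb_rmtg",
            ("RMTg", "VTA"): "w_rmtg_vta",
            ("VP", "LHb"): "w_vp_lhb",
            ("PPTN", "VTA"): "w_pptn_vta",
            ("BLA", "NAcc"): "w_bla_nacc",
        }.get((pre, post))
        if attr is not None:
            setattr(self, attr, 0.0)
        elif (pre, post) == ("NAcc", "VTA"):
            self.w_nacc_vta[:] = 0.0
        elif (pre, post) == ("NAcc", "VP"):
            self.w_nacc_vp[:] = 0.0
        elif (pre, post) == ("vmPFC", "NAcc"):
            self.W_pfc_nacc[:] = 0.0
        else:
            raise KeyError(f"no lesionable projection {pre}->{post}")

    # ------------------------------------------------------------------
    def step(self, cs_vec, us_vec, magnitude: float,
             learning_on: bool = False, noise: np.ndarray | None = None) -> None:
        """One synchronous 1-ms update of the whole network.

        ``noise`` optionally supplies this step's pre-drawn noise vector
        (one value per noisy unit); when omitted it is drawn from the
        network's generator.
        """
        cfg = self.cfg
        dt = cfg.dt

        # ---- 1. typed input sums from rates at time t ---------------------
        g_it = np.repeat(np.asarray(cs_vec, dtype=float), 3) * self.w_vis_it
        g_lh = np.asarray(us_vec, dtype=float) * magnitude * self.w_gus_lh

        g_bla_exc = self.W_lh_bla @ self.r_lh
        g_bla_mod = self.W_it_bla @ self.r_it
        g_bla_inh = self.W_bla_bla @ self.r_bla
        g_bla_dopa = self.w_vta_bla * self.r_vta          # scalar, all units

        g_ce = self.w_bla_ce * self.r_bla.sum()

        lh_sum = self.r_lh.sum()
        g_pptn_exc = np.array([self.w_lh_pptn * lh_sum,
                               self.w_ce_pptn * self.r_ce])
        g_pptn_inh = self.w_pptn_pptn * self.r_pptn[::-1]

        bank_input = self.w_it_pfc * self.r_it.reshape(cfg.n_banks, 3).sum(axis=1)

        g_nacc_exc = self.w_bla_nacc * self.r_bla
        g_nacc_mod = self.W_pfc_nacc @ self.r_pfc
        g_nacc_inh = self.W_nacc_nacc @ self.r_nacc
        g_nacc_dopa = self.w_vta_nacc * self.r_vta

        pptn_sum = self.r_pptn.sum()
        g_vp_exc = self.w_pptn_vp * pptn_sum
        g_vp_inh = self.w_nacc_vp @ self.r_nacc
        g_lhb_inh = self.w_vp_lhb * self.r_vp
        g_rmtg_exc = self.w_lhb_rmtg * self.r_lhb
        g_rmtg_inh = self.w_vp_rmtg * self.r_vp
        g_vta_exc = self.w_pptn_vta * pptn_sum
        g_vta_mod = self.w_nacc_vta @ self.r_nacc
        g_vta_inh = self.w_rmtg_vta * self.r_rmtg

        # ---- 2. phasic filters -------------------------------------------
        y_bla_exc = self.phi_bla_exc.step(g_bla_exc, dt)
        y_bla_mod = self.phi_bla_mod.step(g_bla_mod, dt)
        y_pptn = self.phi_pptn.step(g_pptn_exc, dt)
        y_vta_mod = self.phi_vta_mod.step(g_vta_mod, dt)
        y_vta_inh = self.phi_vta_inh.step(g_vta_inh, dt)
        da_bla = self.phi_da_bla.step(g_bla_dopa, dt)
        da_nacc = self.phi_da_nacc.step(g_nacc_dopa, dt)

        # ---- 3. membrane updates ------------------------------------------
        eta = noise
        if eta is None:
            eta = self.rng.uniform(-cfg.noise_amp, cfg.noise_amp, self._n_noise)
        o = 0
        n = cfg.n_it
        self.m_it += (dt / cfg.tau_m) * (g_it + eta[o:o + n] - self.m_it)
        o += n
        n = cfg.n_lh
        self.m_lh += (dt / cfg.tau_m) * (g_lh + eta[o:o + n] - self.m_lh)
        o += n
        n = cfg.n_bla
        bla_drive = (y_bla_exc
                     + (1.0 - threshold_gate(g_bla_exc, cfg.bla_gamma)) * y_bla_mod
                     - g_bla_inh)
        self.m_bla += (dt / cfg.tau_m) * (bla_drive + eta[o:o + n] - self.m_bla)
        o += n
        self.m_ce += (dt / cfg.tau_m) * (g_ce + eta[o] - self.m_ce)
        o += 1
        n = cfg.n_pptn
        self.m_pptn += (dt / cfg.tau_m) * (y_pptn - g_pptn_inh
                                           + eta[o:o + n] - self.m_pptn)
        o += n
        n = cfg.n_nacc
        nacc_drive = (g_nacc_exc + g_nacc_mod - g_nacc_inh + g_nacc_dopa
                      + self.s)
        self.m_nacc += (dt / cfg.tau_m) * (nacc_drive + eta[o:o + n]
                                           - self.m_nacc)
        o += n
        gate_vp = threshold_gate(g_vp_exc, cfg.vp_gamma)
        inh_gate = gate_vp if cfg.vp_gating_printed else 1.0 - gate_vp
        self.m_vp += (dt / cfg.tau_m) * (g_vp_exc - inh_gate * g_vp_inh
                                         + cfg.vp_baseline + eta[o] - self.m_vp)
        o += 1
        self.m_lhb += (dt / cfg.tau_m) * (-g_lhb_inh + cfg.lhb_baseline
                                          + eta[o] - self.m_lhb)
        o += 1
        self.m_rmtg += (dt / cfg.tau_m) * (g_rmtg_exc - g_rmtg_inh
                                           + eta[o] - self.m_rmtg)
        o += 1
        vta_drive = (g_vta_exc * (1.0 - y_vta_mod)
                     - (1.0 - threshold_gate(g_vta_exc, cfg.vta_gamma)) * y_vta_inh
                     + cfg.vta_baseline)
        self.m_vta += (dt / cfg.tau_m) * (vta_drive + eta[o] - self.m_vta)

        # vmPFC oscillators: synchronize at cue onset, free-run while the
        # cue input stays above T_stop, silent otherwise.  No noise term.
        t_next = self.t + dt
        for b in range(cfg.n_banks):
            if not self.bank_active[b]:
                if bank_input[b] >= cfg.t_start:
                    self.bank_active[b] = True
                    self.bank_t0[b] = t_next
            elif bank_input[b] < cfg.t_stop:
                self.bank_active[b] = False
                self.m_pfc[self._banks[b]] = 0.0
        if self.bank_active.any():
            for b in np.flatnonzero(self.bank_active):
                sl = self._banks[b]
                phase = (2.0 * np.pi * self.osc_freq[sl]
                         * (t_next - self.bank_t0[b]) / 1000.0
                         + self.osc_phase[sl])
                target = 0.5 * (1.0 + np.sin(phase))
                self.m_pfc[sl] += (dt / cfg.pfc_tau) * (target - self.m_pfc[sl])

        # ---- 4. rates ------------------------------------------------------
        np.maximum(self.m_it, 0.0, out=self.r_it)
        np.maximum(self.m_lh, 0.0, out=self.r_lh)
        np.maximum(self.m_bla, 0.0, out=self.r_bla)
        self.r_ce = max(self.m_ce, 0.0)
        np.maximum(self.m_pptn, 0.0, out=self.r_pptn)
        np.maximum(self.m_pfc, 0.0, out=self.r_pfc)
        np.clip(self.m_nacc, 0.0, cfg.nacc_rate_max, out=self.r_nacc)
        self.r_vp = max(self.m_vp, 0.0)
        self.r_lhb = max(self.m_lhb, 0.0)
        self.r_rmtg = max(self.m_rmtg, 0.0)
        self.r_vta = max(self.m_vta, 0.0)

        # ---- 5. NAcc up/down transitions ----------------------------------
        self._nacc_transitions(g_nacc_exc + g_nacc_mod)
        self.s_time += (dt / cfg.tau_s) * (self.s - self.s_time)

        # ---- 6. plasticity -------------------------------------------------
        if learning_on:
            self._learn(da_bla, da_nacc, g_bla_dopa,
                        g_bla_exc, g_bla_mod, dt)

        self.t = t_next

    # ------------------------------------------------------------------
    def _nacc_transitions(self, glut: np.ndarray) -> None:
        """Up/down state switches of the accumbens units.

        An up transition is forced by a dopamine burst (VTA rate at or above
        gamma_dopa) or by massive glutamatergic drive (above gamma_glut).
        In "relaxation" mode the s_time trace otherwise paces spontaneous
        delta-band alternation: down once s_time rises past gamma_up, up
        once it falls past gamma_down.  In "latched" mode the transition
        lists are evaluated literally every step.
        """
        cfg = self.cfg
        da_on = self.r_vta >= cfg.gamma_dopa
        forced_up = da_on | (glut >= cfg.gamma_glut)
        if cfg.nacc_state_mode == "latched":
            up_cond = forced_up | (self.s_time >= cfg.gamma_up)
            down_cond = (~da_on) & (self.s_time < cfg.gamma_down)
            self.nacc_up = np.where(up_cond, True,
                                    np.where(down_cond, False, self.nacc_up))
        else:
            self.nacc_up[forced_up] = True
            free = ~forced_up
            self.nacc_up[free & (self.s_time >= cfg.gamma_up)] = False
            self.nacc_up[free & (self.s_time <= cfg.gamma_down)] = True
        self.s = np.where(self.nacc_up, cfg.s_up, cfg.s_down)

    # ------------------------------------------------------------------
    def _learn(self, da_bla: float, da_nacc: float, g_bla_dopa,
               g_bla_exc, g_bla_mod, dt: float) -> None:
        r_bla, r_nacc, r_pfc, r_lh = self.r_bla, self.r_nacc, self.r_pfc, self.r_lh
        mean_lh = r_lh.mean()
        mean_bla = r_bla.mean()
        mean_nacc = r_nacc.mean()
        # The oscillator population mean is taken over the synchronized
        # assembly (the active banks): silent banks are shut off, and
        # including them would bias every active unit's deviation positive,
        # producing a DC-loaded (untuned) corticostriatal kernel.
        n_active = int(self.bank_active.sum())
        if n_active:
            mean_pfc = r_pfc.sum() / (n_active * self.cfg.bank_size)
        else:
            mean_pfc = 0.0

        regularizer_step(self.reg_lh_bla, r_bla, self.p_lh_bla, dt)
        if da_bla != 0.0 or self.reg_lh_bla.alpha.any():
            da_covariance_update(self.W_lh_bla, r_lh, r_bla, mean_lh,
                                 mean_bla, da_bla, self.reg_lh_bla,
                                 self.p_lh_bla, dt)
        modulated_transfer_update(self.W_it_bla, self.r_it, r_bla,
                                  self.r_it.mean(), mean_bla,
                                  g_bla_dopa, g_bla_exc, g_bla_mod,
                                  self.p_it_bla, dt)
        covariance_update(self.W_bla_bla, r_bla, r_bla, mean_bla, mean_bla,
                          self.p_bla_bla, dt)
        np.fill_diagonal(self.W_bla_bla, 0.0)

        regularizer_step(self.reg_pfc_nacc, r_nacc, self.p_pfc_nacc, dt)
        if da_nacc != 0.0 or self.reg_pfc_nacc.alpha.any():
            da_covariance_update(self.W_pfc_nacc, r_pfc, r_nacc, mean_pfc,
                                 mean_nacc, da_nacc, self.reg_pfc_nacc,
                                 self.p_pfc_nacc, dt)
        covariance_update(self.W_nacc_nacc, r_nacc, r_nacc, mean_nacc,
                          mean_nacc, self.p_nacc_nacc, dt)
        np.fill_diagonal(self.W_nacc_nacc, 0.0)

        if self.r_vp > self.p_nacc_vp.theta_post:
            self._post_buf[0] = self.r_vp
            hebbian_threshold_update(self._w_nacc_vp_2d, r_nacc,
                                     self._post_buf, self.p_nacc_vp, dt)
        if self.r_vta > self.p_nacc_vta.theta_post:
            self._post_buf[0] = self.r_vta
            hebbian_threshold_update(self._w_nacc_vta_2d, r_nacc,
                                     self._post_buf, self.p_nacc_vta, dt)

    # ------------------------------------------------------------------
    def weights_snapshot(self) -> dict[str, np.ndarray]:
        """Copies of all learnable weight matrices (for recording/tests)."""
        return {
            "LH->BLA": self.W_lh_bla.copy(),
            "IT->BLA": self.W_it_bla.copy(),
            "BLA->BLA": self.W_bla_bla.copy(),
            "vmPFC->NAcc": self.W_pfc_nacc.copy(),
            "NAcc->NAcc": self.W_nacc_nacc.copy(),
            "NAcc->VP": self.w_nacc_vp.copy(),
            "NAcc->VTA": self.w_nacc_vta.copy(),
        }


def build_network(cfg: NetworkConfig | None = None,
                  rng: np.random.Generator | int | None = None) -> Network:
    """Instantiate the full circuit from a validated configuration.

    ``rng`` may be a Generator, an integer seed, or None (non-reproducible).
    The same seed yields identical initial weights, oscillator parameters
    and noise streams.
    """
    if cfg is None:
        cfg = NetworkConfig()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return Network(cfg, rng)
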