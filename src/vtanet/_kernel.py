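"""Accelerated trial execution.

The readable reference dynamics live in :meth:`vtanet.network.Network.step`.
This module reimplements the identical update (same equations, same
synchronous ordering, same noise stream) as a single numba-compiled loop
over a whole trial, which is what the experiment schedules use by default.
A test drives both implementations with the same pre-drawn noise and
checks that the trajectories agree.

When numba is unavailable the schedules silently fall back to the numpy
implementation.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f
        return deco if not (args and callable(args[0])) else args[0]


# ---- scalar-state vector layout -------------------------------------------
SC_M_CE, SC_R_CE = 0, 1
SC_M_VP, SC_R_VP = 2, 3
SC_M_LHB, SC_R_LHB = 4, 5
SC_M_RMTG, SC_R_RMTG = 6, 7
SC_M_VTA, SC_R_VTA = 8, 9
SC_XB_VTA_MOD, SC_XB_VTA_INH = 10, 11
SC_XB_DA_BLA, SC_XB_DA_NACC = 12, 13
SC_XB2_VTA_MOD, SC_XB2_VTA_INH = 14, 15
SC_XB2_DA_BLA, SC_XB2_DA_NACC = 16, 17
SC_T = 18
N_SC = 19

# ---- parameter vector layout ----------------------------------------------
(P_DT, P_TAU_M, P_BLA_TAU_EXC, P_BLA_TAU_MOD, P_BLA_K, P_BLA_GAMMA,
 P_PPTN_TAU, P_PPTN_K,
 P_VTA_TAU_MOD, P_VTA_TAU_INH, P_VTA_K, P_VTA_GAMMA, P_VTA_B,
 P_VP_B, P_VP_GAMMA, P_VP_PRINTED, P_LHB_B,
 P_PFC_TAU, P_TSTART, P_TSTOP,
 P_S_DOWN, P_S_UP, P_TAU_S, P_G_DOPA, P_G_GLUT, P_G_UP, P_G_DOWN,
 P_NACC_RMAX, P_RELAX,
 P_EPS_LH_BLA, P_K_LH_BLA, P_TA_LH_BLA, P_RMAX_LH_BLA,
 P_WMIN_LH_BLA, P_WMAX_LH_BLA, P_TD_LH_BLA, P_KD_LH_BLA,
 P_EPS_IT_BLA, P_GDOPA_IT_BLA,
 P_EPS_BLA_BLA, P_WMIN_BLA_BLA, P_WMAX_BLA_BLA,
 P_EPS_PFC_NACC, P_K_PFC_NACC, P_TA_PFC_NACC, P_RMAX_PFC_NACC,
 P_WMIN_PFC_NACC, P_WMAX_PFC_NACC, P_TD_PFC_NACC, P_KD_PFC_NACC,
 P_EPS_NACC_NACC, P_WMIN_NACC_NACC, P_WMAX_NACC_NACC,
 P_EPS_NACC_VP, P_THPOST_NACC_VP, P_WMIN_NACC_VP, P_WMAX_NACC_VP,
 P_EPS_NACC_VTA, P_THPOST_NACC_VTA, P_WMIN_NACC_VTA, P_WMAX_NACC_VTA,
 P_BLA_CASCADE, P_PPTN_CASCADE, P_VTA_CASCADE, P_DA_CASCADE,
 P_THDA_LH_BLA, P_THDA_PFC_NACC,
 ) = range(67)
N_P = 67

# ---- fixed-weight vector layout -------------------------------------------
(FW_VIS_IT, FW_GUS_LH, FW_BLA_CE, FW_CE_PPTN, FW_LH_PPTN, FW_PPTN_PPTN,
 FW_PPTN_VTA, FW_PPTN_VP, FW_VP_RMTG, FW_VP_LHB, FW_LHB_RMTG, FW_RMTG_VTA,
 FW_IT_PFC, FW_BLA_NACC, FW_VTA_NACC, FW_VTA_BLA) = range(16)
N_FW = 16


def pack_params(net) -> tuple[np.ndarray, np.ndarray]:
    cfg = net.cfg
    P = np.zeros(N_P)
    P[P_DT] = cfg.dt
    P[P_TAU_M] = cfg.tau_m
    P[P_BLA_TAU_EXC] = cfg.bla_tau_exc
    P[P_BLA_TAU_MOD] = cfg.bla_tau_mod
    P[P_BLA_K] = cfg.bla_k
    P[P_BLA_GAMMA] = cfg.bla_gamma
    P[P_PPTN_TAU] = cfg.pptn_tau_exc
    P[P_PPTN_K] = cfg.pptn_k
    P[P_VTA_TAU_MOD] = cfg.vta_tau_mod
    P[P_VTA_TAU_INH] = cfg.vta_tau_inh
    P[P_VTA_K] = cfg.vta_k
    P[P_VTA_GAMMA] = cfg.vta_gamma
    P[P_VTA_B] = cfg.vta_baseline
    P[P_VP_B] = cfg.vp_baseline
    P[P_VP_GAMMA] = cfg.vp_gamma
    P[P_VP_PRINTED] = 1.0 if cfg.vp_gating_printed else 0.0
    P[P_LHB_B] = cfg.lhb_baseline
    P[P_PFC_TAU] = cfg.pfc_tau
    P[P_TSTART] = cfg.t_start
    P[P_TSTOP] = cfg.t_stop
    P[P_S_DOWN] = cfg.s_down
    P[P_S_UP] = cfg.s_up
    P[P_TAU_S] = cfg.tau_s
    P[P_G_DOPA] = cfg.gamma_dopa
    P[P_G_GLUT] = cfg.gamma_glut
    P[P_G_UP] = cfg.gamma_up
    P[P_G_DOWN] = cfg.gamma_down
    P[P_NACC_RMAX] = cfg.nacc_rate_max
    P[P_RELAX] = 1.0 if cfg.nacc_state_mode == "relaxation" else 0.0

    P[P_EPS_LH_BLA] = net.p_lh_bla.eps
    P[P_K_LH_BLA] = net.p_lh_bla.K
    P[P_TA_LH_BLA] = net.p_lh_bla.tau_alpha
    P[P_RMAX_LH_BLA] = net.p_lh_bla.r_max
    P[P_WMIN_LH_BLA] = net.p_lh_bla.w_min
    P[P_WMAX_LH_BLA] = net.p_lh_bla.w_max
    P[P_TD_LH_BLA] = net.p_lh_bla.tau_dopa
    P[P_KD_LH_BLA] = net.p_lh_bla.k_dopa
    P[P_EPS_IT_BLA] = net.p_it_bla.eps
    P[P_GDOPA_IT_BLA] = net.p_it_bla.gamma_dopa
    P[P_EPS_BLA_BLA] = net.p_bla_bla.eps
    P[P_WMIN_BLA_BLA] = net.p_bla_bla.w_min
    P[P_WMAX_BLA_BLA] = net.p_bla_bla.w_max
    P[P_EPS_PFC_NACC] = net.p_pfc_nacc.eps
    P[P_K_PFC_NACC] = net.p_pfc_nacc.K
    P[P_TA_PFC_NACC] = net.p_pfc_nacc.tau_alpha
    P[P_RMAX_PFC_NACC] = net.p_pfc_nacc.r_max
    P[P_WMIN_PFC_NACC] = net.p_pfc_nacc.w_min
    P[P_WMAX_PFC_NACC] = net.p_pfc_nacc.w_max
    P[P_TD_PFC_NACC] = net.p_pfc_nacc.tau_dopa
    P[P_KD_PFC_NACC] = net.p_pfc_nacc.k_dopa
    P[P_EPS_NACC_NACC] = net.p_nacc_nacc.eps
    P[P_WMIN_NACC_NACC] = net.p_nacc_nacc.w_min
    P[P_WMAX_NACC_NACC] = net.p_nacc_nacc.w_max
    P[P_EPS_NACC_VP] = net.p_nacc_vp.eps
    P[P_THPOST_NACC_VP] = net.p_nacc_vp.theta_post
    P[P_WMIN_NACC_VP] = net.p_nacc_vp.w_min
    P[P_WMAX_NACC_VP] = net.p_nacc_vp.w_max
    P[P_EPS_NACC_VTA] = net.p_nacc_vta.eps
    P[P_THPOST_NACC_VTA] = net.p_nacc_vta.theta_post
    P[P_WMIN_NACC_VTA] = net.p_nacc_vta.w_min
    P[P_WMAX_NACC_VTA] = net.p_nacc_vta.w_max
    P[P_BLA_CASCADE] = 1.0 if cfg.bla_phasic_cascade else 0.0
    P[P_PPTN_CASCADE] = 1.0 if cfg.pptn_phasic_cascade else 0.0
    P[P_VTA_CASCADE] = 1.0 if cfg.vta_phasic_cascade else 0.0
    P[P_DA_CASCADE] = 1.0 if cfg.da_phasic_cascade else 0.0
    P[P_THDA_LH_BLA] = net.p_lh_bla.theta_dopa
    P[P_THDA_PFC_NACC] = net.p_pfc_nacc.theta_dopa

    FW = np.zeros(N_FW)
    FW[FW_VIS_IT] = net.w_vis_it
    FW[FW_GUS_LH] = net.w_gus_lh
    FW[FW_BLA_CE] = net.w_bla_ce
    FW[FW_CE_PPTN] = net.w_ce_pptn
    FW[FW_LH_PPTN] = net.w_lh_pptn
    FW[FW_PPTN_PPTN] = net.w_pptn_pptn
    FW[FW_PPTN_VTA] = net.w_pptn_vta
    FW[FW_PPTN_VP] = net.w_pptn_vp
    FW[FW_VP_RMTG] = net.w_vp_rmtg
    FW[FW_VP_LHB] = net.w_vp_lhb
    FW[FW_LHB_RMTG] = net.w_lhb_rmtg
    FW[FW_RMTG_VTA] = net.w_rmtg_vta
    FW[FW_IT_PFC] = net.w_it_pfc
    FW[FW_BLA_NACC] = net.w_bla_nacc
    FW[FW_VTA_NACC] = net.w_vta_nacc
    FW[FW_VTA_BLA] = net.w_vta_bla
    return P, FW


def pack_scalars(net) -> np.ndarray:
    sc = np.zeros(N_SC)
    sc[SC_M_CE], sc[SC_R_CE] = net.m_ce, net.r_ce
    sc[SC_M_VP], sc[SC_R_VP] = net.m_vp, net.r_vp
    sc[SC_M_LHB], sc[SC_R_LHB] = net.m_lhb, net.r_lhb
    sc[SC_M_RMTG], sc[SC_R_RMTG] = net.m_rmtg, net.r_rmtg
    sc[SC_M_VTA], sc[SC_R_VTA] = net.m_vta, net.r_vta
    sc[SC_XB_VTA_MOD] = net.phi_vta_mod.xbar
    sc[SC_XB_VTA_INH] = net.phi_vta_inh.xbar
    sc[SC_XB_DA_BLA] = net.phi_da_bla.xbar
    sc[SC_XB_DA_NACC] = net.phi_da_nacc.xbar
    sc[SC_XB2_VTA_MOD] = net.phi_vta_mod.xbar2
    sc[SC_XB2_VTA_INH] = net.phi_vta_inh.xbar2
    sc[SC_XB2_DA_BLA] = net.phi_da_bla.xbar2
    sc[SC_XB2_DA_NACC] = net.phi_da_nacc.xbar2
    sc[SC_T] = net.t
    return sc


def unpack_scalars(net, sc: np.ndarray) -> None:
    net.m_ce, net.r_ce = sc[SC_M_CE], sc[SC_R_CE]
    net.m_vp, net.r_vp = sc[SC_M_VP], sc[SC_R_VP]
    net.m_lhb, net.r_lhb = sc[SC_M_LHB], sc[SC_R_LHB]
    net.m_rmtg, net.r_rmtg = sc[SC_M_RMTG], sc[SC_R_RMTG]
    net.m_vta, net.r_vta = sc[SC_M_VTA], sc[SC_R_VTA]
    net.phi_vta_mod.xbar = sc[SC_XB_VTA_MOD]
    net.phi_vta_inh.xbar = sc[SC_XB_VTA_INH]
    net.phi_da_bla.xbar = sc[SC_XB_DA_BLA]
    net.phi_da_nacc.xbar = sc[SC_XB_DA_NACC]
    net.phi_vta_mod.xbar2 = sc[SC_XB2_VTA_MOD]
    net.phi_vta_inh.xbar2 = sc[SC_XB2_VTA_INH]
    net.phi_da_bla.xbar2 = sc[SC_XB2_DA_BLA]
    net.phi_da_nacc.xbar2 = sc[SC_XB2_DA_NACC]
    net.t = sc[SC_T]


@njit(cache=True)
def _run(cs, us, mag, learning_on, noise, sc, P, FW,
         m_it, r_it, m_lh, r_lh, m_bla, r_bla, m_pptn, r_pptn,
         m_pfc, r_pfc, m_nacc, r_nacc,
         xb_bla_exc, xb_bla_mod, xb_pptn,
         xb2_bla_exc, xb2_bla_mod, xb2_pptn,
         osc_freq, osc_phase, bank_active, bank_t0,
         nacc_up, s, s_time, alpha_bla, alpha_nacc,
         W_lh_bla, W_it_bla, W_bla_bla, W_pfc_nacc, W_nacc_nacc,
         w_nacc_vp, w_nacc_vta,
         rec_vta, rec_bla, rec_nacc, rec_nacc_m, rec_s, rec_st,
         rec_ce, rec_pptn, rec_vp, rec_lhb, rec_rmtg,
         rec_it, rec_lh, rec_pfc):
    n_steps = cs.shape[0]
    n_it = m_it.shape[0]
    n_lh = m_lh.shape[0]
    n_bla = m_bla.shape[0]
    n_nacc = m_nacc.shape[0]
    n_pfc = m_pfc.shape[0]
    n_banks = bank_active.shape[0]
    bank_size = n_pfc // n_banks

    dt = P[P_DT]
    tau_m = P[P_TAU_M]
    lam = dt / tau_m

    g_bla_exc = np.empty(n_bla)
    g_bla_mod = np.empty(n_bla)
    g_bla_inh = np.empty(n_bla)
    g_nacc_mod = np.empty(n_nacc)
    g_nacc_inh = np.empty(n_nacc)
    glut = np.empty(n_nacc)

    for it_step in range(n_steps):
        t = sc[SC_T]
        r_vta = sc[SC_R_VTA]
        r_ce = sc[SC_R_CE]
        r_vp = sc[SC_R_VP]
        r_lhb = sc[SC_R_LHB]
        r_rmtg = sc[SC_R_RMTG]

        # ---- 1. typed input sums -------------------------------------
        lh_sum = 0.0
        for i in range(n_lh):
            lh_sum += r_lh[i]
        bla_sum = 0.0
        for i in range(n_bla):
            bla_sum += r_bla[i]

        for j in range(n_bla):
            a = 0.0
            for i in range(n_lh):
                a += W_lh_bla[j, i] * r_lh[i]
            g_bla_exc[j] = a
            b = 0.0
            for i in range(n_it):
                b += W_it_bla[j, i] * r_it[i]
            g_bla_mod[j] = b
            c = 0.0
            for i in range(n_bla):
                c += W_bla_bla[j, i] * r_bla[i]
            g_bla_inh[j] = c
        g_bla_dopa = FW[FW_VTA_BLA] * r_vta

        g_ce = FW[FW_BLA_CE] * bla_sum
        g_pptn_exc0 = FW[FW_LH_PPTN] * lh_sum
        g_pptn_exc1 = FW[FW_CE_PPTN] * r_ce

        for j in range(n_nacc):
            a = 0.0
            for i in range(n_pfc):
                a += W_pfc_nacc[j, i] * r_pfc[i]
            g_nacc_mod[j] = a
            c = 0.0
            for i in range(n_nacc):
                c += W_nacc_nacc[j, i] * r_nacc[i]
            g_nacc_inh[j] = c
        g_nacc_dopa = FW[FW_VTA_NACC] * r_vta

        pptn_sum = r_pptn[0] + r_pptn[1]
        g_vp_exc = FW[FW_PPTN_VP] * pptn_sum
        g_vp_inh = 0.0
        for i in range(n_nacc):
            g_vp_inh += w_nacc_vp[i] * r_nacc[i]
        g_lhb_inh = FW[FW_VP_LHB] * r_vp
        g_rmtg_exc = FW[FW_LHB_RMTG] * r_lhb
        g_rmtg_inh = FW[FW_VP_RMTG] * r_vp
        g_vta_exc = FW[FW_PPTN_VTA] * pptn_sum
        g_vta_mod = 0.0
        for i in range(n_nacc):
            g_vta_mod += w_nacc_vta[i] * r_nacc[i]
        g_vta_inh = FW[FW_RMTG_VTA] * r_rmtg

        # ---- 2. phasic filters ---------------------------------------
        k_bla = P[P_BLA_K]
        bla_cas = P[P_BLA_CASCADE] != 0.0
        for j in range(n_bla):
            xb_bla_exc[j] += (dt / P[P_BLA_TAU_EXC]) * (g_bla_exc[j] - xb_bla_exc[j])
            xb_bla_mod[j] += (dt / P[P_BLA_TAU_MOD]) * (g_bla_mod[j] - xb_bla_mod[j])
            if bla_cas:
                xb2_bla_exc[j] += (dt / P[P_BLA_TAU_EXC]) * (xb_bla_exc[j] - xb2_bla_exc[j])
                xb2_bla_mod[j] += (dt / P[P_BLA_TAU_MOD]) * (xb_bla_mod[j] - xb2_bla_mod[j])
        xb_pptn[0] += (dt / P[P_PPTN_TAU]) * (g_pptn_exc0 - xb_pptn[0])
        xb_pptn[1] += (dt / P[P_PPTN_TAU]) * (g_pptn_exc1 - xb_pptn[1])
        if P[P_PPTN_CASCADE] != 0.0:
            xb2_pptn[0] += (dt / P[P_PPTN_TAU]) * (xb_pptn[0] - xb2_pptn[0])
            xb2_pptn[1] += (dt / P[P_PPTN_TAU]) * (xb_pptn[1] - xb2_pptn[1])
            y_pptn0 = max(xb_pptn[0] - P[P_PPTN_K] * xb2_pptn[0], 0.0)
            y_pptn1 = max(xb_pptn[1] - P[P_PPTN_K] * xb2_pptn[1], 0.0)
        else:
            y_pptn0 = max(g_pptn_exc0 - P[P_PPTN_K] * xb_pptn[0], 0.0)
            y_pptn1 = max(g_pptn_exc1 - P[P_PPTN_K] * xb_pptn[1], 0.0)
        sc[SC_XB_VTA_MOD] += (dt / P[P_VTA_TAU_MOD]) * (g_vta_mod - sc[SC_XB_VTA_MOD])
        sc[SC_XB_VTA_INH] += (dt / P[P_VTA_TAU_INH]) * (g_vta_inh - sc[SC_XB_VTA_INH])
        if P[P_VTA_CASCADE] != 0.0:
            sc[SC_XB2_VTA_MOD] += (dt / P[P_VTA_TAU_MOD]) * (sc[SC_XB_VTA_MOD] - sc[SC_XB2_VTA_MOD])
            sc[SC_XB2_VTA_INH] += (dt / P[P_VTA_TAU_INH]) * (sc[SC_XB_VTA_INH] - sc[SC_XB2_VTA_INH])
            y_vta_mod = max(sc[SC_XB_VTA_MOD] - P[P_VTA_K] * sc[SC_XB2_VTA_MOD], 0.0)
            y_vta_inh = max(sc[SC_XB_VTA_INH] - P[P_VTA_K] * sc[SC_XB2_VTA_INH], 0.0)
        else:
            y_vta_mod = max(g_vta_mod - P[P_VTA_K] * sc[SC_XB_VTA_MOD], 0.0)
            y_vta_inh = max(g_vta_inh - P[P_VTA_K] * sc[SC_XB_VTA_INH], 0.0)
        sc[SC_XB_DA_BLA] += (dt / P[P_TD_LH_BLA]) * (g_bla_dopa - sc[SC_XB_DA_BLA])
        sc[SC_XB_DA_NACC] += (dt / P[P_TD_PFC_NACC]) * (g_nacc_dopa - sc[SC_XB_DA_NACC])
        if P[P_DA_CASCADE] != 0.0:
            sc[SC_XB2_DA_BLA] += (dt / P[P_TD_LH_BLA]) * (sc[SC_XB_DA_BLA] - sc[SC_XB2_DA_BLA])
            sc[SC_XB2_DA_NACC] += (dt / P[P_TD_PFC_NACC]) * (sc[SC_XB_DA_NACC] - sc[SC_XB2_DA_NACC])
            da_bla = max(sc[SC_XB_DA_BLA] - P[P_KD_LH_BLA] * sc[SC_XB2_DA_BLA], 0.0)
            da_nacc = max(sc[SC_XB_DA_NACC] - P[P_KD_PFC_NACC] * sc[SC_XB2_DA_NACC], 0.0)
        else:
            da_bla = max(g_bla_dopa - P[P_KD_LH_BLA] * sc[SC_XB_DA_BLA], 0.0)
            da_nacc = max(g_nacc_dopa - P[P_KD_PFC_NACC] * sc[SC_XB_DA_NACC], 0.0)
        da_bla = max(da_bla - P[P_THDA_LH_BLA], 0.0)
        da_nacc = max(da_nacc - P[P_THDA_PFC_NACC], 0.0)

        # ---- 3. membranes --------------------------------------------
        o = 0
        for i in range(n_it):
            g = FW[FW_VIS_IT] * cs[it_step, i // 3]
            m_it[i] += lam * (g + noise[it_step, o] - m_it[i])
            o += 1
        for i in range(n_lh):
            g = FW[FW_GUS_LH] * us[it_step, i] * mag
            m_lh[i] += lam * (g + noise[it_step, o] - m_lh[i])
            o += 1
        for j in range(n_bla):
            y_exc = max(g_bla_exc[j] - k_bla * xb_bla_exc[j], 0.0)
            y_mod = max(g_bla_mod[j] - k_bla * xb_bla_mod[j], 0.0)
            gate = 1.0 if g_bla_exc[j] >= P[P_BLA_GAMMA] else 0.0
            drive = y_exc + (1.0 - gate) * y_mod - g_bla_inh[j]
            m_bla[j] += lam * (drive + noise[it_step, o] - m_bla[j])
            o += 1
        sc[SC_M_CE] += lam * (g_ce + noise[it_step, o] - sc[SC_M_CE])
        o += 1
        d0 = y_pptn0 - FW[FW_PPTN_PPTN] * r_pptn[1]
        d1 = y_pptn1 - FW[FW_PPTN_PPTN] * r_pptn[0]
        m_pptn[0] += lam * (d0 + noise[it_step, o] - m_pptn[0])
        o += 1
        m_pptn[1] += lam * (d1 + noise[it_step, o] - m_pptn[1])
        o += 1
        for j in range(n_nacc):
            g_exc_j = FW[FW_BLA_NACC] * r_bla[j]
            glut[j] = g_exc_j + g_nacc_mod[j]
            drive = (glut[j] - g_nacc_inh[j] + g_nacc_dopa + s[j])
            m_nacc[j] += lam * (drive + noise[it_step, o] - m_nacc[j])
            o += 1
        gate_vp = 1.0 if g_vp_exc >= P[P_VP_GAMMA] else 0.0
        inh_gate = gate_vp if P[P_VP_PRINTED] != 0.0 else 1.0 - gate_vp
        sc[SC_M_VP] += lam * (g_vp_exc - inh_gate * g_vp_inh + P[P_VP_B]
                              + noise[it_step, o] - sc[SC_M_VP])
        o += 1
        sc[SC_M_LHB] += lam * (-g_lhb_inh + P[P_LHB_B]
                               + noise[it_step, o] - sc[SC_M_LHB])
        o += 1
        sc[SC_M_RMTG] += lam * (g_rmtg_exc - g_rmtg_inh
                                + noise[it_step, o] - sc[SC_M_RMTG])
        o += 1
        gate_vta = 1.0 if g_vta_exc >= P[P_VTA_GAMMA] else 0.0
        vta_drive = (g_vta_exc * (1.0 - y_vta_mod)
                     - (1.0 - gate_vta) * y_vta_inh + P[P_VTA_B])
        sc[SC_M_VTA] += lam * (vta_drive + noise[it_step, o] - sc[SC_M_VTA])

        # vmPFC oscillator banks (no noise)
        t_next = t + dt
        for b in range(n_banks):
            inp = 0.0
            for i in range(3 * b, 3 * b + 3):
                inp += r_it[i]
            inp *= FW[FW_IT_PFC]
            if not bank_active[b]:
                if inp >= P[P_TSTART]:
                    bank_active[b] = True
                    bank_t0[b] = t_next
            elif inp < P[P_TSTOP]:
                bank_active[b] = False
                for i in range(bank_size * b, bank_size * (b + 1)):
                    m_pfc[i] = 0.0
            if bank_active[b]:
                for i in range(bank_size * b, bank_size * (b + 1)):
                    ph = (2.0 * np.pi * osc_freq[i] * (t_next - bank_t0[b])
                          / 1000.0 + osc_phase[i])
                    target = 0.5 * (1.0 + np.sin(ph))
                    m_pfc[i] += (dt / P[P_PFC_TAU]) * (target - m_pfc[i])

        # ---- 4. rates -------------------------------------------------
        for i in range(n_it):
            r_it[i] = max(m_it[i], 0.0)
        for i in range(n_lh):
            r_lh[i] = max(m_lh[i], 0.0)
        for i in range(n_bla):
            r_bla[i] = max(m_bla[i], 0.0)
        sc[SC_R_CE] = max(sc[SC_M_CE], 0.0)
        r_pptn[0] = max(m_pptn[0], 0.0)
        r_pptn[1] = max(m_pptn[1], 0.0)
        for i in range(n_pfc):
            r_pfc[i] = max(m_pfc[i], 0.0)
        for i in range(n_nacc):
            r_nacc[i] = min(max(m_nacc[i], 0.0), P[P_NACC_RMAX])
        sc[SC_R_VP] = max(sc[SC_M_VP], 0.0)
        sc[SC_R_LHB] = max(sc[SC_M_LHB], 0.0)
        sc[SC_R_RMTG] = max(sc[SC_M_RMTG], 0.0)
        sc[SC_R_VTA] = max(sc[SC_M_VTA], 0.0)

        # ---- 5. NAcc up/down transitions ------------------------------
        da_on = sc[SC_R_VTA] >= P[P_G_DOPA]
        relax = P[P_RELAX] != 0.0
        for j in range(n_nacc):
            forced = da_on or (glut[j] >= P[P_G_GLUT])
            if relax:
                if forced:
                    nacc_up[j] = True
                elif s_time[j] >= P[P_G_UP]:
                    nacc_up[j] = False
                elif s_time[j] <= P[P_G_DOWN]:
                    nacc_up[j] = True
            else:
                if forced or (s_time[j] >= P[P_G_UP]):
                    nacc_up[j] = True
                elif (not da_on) and (s_time[j] < P[P_G_DOWN]):
                    nacc_up[j] = False
            s[j] = P[P_S_UP] if nacc_up[j] else P[P_S_DOWN]
            s_time[j] += (dt / P[P_TAU_S]) * (s[j] - s_time[j])

        # ---- 6. plasticity --------------------------------------------
        if learning_on:
            mean_lh = lh_sum_new = 0.0
            for i in range(n_lh):
                lh_sum_new += r_lh[i]
            mean_lh = lh_sum_new / n_lh
            tot = 0.0
            for i in range(n_bla):
                tot += r_bla[i]
            mean_bla = tot / n_bla
            tot = 0.0
            for i in range(n_nacc):
                tot += r_nacc[i]
            mean_nacc = tot / n_nacc
            # oscillator mean over the synchronized (active) banks only
            tot = 0.0
            for i in range(n_pfc):
                tot += r_pfc[i]
            n_active_banks = 0
            for b in range(n_banks):
                if bank_active[b]:
                    n_active_banks += 1
            if n_active_banks > 0:
                mean_pfc = tot / (n_active_banks * bank_size)
            else:
                mean_pfc = 0.0
            tot = 0.0
            for i in range(n_it):
                tot += r_it[i]
            mean_it = tot / n_it

            # LH -> BLA: regularizer trace, then DA-modulated covariance
            any_alpha = False
            for j in range(n_bla):
                tgt = max(r_bla[j] - P[P_RMAX_LH_BLA], 0.0)
                alpha_bla[j] += (dt / P[P_TA_LH_BLA]) * (tgt - alpha_bla[j])
                if alpha_bla[j] < 1e-15:
                    alpha_bla[j] = 0.0
                if alpha_bla[j] > 0.0:
                    any_alpha = True
            if da_bla != 0.0 or any_alpha:
                scale = dt / P[P_EPS_LH_BLA]
                cK = scale * P[P_K_LH_BLA] * da_bla
                for j in range(n_bla):
                    yj = r_bla[j] - mean_bla
                    dec = scale * alpha_bla[j] * r_bla[j] * r_bla[j]
                    for i in range(n_lh):
                        w = W_lh_bla[j, i]
                        if da_bla != 0.0:
                            xi = r_lh[i] - mean_lh
                            if xi > 0.0 or yj > 0.0:
                                w += cK * yj * xi
                        w -= dec * w
                        if w < P[P_WMIN_LH_BLA]:
                            w = P[P_WMIN_LH_BLA]
                        elif w > P[P_WMAX_LH_BLA]:
                            w = P[P_WMAX_LH_BLA]
                        W_lh_bla[j, i] = w

            # IT -> BLA: DA-gated transfer rule (unbounded weights)
            if g_bla_dopa >= P[P_GDOPA_IT_BLA]:
                scale = dt / P[P_EPS_IT_BLA]
                for j in range(n_bla):
                    head = max(g_bla_exc[j] - g_bla_mod[j], 0.0)
                    if head == 0.0:
                        continue
                    cj = scale * head * (r_bla[j] - mean_bla)
                    for i in range(n_it):
                        W_it_bla[j, i] += cj * (r_it[i] - mean_it)

            # BLA lateral inhibition: anti-Hebbian covariance
            scale = dt / P[P_EPS_BLA_BLA]
            for j in range(n_bla):
                yj = max(r_bla[j] - mean_bla, 0.0)
                if yj == 0.0:
                    continue
                for i in range(n_bla):
                    if i == j:
                        continue
                    xi = max(r_bla[i] - mean_bla, 0.0)
                    if xi == 0.0:
                        continue
                    w = W_bla_bla[j, i] + scale * yj * xi
                    if w > P[P_WMAX_BLA_BLA]:
                        w = P[P_WMAX_BLA_BLA]
                    W_bla_bla[j, i] = w

            # vmPFC -> NAcc: regularizer + DA-modulated covariance
            any_alpha = False
            for j in range(n_nacc):
                tgt = max(r_nacc[j] - P[P_RMAX_PFC_NACC], 0.0)
                alpha_nacc[j] += (dt / P[P_TA_PFC_NACC]) * (tgt - alpha_nacc[j])
                if alpha_nacc[j] < 1e-15:
                    alpha_nacc[j] = 0.0
                if alpha_nacc[j] > 0.0:
                    any_alpha = True
            if da_nacc != 0.0 or any_alpha:
                scale = dt / P[P_EPS_PFC_NACC]
                cK = scale * P[P_K_PFC_NACC] * da_nacc
                for j in range(n_nacc):
                    yj = r_nacc[j] - mean_nacc
                    dec = scale * alpha_nacc[j] * r_nacc[j] * r_nacc[j]
                    for i in range(n_pfc):
                        w = W_pfc_nacc[j, i]
                        if da_nacc != 0.0:
                            xi = r_pfc[i] - mean_pfc
                            if xi > 0.0 or yj > 0.0:
                                w += cK * yj * xi
                        w -= dec * w
                        if w < P[P_WMIN_PFC_NACC]:
                            w = P[P_WMIN_PFC_NACC]
                        elif w > P[P_WMAX_PFC_NACC]:
                            w = P[P_WMAX_PFC_NACC]
                        W_pfc_nacc[j, i] = w

            # NAcc lateral inhibition
            scale = dt / P[P_EPS_NACC_NACC]
            for j in range(n_nacc):
                yj = max(r_nacc[j] - mean_nacc, 0.0)
                if yj == 0.0:
                    continue
                for i in range(n_nacc):
                    if i == j:
                        continue
                    xi = max(r_nacc[i] - mean_nacc, 0.0)
                    if xi == 0.0:
                        continue
                    w = W_nacc_nacc[j, i] + scale * yj * xi
                    if w > P[P_WMAX_NACC_NACC]:
                        w = P[P_WMAX_NACC_NACC]
                    W_nacc_nacc[j, i] = w

            # NAcc -> VP and NAcc -> VTA: thresholded Hebb
            post = sc[SC_R_VP] - P[P_THPOST_NACC_VP]
            if post > 0.0:
                scale = (dt / P[P_EPS_NACC_VP]) * post
                for i in range(n_nacc):
                    w = w_nacc_vp[i] + scale * r_nacc[i]
                    if w > P[P_WMAX_NACC_VP]:
                        w = P[P_WMAX_NACC_VP]
                    w_nacc_vp[i] = w
            post = sc[SC_R_VTA] - P[P_THPOST_NACC_VTA]
            if post > 0.0:
                scale = (dt / P[P_EPS_NACC_VTA]) * post
                for i in range(n_nacc):
                    w = w_nacc_vta[i] + scale * r_nacc[i]
                    if w > P[P_WMAX_NACC_VTA]:
                        w = P[P_WMAX_NACC_VTA]
                    w_nacc_vta[i] = w

        sc[SC_T] = t_next

        # ---- 7. recording ---------------------------------------------
        if rec_vta.shape[0] == n_steps:
            rec_vta[it_step] = sc[SC_R_VTA]
        if rec_bla.shape[0] == n_steps:
            rec_bla[it_step] = r_bla
        if rec_nacc.shape[0] == n_steps:
            rec_nacc[it_step] = r_nacc
        if rec_nacc_m.shape[0] == n_steps:
            rec_nacc_m[it_step] = m_nacc
        if rec_s.shape[0] == n_steps:
            rec_s[it_step] = s
        if rec_st.shape[0] == n_steps:
            rec_st[it_step] = s_time
        if rec_ce.shape[0] == n_steps:
            rec_ce[it_step] = sc[SC_R_CE]
        if rec_pptn.shape[0] == n_steps:
            rec_pptn[it_step] = r_pptn
        if rec_vp.shape[0] == n_steps:
            rec_vp[it_step] = sc[SC_R_VP]
        if rec_lhb.shape[0] == n_steps:
            rec_lhb[it_step] = sc[SC_R_LHB]
        if rec_rmtg.shape[0] == n_steps:
            rec_rmtg[it_step] = sc[SC_R_RMTG]
        if rec_it.shape[0] == n_steps:
            rec_it[it_step] = r_it
        if rec_lh.shape[0] == n_steps:
            rec_lh[it_step] = r_lh
        if rec_pfc.shape[0] == n_steps:
            rec_pfc[it_step] = r_pfc


_REC_ORDER = ("VTA", "BLA", "NAcc", "NAcc_m", "NAcc_s", "NAcc_s_time",
              "CE", "PPTN", "VP", "LHb", "RMTg", "IT", "LH", "vmPFC")
_REC_WIDTH = {"VTA": 0, "BLA": 36, "NAcc": 36, "NAcc_m": 36, "NAcc_s": 36,
              "NAcc_s_time": 36, "CE": 0, "PPTN": 2, "VP": 0, "LHb": 0,
              "RMTg": 0, "IT": 9, "LH": 4, "vmPFC": 150}


def simulate_trial(net, cs, us, mag, learning_on, noise, record):
    """Run one trial through the compiled kernel; returns trace dict."""
    cfg = net.cfg
    n_steps = cs.shape[0]
    widths = {"VTA": 0, "BLA": cfg.n_bla, "NAcc": cfg.n_nacc,
              "NAcc_m": cfg.n_nacc, "NAcc_s": cfg.n_nacc,
              "NAcc_s_time": cfg.n_nacc, "CE": 0, "PPTN": cfg.n_pptn,
              "VP": 0, "LHb": 0, "RMTg": 0, "IT": cfg.n_it, "LH": cfg.n_lh,
              "vmPFC": cfg.n_pfc}
    bufs = {}
    args = []
    for name in _REC_ORDER:
        w = widths[name]
        if name in record:
            buf = np.empty(n_steps) if w == 0 else np.empty((n_steps, w))
        else:
            buf = np.empty(0) if w == 0 else np.empty((0, w))
        bufs[name] = buf
        args.append(buf)
    P, FW = pack_params(net)
    sc = pack_scalars(net)
    _run(cs, us, float(mag), bool(learning_on), noise, sc, P, FW,
         net.m_it, net.r_it, net.m_lh, net.r_lh, net.m_bla, net.r_bla,
         net.m_pptn, net.r_pptn, net.m_pfc, net.r_pfc, net.m_nacc,
         net.r_nacc,
         net.phi_bla_exc.xbar, net.phi_bla_mod.xbar, net.phi_pptn.xbar,
         net.phi_bla_exc.xbar2, net.phi_bla_mod.xbar2, net.phi_pptn.xbar2,
         net.osc_freq, net.osc_phase, net.bank_active, net.bank_t0,
         net.nacc_up, net.s, net.s_time,
         net.reg_lh_bla.alpha, net.reg_pfc_nacc.alpha,
         net.W_lh_bla, net.W_it_bla, net.W_bla_bla, net.W_pfc_nacc,
         net.W_nacc_nacc, net.w_nacc_vp, net.w_nacc_vta,
         *args)
    unpack_scalars(net, sc)
    return {name: bufs[name] for name in record}
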