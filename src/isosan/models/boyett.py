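"""Boyett-family rabbit SAN cell models (central and peripheral).

Membrane formulation: the Zhang et al. (2000) central/peripheral rabbit
sinoatrial-node action-potential models (Hodgkin-Huxley-type gating, fixed
intracellular Na+/K+), upgraded with

* a sustained inward current I_st (Guo/Noma-type qa*qi gating, identical
  current *density* in centre and periphery), and
* an intracellular Ca2+-handling subsystem (subsarcolemmal space, bulk
  myoplasm, SR uptake and release compartments, troponin/calmodulin/
  calsequestrin buffering) after the Kurata et al. (2002) formulation,
  scaled to cell volume, with I_NaCa and the Ca2+ background current sensing
  the dynamic subsarcolemmal [Ca2+].

See PROVENANCE.md in this directory for sources, reconstruction choices and
the verification of emergent properties.

Hooks used by the isoprenaline layer: ``v_shift_f`` (mV, shifts the I_f
steady-state activation only), ``v_shift_kr`` (mV, shifts the I_Kr
steady-state activation only), ``taukr_rate_scale`` (divides both I_Kr
activation-gate time constants), ``p_up``/``p_rel`` (SR flux rates) and the
maximal conductances ``g_cal``, ``g_kr``, ``g_ks``, ``g_st``.
"""

from __future__ import annotations

import math

import numpy as np

from ._compat import maybe_njit
from .base import CellModelSpec

# Physical constants (310.15 K)
_F = 96485.0          # C/mol
_RTF = 26.713         # mV
_FRT = 1.0 / _RTF

STATE_LABELS = (
    "v", "m", "h1", "h2", "d_l", "f_l", "d_t", "f_t", "q", "r",
    "p_af", "p_as", "p_ik", "xs", "y", "q_a", "q_i",
    "cai", "casub", "caup", "carel",
    "f_tc", "f_tmc", "f_tmm", "f_cmi", "f_cms", "f_cq",
)

PARAM_NAMES = (
    "cm", "g_na", "g_cal", "g_cat", "g_to", "g_sus", "g_kr", "g_ks",
    "g_fna", "g_fk", "g_bna", "g_bca", "g_bk", "k_naca", "i_pmax", "g_st",
    "nao", "nai", "ko", "ki", "cao", "e_cal", "e_cat", "e_st",
    "v_shift_f", "v_shift_kr", "taukr_rate_scale",
    "p_up", "k_up", "p_rel", "k_rel", "tau_tr", "tau_difca",
    "v_i", "v_sub", "v_up", "v_rel", "k_leak",
)

CURRENT_LABELS = (
    "i_na", "i_cal", "i_cat", "i_to", "i_sus", "i_kr", "i_ks",
    "i_f_na", "i_f_k", "i_st", "i_b_na", "i_b_ca", "i_b_k",
    "i_naca", "i_p",
)

# Ca2+ buffering (Kurata et al. 2002; rates in 1/(mM*ms) and 1/ms, totals mM)
_KF_TC, _KB_TC = 88.8, 0.446
_KF_TMC, _KB_TMC = 227.7, 0.00751
_KF_TMM, _KB_TMM = 2.277, 0.751
_KF_CM, _KB_CM = 227.7, 0.542
_KF_CQ, _KB_CQ = 0.534, 0.445
_TC_TOT, _TMC_TOT, _CM_TOT, _CQ_TOT = 0.031, 0.062, 0.045, 10.0
_MG = 2.5  # mM


def _membrane_and_fluxes(t, y, p):
    """Right-hand side; also used (via a flag) to report currents."""
    # unpack parameters
    cm = p[0]; g_na = p[1]; g_cal = p[2]; g_cat = p[3]; g_to = p[4]
    g_sus = p[5]; g_kr = p[6]; g_ks = p[7]; g_fna = p[8]; g_fk = p[9]
    g_bna = p[10]; g_bca = p[11]; g_bk = p[12]; k_naca = p[13]
    i_pmax = p[14]; g_st = p[15]; nao = p[16]; nai = p[17]; ko = p[18]
    ki = p[19]; cao = p[20]; e_cal = p[21]; e_cat = p[22]; e_st = p[23]
    v_shift_f = p[24]; v_shift_kr = p[25]; taukr_scale = p[26]
    p_up = p[27]; k_up = p[28]; p_rel = p[29]; k_rel = p[30]
    tau_tr = p[31]; tau_difca = p[32]
    v_i = p[33]; v_sub = p[34]; v_up = p[35]; v_rel = p[36]
    k_leak = p[37]

    v = y[0]; m = y[1]; h1 = y[2]; h2 = y[3]; d_l = y[4]; f_l = y[5]
    d_t = y[6]; f_t = y[7]; q = y[8]; r = y[9]; p_af = y[10]; p_as = y[11]
    p_ik = y[12]; xs = y[13]; yf = y[14]; q_a = y[15]; q_i = y[16]
    cai = y[17]; casub = y[18]; caup = y[19]; carel = y[20]
    f_tc = y[21]; f_tmc = y[22]; f_tmm = y[23]; f_cmi = y[24]
    f_cms = y[25]; f_cq = y[26]

    if cai < 1e-10:
        cai = 1e-10
    if casub < 1e-10:
        casub = 1e-10

    e_na = _RTF * math.log(nao / nai)
    e_k = _RTF * math.log(ko / ki)
    e_ca = 0.5 * _RTF * math.log(cao / casub)

    # --- I_Na (Lindblad-type permeability formulation; zero in the centre)
    if abs(v) > 1e-6:
        pre = v / math.expm1(v * _FRT)
    else:
        pre = _RTF
    h = (1.0 - _fna_frac(v)) * h1 + _fna_frac(v) * h2
    i_na = g_na * m * m * m * h * nao * _F * _FRT * pre * math.expm1((v - e_na) * _FRT)

    # --- I_CaL (with small voltage-dependent pedestal)
    i_cal = g_cal * (f_l * d_l + 0.006 / (1.0 + math.exp(-(v + 14.1) / 6.0))) * (v - e_cal)
    i_cat = g_cat * d_t * f_t * (v - e_cat)

    i_to = g_to * q * r * (v - e_k)
    i_sus = g_sus * r * (v - e_k)

    i_kr = g_kr * (0.6 * p_af + 0.4 * p_as) * p_ik * (v - e_k)
    i_ks = g_ks * xs * xs * (v - e_k)

    i_f_na = g_fna * yf * (v - e_na)
    i_f_k = g_fk * yf * (v - e_k)

    i_st = g_st * q_a * q_i * (v - e_st)

    i_b_na = g_bna * (v - e_na)
    i_b_ca = g_bca * (v - e_ca)
    i_b_k = g_bk * (v - e_k)

    # --- Na/Ca exchanger (DiFrancesco-Noble form), senses subsarcolemmal Ca
    x1 = nai ** 3 * cao * math.exp(0.03743 * v * 0.5)
    x2 = nao ** 3 * casub * math.exp(0.03743 * v * (0.5 - 1.0))
    i_naca = k_naca * (x1 - x2) / (1.0 + 0.0001 * (casub * nao ** 3 + cao * nai ** 3))

    # --- Na/K pump
    i_p = (i_pmax * (nai / (5.64 + nai)) ** 3 * (ko / (0.621 + ko)) ** 2
           * 1.6 / (1.5 + math.exp(-(v + 60.0) / 40.0)))

    i_tot = (i_na + i_cal + i_cat + i_to + i_sus + i_kr + i_ks + i_f_na
             + i_f_k + i_st + i_b_na + i_b_ca + i_b_k + i_naca + i_p)

    dy = np.empty(27)
    dy[0] = -i_tot / cm

    # --- gating kinetics (time constants in ms)
    # I_Na
    m_inf = 1.0 / (1.0 + math.exp(-(v + 30.32) / 5.46))
    tau_m = 0.6247 / (0.8322166 * math.exp(-0.33566 * (v + 56.7062))
                      + 0.6274 * math.exp(0.0823 * (v + 65.0131))) + 0.04569
    h_inf = 1.0 / (1.0 + math.exp((v + 66.1) / 6.4))
    tau_h1 = (3.717e-3 * math.exp(-0.2815 * (v + 17.11))
              / (1.0 + 0.003732 * math.exp(-0.3426 * (v + 37.76))) + 0.5977)
    tau_h2 = (3.186e-5 * math.exp(-0.6219 * (v + 18.8))
              / (1.0 + 7.189e-5 * math.exp(-0.6683 * (v + 34.07))) + 3.556)
    dy[1] = (m_inf - m) / tau_m
    dy[2] = (h_inf - h1) / tau_h1
    dy[3] = (h_inf - h2) / tau_h2

    # I_CaL activation/inactivation (rates below in 1/s -> tau in ms)
    a = _lin_exp(-28.38, v + 35.0, -2.5) + _lin_exp(-84.9, v, -4.8077)
    b = _lin_exp(11.42, v - 5.0, 2.5)
    tau_dl = 1000.0 / (a + b)
    dl_inf = 1.0 / (1.0 + math.exp(-(v + 23.1) / 6.0))
    a = _lin_exp(3.12, v + 28.0, 4.0)
    b = 25.0 / (1.0 + math.exp(-(v + 28.0) / 4.0))
    tau_fl = 1000.0 / (a + b)
    fl_inf = 1.0 / (1.0 + math.exp((v + 45.0) / 5.0))
    dy[4] = (dl_inf - d_l) / tau_dl
    dy[5] = (fl_inf - f_l) / tau_fl

    # I_CaT
    dt_inf = 1.0 / (1.0 + math.exp(-(v + 37.0) / 6.8))
    tau_dt = 1000.0 / (1068.0 * math.exp((v + 26.3) / 30.0)
                       + 1068.0 * math.exp(-(v + 26.3) / 30.0))
    ft_inf = 1.0 / (1.0 + math.exp((v + 71.0) / 9.0))
    tau_ft = 1000.0 / (15.3 * math.exp(-(v + 71.7) / 83.3)
                       + 15.0 * math.exp((v + 71.7) / 15.38))
    dy[6] = (dt_inf - d_t) / tau_dt
    dy[7] = (ft_inf - f_t) / tau_ft

    # I_to / I_sus
    q_inf = 1.0 / (1.0 + math.exp((v + 59.37) / 13.1))
    tau_q = 10.1 + 65.17 / (0.57 * math.exp(-0.08 * (v + 49.0))
                            + 0.024 * math.exp(0.1 * (v + 50.93)))
    r_inf = 1.0 / (1.0 + math.exp(-(v - 10.93) / 19.7))
    tau_r = 2.98 + 15.59 / (1.037 * math.exp(0.09 * (v + 30.61))
                            + 0.369 * math.exp(-0.12 * (v + 23.84)))
    dy[8] = (q_inf - q) / tau_q
    dy[9] = (r_inf - r) / tau_r

    # I_Kr: ISO shifts the steady-state activation (v_shift_kr, negative) and
    # scales the activation-gate time constants (deactivation acceleration).
    vk = v - v_shift_kr
    pa_inf = 1.0 / (1.0 + math.exp(-(vk + 14.2) / 10.6))
    tau_paf = 1000.0 / (37.2 * math.exp((v - 9.0) / 15.9)
                        + 0.96 * math.exp(-(v - 9.0) / 22.5)) / taukr_scale
    tau_pas = 1000.0 / (4.2 * math.exp((v - 9.0) / 17.0)
                        + 0.15 * math.exp(-(v - 9.0) / 21.6)) / taukr_scale
    pik_inf = 1.0 / (1.0 + math.exp((v + 18.6) / 10.1))
    dy[10] = (pa_inf - p_af) / tau_paf
    dy[11] = (pa_inf - p_as) / tau_pas
    dy[12] = (pik_inf - p_ik) / 2.0

    # I_Ks
    a = 14.0 / (1.0 + math.exp(-(v - 40.0) / 9.0))
    b = math.exp(-v / 45.0)
    dy[13] = (a / (a + b) - xs) * (a + b) / 1000.0

    # I_f: steady-state activation shifted by +v_shift_f (depolarizing);
    # the time constant keeps its control voltage dependence.
    vf = v - v_shift_f
    a_inf = math.exp(-(vf + 78.91) / 26.62)
    b_inf = math.exp((vf + 75.13) / 21.25)
    y_inf = a_inf / (a_inf + b_inf)
    a = math.exp(-(v + 78.91) / 26.62)
    b = math.exp((v + 75.13) / 21.25)
    tau_y = 1000.0 / (a + b)
    dy[14] = (y_inf - yf) / tau_y

    # I_st gating (Guo/Noma type)
    qa_inf = 1.0 / (1.0 + math.exp(-(v + 57.0) / 5.0))
    a = 1.0 / (0.15 * math.exp(-v / 11.0) + 0.2 * math.exp(-v / 700.0))
    b = 1.0 / (16.0 * math.exp(v / 8.0) + 15.0 * math.exp(v / 50.0))
    dy[15] = (qa_inf - q_a) * (a + b)
    a = 1.0 / (3100.0 * math.exp(v / 13.0) + 700.0 * math.exp(v / 70.0))
    b = (1.0 / (95.0 * math.exp(-v / 10.0) + 50.0 * math.exp(-v / 700.0))
         + 0.000229 / (1.0 + math.exp(-v / 5.0)))
    qi_inf = a / (a + b)
    dy[16] = (qi_inf - q_i) * (a + b) / 6.65

    # --- Ca2+ handling (Kurata-type compartments)
    j_up = p_up / (1.0 + k_up / cai)
    j_tr = (caup - carel) / tau_tr
    j_rel = p_rel * (carel - casub) / (1.0 + (k_rel / casub) ** 2)
    # diastolic ryanodine-receptor leak; scaled together with p_rel by ISO
    j_leak = k_leak * (carel - cai)
    j_dif = (casub - cai) / tau_difca

    dftc = _KF_TC * cai * (1.0 - f_tc) - _KB_TC * f_tc
    dftmc = _KF_TMC * cai * (1.0 - f_tmc - f_tmm) - _KB_TMC * f_tmc
    dftmm = _KF_TMM * _MG * (1.0 - f_tmc - f_tmm) - _KB_TMM * f_tmm
    dfcmi = _KF_CM * cai * (1.0 - f_cmi) - _KB_CM * f_cmi
    dfcms = _KF_CM * casub * (1.0 - f_cms) - _KB_CM * f_cms
    dfcq = _KF_CQ * carel * (1.0 - f_cq) - _KB_CQ * f_cq

    # nA -> mM/ms conversion: I / (2 F Vol[ul]) * 1e-3.
    # The phenomenological background Ca2+ current is kept out of the Ca2+
    # mass balance so that the exchanger balance of the parent membrane
    # model is preserved (see PROVENANCE.md).
    ca_influx = -(i_cal + i_cat - 2.0 * i_naca) / (2.0 * _F * v_sub) * 1e-3

    dy[17] = (j_dif * v_sub - j_up * v_up + j_leak * v_rel) / v_i - (
        _CM_TOT * dfcmi + _TC_TOT * dftc + _TMC_TOT * dftmc)
    dy[18] = ca_influx + j_rel * v_rel / v_sub - j_dif - _CM_TOT * dfcms
    dy[19] = j_up - j_tr * v_rel / v_up
    dy[20] = j_tr - j_rel - j_leak - _CQ_TOT * dfcq
    dy[21] = dftc
    dy[22] = dftmc
    dy[23] = dftmm
    dy[24] = dfcmi
    dy[25] = dfcms
    dy[26] = dfcq
    return dy


def _fna_frac(v):
    # voltage-dependent weighting of fast/slow Na inactivation
    return (0.0952 * math.exp(-0.063 * (v + 34.4))
            / (1.0 + 1.66 * math.exp(-0.225 * (v + 63.7))) + 0.0869)


def _lin_exp(a, x, s):
    """a*x / (exp(x/s) - 1) with the x->0 limit a*s handled."""
    r = x / s
    if abs(r) < 1e-6:
        return a * s * (1.0 - 0.5 * r)
    return a * x / math.expm1(r)


def _currents(y, p):
    cm = p[0]; g_na = p[1]; g_cal = p[2]; g_cat = p[3]; g_to = p[4]
    g_sus = p[5]; g_kr = p[6]; g_ks = p[7]; g_fna = p[8]; g_fk = p[9]
    g_bna = p[10]; g_bca = p[11]; g_bk = p[12]; k_naca = p[13]
    i_pmax = p[14]; g_st = p[15]; nao = p[16]; nai = p[17]; ko = p[18]
    ki = p[19]; cao = p[20]; e_cal = p[21]; e_cat = p[22]; e_st = p[23]

    v = y[0]; m = y[1]; h1 = y[2]; h2 = y[3]; d_l = y[4]; f_l = y[5]
    d_t = y[6]; f_t = y[7]; q = y[8]; r = y[9]; p_af = y[10]; p_as = y[11]
    p_ik = y[12]; xs = y[13]; yf = y[14]; q_a = y[15]; q_i = y[16]
    casub = y[18]
    if casub < 1e-10:
        casub = 1e-10

    e_na = _RTF * math.log(nao / nai)
    e_k = _RTF * math.log(ko / ki)
    e_ca = 0.5 * _RTF * math.log(cao / casub)

    if abs(v) > 1e-6:
        pre = v / math.expm1(v * _FRT)
    else:
        pre = _RTF
    h = (1.0 - _fna_frac(v)) * h1 + _fna_frac(v) * h2
    i_na = g_na * m * m * m * h * nao * _F * _FRT * pre * math.expm1((v - e_na) * _FRT)
    i_cal = g_cal * (f_l * d_l + 0.006 / (1.0 + math.exp(-(v + 14.1) / 6.0))) * (v - e_cal)
    i_cat = g_cat * d_t * f_t * (v - e_cat)
    i_to = g_to * q * r * (v - e_k)
    i_sus = g_sus * r * (v - e_k)
    i_kr = g_kr * (0.6 * p_af + 0.4 * p_as) * p_ik * (v - e_k)
    i_ks = g_ks * xs * xs * (v - e_k)
    i_f_na = g_fna * yf * (v - e_na)
    i_f_k = g_fk * yf * (v - e_k)
    i_st = g_st * q_a * q_i * (v - e_st)
    i_b_na = g_bna * (v - e_na)
    i_b_ca = g_bca * (v - e_ca)
    i_b_k = g_bk * (v - e_k)
    x1 = nai ** 3 * cao * math.exp(0.03743 * v * 0.5)
    x2 = nao ** 3 * casub * math.exp(0.03743 * v * (0.5 - 1.0))
    i_naca = k_naca * (x1 - x2) / (1.0 + 0.0001 * (casub * nao ** 3 + cao * nai ** 3))
    i_p = (i_pmax * (nai / (5.64 + nai)) ** 3 * (ko / (0.621 + ko)) ** 2
           * 1.6 / (1.5 + math.exp(-(v + 60.0) / 40.0)))
    out = np.empty(15)
    out[0] = i_na; out[1] = i_cal; out[2] = i_cat; out[3] = i_to
    out[4] = i_sus; out[5] = i_kr; out[6] = i_ks; out[7] = i_f_na
    out[8] = i_f_k; out[9] = i_st; out[10] = i_b_na; out[11] = i_b_ca
    out[12] = i_b_k; out[13] = i_naca; out[14] = i_p
    return out


_fna_frac = maybe_njit(_fna_frac)
_lin_exp = maybe_njit(_lin_exp)
rhs = maybe_njit(_membrane_and_fluxes)
currents = maybe_njit(_currents)


def _volumes(cm_pf: float) -> dict:
    # cell volume scaled from 3.5 pl at 32 pF (Kurata et al. geometry)
    v_cell = 3.5e-6 * cm_pf / 32.0  # ul
    v_sub = 0.01 * v_cell
    return {
        "v_i": 0.46 * v_cell - v_sub,
        "v_sub": v_sub,
        "v_up": 0.0116 * v_cell,
        "v_rel": 0.0012 * v_cell,
    }


def _common_params() -> dict:
    return {
        "nao": 140.0, "nai": 8.0, "ko": 5.4, "ki": 140.0, "cao": 2.0,
        "e_cal": 46.4, "e_cat": 45.0, "e_st": 37.4,
        "v_shift_f": 0.0, "v_shift_kr": 0.0, "taukr_rate_scale": 1.0,
        "p_up": 0.005, "k_up": 0.0006, "p_rel": 5.0, "k_rel": 0.0012,
        "tau_tr": 60.0, "tau_difca": 0.04, "k_leak": 0.02,
    }


#: Maximal conductances (uS), pump/exchanger scalers (nA) and capacitance
#: (nF) for the two published cell types; I_st density 0.002 nS/pF in both
#: (identical current density centre/periphery; see PROVENANCE.md).
# g_kr, g_bna and k_naca carry the rebalance required by the dynamic
# Ca2+/exchanger coupling (the parent membrane model fixed [Ca2+]_i);
# calibrated once against the published control AP, see PROVENANCE.md.
CENTRAL_PARAMS = {
    "cm": 0.02, "g_na": 0.0, "g_cal": 0.0058, "g_cat": 0.0043,
    "g_to": 0.00491, "g_sus": 6.645e-5, "g_kr": 1.1955e-3, "g_ks": 5.18e-4,
    "g_fna": 5.48e-4, "g_fk": 5.48e-4, "g_bna": 2.9e-5, "g_bca": 1.32e-5,
    "g_bk": 2.52e-5, "k_naca": 2.16e-5, "i_pmax": 0.0478, "g_st": 4.0e-5,
}

PERIPHERAL_PARAMS = {
    "cm": 0.065, "g_na": 1.2e-6, "g_cal": 0.0659, "g_cat": 0.0139,
    "g_to": 0.03649, "g_sus": 1.14e-3, "g_kr": 0.016, "g_ks": 0.0104,
    "g_fna": 6.9e-3, "g_fk": 6.9e-3, "g_bna": 1.89e-4, "g_bca": 4.3e-5,
    "g_bk": 8.19e-5, "k_naca": 1.408e-4, "i_pmax": 0.16, "g_st": 1.3e-4,
}

# Settled on-limit-cycle states (frozen after a long control integration;
# see PROVENANCE.md). Order matches STATE_LABELS.
INITIAL_STATE_CENTRAL = np.array([
    -59.46003591, 0.004787754607, 0.09925277714, 0.01197246136, 0.002335608523,
    0.9128864839, 0.03547399387, 0.1689835474, 0.2133682976, 0.02747739042,
    0.3324378257, 0.674826447, 0.9827375344, 0.222317786, 0.02184650005,
    0.3871720788, 0.150476455, 0.0002457286721, 0.0001055423604, 1.17687202,
    0.1019579224, 0.04717448102, 0.557221209, 0.3909956726, 0.09435668599,
    0.04264781333, 0.1068394832,
])

INITIAL_STATE_PERIPHERAL = np.array([
    -76.06756082, 0.0002296654851, 0.2597462421, 0.01520093762, 0.0001478763007,
    0.9140647237, 0.003188326948, 0.227767157, 0.3421718723, 0.01286972061,
    0.4505769225, 0.7146109116, 0.9965329578, 0.3339282657, 0.01568350381,
    0.03282380768, 0.1746645548, 0.0004668078943, 7.069647336e-05, 1.482727742,
    0.06500338199, 0.08777537272, 0.7222624303, 0.2450991269, 0.1674891745,
    0.02957649262, 0.06832314958,
])


def build(region: str) -> CellModelSpec:
    if region == "central":
        params = {**CENTRAL_PARAMS, **_common_params(), **_volumes(20.0)}
        y0 = INITIAL_STATE_CENTRAL
    elif region == "peripheral":
        params = {**PERIPHERAL_PARAMS, **_common_params(), **_volumes(65.0)}
        y0 = INITIAL_STATE_PERIPHERAL
    else:  # pragma: no cover
        raise ValueError(f"unknown region {region!r}")
    return CellModelSpec(
        name=f"boyett-{region}",
        family="boyett",
        region=region,
        state_labels=STATE_LABELS,
        initial_state=y0.copy(),
        param_names=PARAM_NAMES,
        parameters=params,
        current_labels=CURRENT_LABELS,
        rhs_fn=rhs,
        currents_fn=currents,
        cai_index=STATE_LABELS.index("cai"),
    )
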