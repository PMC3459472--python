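"""Kurata-family rabbit SAN cell models (central and peripheral).

Membrane and Ca2+-handling formulation after Kurata et al. (2002): L- and
T-type Ca2+ currents (with Ca2+-dependent inactivation of I_CaL), fast and
slow delayed rectifiers, 4-AP-sensitive currents, hyperpolarization-
activated current, Na+/K+ pump and Na+/Ca2+ exchanger, and a four-
compartment intracellular Ca2+ subsystem (subsarcolemmal space, myoplasm,
SR uptake and release stores with troponin/calmodulin/calsequestrin
buffers). Intracellular Na+ and K+ are held fixed. Following the study
design this family carries *no* sustained inward current, so the ISO action
on I_st is undefined for it.

The peripheral variant is a conductance-scaled version of the central cell
(capacitance 65 pF vs 32 pF, with the regional current-density gradients of
the rabbit SAN applied to I_CaL, I_Kr, I_Ks, I_to, I_sus and I_f). See
PROVENANCE.md.
"""

from __future__ import annotations

import math

import numpy as np

from ._compat import maybe_njit
from .base import CellModelSpec

_F = 96485.0
_RTF = 26.713
_FRT = 1.0 / _RTF

STATE_LABELS = (
    "v", "d_l", "f_l", "f_ca", "d_t", "f_t",
    "p_af", "p_as", "p_ik", "n", "q", "r", "y",
    "cai", "casub", "caup", "carel",
    "f_tc", "f_tmc", "f_tmm", "f_cmi", "f_cms", "f_cq",
)

PARAM_NAMES = (
    "cm", "g_cal", "g_cat", "g_kr", "g_ks", "g_to", "g_sus",
    "g_hna", "g_hk", "k_naca", "i_nakmax",
    "nao", "nai", "ko", "ki", "cao", "e_cal", "e_cat",
    "v_shift_f", "v_shift_kr", "taukr_rate_scale",
    "p_up", "k_up", "p_rel", "k_rel", "tau_tr", "tau_difca",
    "v_i", "v_sub", "v_up", "v_rel", "k_leak",
)

CURRENT_LABELS = (
    "i_cal", "i_cat", "i_kr", "i_ks", "i_to", "i_sus",
    "i_f_na", "i_f_k", "i_naca", "i_nak",
)

_KF_TC, _KB_TC = 88.8, 0.446
_KF_TMC, _KB_TMC = 227.7, 0.00751
_KF_TMM, _KB_TMM = 2.277, 0.751
_KF_CM, _KB_CM = 227.7, 0.542
_KF_CQ, _KB_CQ = 0.534, 0.445
_TC_TOT, _TMC_TOT, _CM_TOT, _CQ_TOT = 0.031, 0.062, 0.045, 10.0
_MG = 2.5


def _lin_exp(a, x, s):
    r = x / s
    if abs(r) < 1e-6:
        return a * s * (1.0 - 0.5 * r)
    return a * x / math.expm1(r)


def _rhs(t, y, p):
    cm = p[0]; g_cal = p[1]; g_cat = p[2]; g_kr = p[3]; g_ks = p[4]
    g_to = p[5]; g_sus = p[6]; g_hna = p[7]; g_hk = p[8]; k_naca = p[9]
    i_nakmax = p[10]; nao = p[11]; nai = p[12]; ko = p[13]; ki = p[14]
    cao = p[15]; e_cal = p[16]; e_cat = p[17]
    v_shift_f = p[18]; v_shift_kr = p[19]; taukr_scale = p[20]
    p_up = p[21]; k_up = p[22]; p_rel = p[23]; k_rel = p[24]
    tau_tr = p[25]; tau_difca = p[26]
    v_i = p[27]; v_sub = p[28]; v_up = p[29]; v_rel = p[30]
    k_leak = p[31]

    v = y[0]; d_l = y[1]; f_l = y[2]; f_ca = y[3]; d_t = y[4]; f_t = y[5]
    p_af = y[6]; p_as = y[7]; p_ik = y[8]; n = y[9]; q = y[10]; r = y[11]
    yf = y[12]
    cai = y[13]; casub = y[14]; caup = y[15]; carel = y[16]
    f_tc = y[17]; f_tmc = y[18]; f_tmm = y[19]; f_cmi = y[20]
    f_cms = y[21]; f_cq = y[22]

    if cai < 1e-10:
        cai = 1e-10
    if casub < 1e-10:
        casub = 1e-10

    e_na = _RTF * math.log(nao / nai)
    e_k = _RTF * math.log(ko / ki)

    i_cal = g_cal * d_l * f_l * f_ca * (v - e_cal)
    i_cat = g_cat * d_t * f_t * (v - e_cat)
    i_kr = g_kr * (0.6 * p_af + 0.4 * p_as) * p_ik * (v - e_k)
    i_ks = g_ks * n * n * (v - e_k)
    i_to = g_to * q * r * (v - e_k)
    i_sus = g_sus * r * (v - e_k)
    i_f_na = g_hna * yf * yf * (v - e_na)
    i_f_k = g_hk * yf * yf * (v - e_k)
    x1 = nai ** 3 * cao * math.exp(0.03743 * v * 0.5)
    x2 = nao ** 3 * casub * math.exp(0.03743 * v * (0.5 - 1.0))
    i_naca = k_naca * (x1 - x2) / (1.0 + 0.0001 * (casub * nao ** 3 + cao * nai ** 3))
    i_nak = (i_nakmax
             / (1.0 + (1.4 / ko) ** 1.2)
             / (1.0 + (14.0 / nai) ** 1.3)
             / (1.0 + math.exp(-(v - e_na + 120.0) / 30.0)))

    i_tot = (i_cal + i_cat + i_kr + i_ks + i_to + i_sus + i_f_na + i_f_k
             + i_naca + i_nak)

    dy = np.empty(23)
    dy[0] = -i_tot / cm

    # I_CaL gating
    a = _lin_exp(-0.02839, v + 35.0, -2.5) + _lin_exp(-0.0849, v, -4.8077)
    b = _lin_exp(0.01143, v - 5.0, 2.5)
    dl_inf = 1.0 / (1.0 + math.exp(-(v + 14.1) / 6.0))
    dy[1] = (dl_inf - d_l) * (a + b)
    fl_inf = 1.0 / (1.0 + math.exp((v + 30.0) / 5.0))
    tau_fl = 257.1 * math.exp(-(((v + 32.5) / 13.9) ** 2)) + 44.3
    dy[2] = (fl_inf - f_l) / tau_fl
    fca_inf = 0.00035 / (0.00035 + casub)
    dy[3] = (fca_inf - f_ca) * 0.021 / fca_inf

    # I_CaT gating
    dt_inf = 1.0 / (1.0 + math.exp(-(v + 37.0) / 6.8))
    tau_dt = 1.0 / (1.068 * math.exp((v + 26.3) / 30.0)
                    + 1.068 * math.exp(-(v + 26.3) / 30.0))
    ft_inf = 1.0 / (1.0 + math.exp((v + 61.7) / 5.6))
    tau_ft = 1.0 / (0.0153 * math.exp(-(v + 61.7) / 83.3)
                    + 0.015 * math.exp((v + 61.7) / 15.38))
    dy[4] = (dt_inf - d_t) / tau_dt
    dy[5] = (ft_inf - f_t) / tau_ft

    # I_Kr gating (ISO hooks identical to the Boyett family)
    vk = v - v_shift_kr
    pa_inf = 1.0 / (1.0 + math.exp(-(vk + 23.2) / 10.6))
    tau_paf = 0.84655354 / (0.0372 * math.exp(v / 15.9)
                            + 0.00096 * math.exp(-v / 22.5)) / taukr_scale
    tau_pas = 0.84655354 / (0.0042 * math.exp(v / 17.0)
                            + 0.00015 * math.exp(-v / 21.6)) / taukr_scale
    pik_inf = 1.0 / (1.0 + math.exp((v + 28.6) / 17.1))
    tau_pik = 1.0 / (0.1 * math.exp(-v / 54.645) + 0.656 * math.exp(v / 106.157))
    dy[6] = (pa_inf - p_af) / tau_paf
    dy[7] = (pa_inf - p_as) / tau_pas
    dy[8] = (pik_inf - p_ik) / tau_pik

    # I_Ks gating
    a = 0.014 / (1.0 + math.exp(-(v - 40.0) / 9.0))
    b = 0.001 * math.exp(-v / 45.0)
    dy[9] = (a / (a + b) - n) * (a + b)

    # 4-AP-sensitive currents
    q_inf = 1.0 / (1.0 + math.exp((v + 49.0) / 13.0))
    tau_q = 6.06 + 39.102 / (0.57 * math.exp(-0.08 * (v + 44.0))
                             + 0.065 * math.exp(0.1 * (v + 45.93)))
    r_inf = 1.0 / (1.0 + math.exp(-(v - 19.3) / 15.0))
    tau_r = 2.75 + 14.40516 / (1.037 * math.exp(0.09 * (v + 30.61))
                               + 0.369 * math.exp(-0.12 * (v + 23.84)))
    dy[10] = (q_inf - q) / tau_q
    dy[11] = (r_inf - r) / tau_r

    # I_f activation; ISO shifts the steady state only
    y_inf = 1.0 / (1.0 + math.exp((v - v_shift_f + 64.0) / 13.5))
    tau_y = 0.7166529 / (math.exp(-(v + 386.9) / 45.302)
                         + math.exp((v - 73.08) / 19.231))
    dy[12] = (y_inf - yf) / tau_y

    # Ca2+ handling
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

    ca_influx = -(i_cal + i_cat - 2.0 * i_naca) / (2.0 * _F * v_sub) * 1e-3

    dy[13] = (j_dif * v_sub - j_up * v_up + j_leak * v_rel) / v_i - (
        _CM_TOT * dfcmi + _TC_TOT * dftc + _TMC_TOT * dftmc)
    dy[14] = ca_influx + j_rel * v_rel / v_sub - j_dif - _CM_TOT * dfcms
    dy[15] = j_up - j_tr * v_rel / v_up
    dy[16] = j_tr - j_rel - j_leak - _CQ_TOT * dfcq
    dy[17] = dftc
    dy[18] = dftmc
    dy[19] = dftmm
    dy[20] = dfcmi
    dy[21] = dfcms
    dy[22] = dfcq
    return dy


def _currents(y, p):
    g_cal = p[1]; g_cat = p[2]; g_kr = p[3]; g_ks = p[4]
    g_to = p[5]; g_sus = p[6]; g_hna = p[7]; g_hk = p[8]; k_naca = p[9]
    i_nakmax = p[10]; nao = p[11]; nai = p[12]; ko = p[13]; ki = p[14]
    cao = p[15]; e_cal = p[16]; e_cat = p[17]

    v = y[0]; d_l = y[1]; f_l = y[2]; f_ca = y[3]; d_t = y[4]; f_t = y[5]
    p_af = y[6]; p_as = y[7]; p_ik = y[8]; n = y[9]; q = y[10]; r = y[11]
    yf = y[12]; casub = y[14]
    if casub < 1e-10:
        casub = 1e-10

    e_na = _RTF * math.log(nao / nai)
    e_k = _RTF * math.log(ko / ki)

    out = np.empty(10)
    out[0] = g_cal * d_l * f_l * f_ca * (v - e_cal)
    out[1] = g_cat * d_t * f_t * (v - e_cat)
    out[2] = g_kr * (0.6 * p_af + 0.4 * p_as) * p_ik * (v - e_k)
    out[3] = g_ks * n * n * (v - e_k)
    out[4] = g_to * q * r * (v - e_k)
    out[5] = g_sus * r * (v - e_k)
    out[6] = g_hna * yf * yf * (v - e_na)
    out[7] = g_hk * yf * yf * (v - e_k)
    x1 = nai ** 3 * cao * math.exp(0.03743 * v * 0.5)
    x2 = nao ** 3 * casub * math.exp(0.03743 * v * (0.5 - 1.0))
    out[8] = k_naca * (x1 - x2) / (1.0 + 0.0001 * (casub * nao ** 3 + cao * nai ** 3))
    out[9] = (i_nakmax / (1.0 + (1.4 / ko) ** 1.2) / (1.0 + (14.0 / nai) ** 1.3)
              / (1.0 + math.exp(-(v - e_na + 120.0) / 30.0)))
    return out


_lin_exp = maybe_njit(_lin_exp)
rhs = maybe_njit(_rhs)
currents = maybe_njit(_currents)


def _volumes(cm_pf: float) -> dict:
    v_cell = 3.5e-6 * cm_pf / 32.0
    v_sub = 0.01 * v_cell
    return {
        "v_i": 0.46 * v_cell - v_sub,
        "v_sub": v_sub,
        "v_up": 0.0116 * v_cell,
        "v_rel": 0.0012 * v_cell,
    }


def _common_params() -> dict:
    return {
        "nao": 140.0, "nai": 9.63, "ko": 5.4, "ki": 140.0, "cao": 2.0,
        "e_cal": 45.0, "e_cat": 45.0,
        "v_shift_f": 0.0, "v_shift_kr": 0.0, "taukr_rate_scale": 1.0,
        "p_up": 0.005, "k_up": 0.0006, "p_rel": 5.0, "k_rel": 0.0012,
        "tau_tr": 60.0, "tau_difca": 0.04, "k_leak": 0.02,
    }


_CM_CENTRAL = 32.0   # pF
_CM_PERIPH = 65.0

# Central conductance densities (nS/pF), converted to uS at build time.
# Calibrated against the published central-cell control action potential
# (cycle length, overshoot, APD, upstroke velocity, Ca2+ transient); see
# PROVENANCE.md for the calibration record.
_DENS_CENTRAL = {
    "g_cal": 0.58, "g_cat": 0.229, "g_kr": 0.0649, "g_ks": 0.0259,
    "g_to": 0.09, "g_sus": 0.02,
    "g_hna": 0.1071 * 0.3833, "g_hk": 0.1071 * 0.6167,
}

# Centre -> periphery density gradients (from the regional current-density
# ratios of the rabbit SAN used by the Zhang-family models, except the
# delayed rectifiers, reduced so the peripheral cell remains a robust
# oscillator over the full ISO range; see PROVENANCE.md).
_PERIPH_GRADIENT = {
    "g_cal": 3.5, "g_kr": 1.5, "g_ks": 1.5, "g_to": 2.3, "g_sus": 5.3,
    "g_hna": 3.9, "g_hk": 3.9, "g_cat": 1.0,
}

INITIAL_STATE_CENTRAL = np.array([
    -73.09961737, 5.366900769e-05, 0.8228593081, 0.7301498358, 0.004923746492,
    0.6755515738, 0.1372305666, 0.4868409721, 0.9309874172, 0.05170924198,
    0.8487196192, 0.002111552518, 0.1013689241, 0.0002227288526, 8.805307916e-05,
    1.111356355, 0.1179745235, 0.04287815552, 0.5370044652, 0.408856099,
    0.08618704599, 0.03581037836, 0.1220492112,
])

INITIAL_STATE_PERIPHERAL = np.array([
    -70.31772574, 8.540311703e-05, 0.6919825478, 0.6168660462, 0.007394294295,
    0.5202123431, 0.2609983214, 0.609618758, 0.9197377519, 0.07378125094,
    0.7711105141, 0.002547144151, 0.07358616685, 0.0003742063154, 0.0001323584502,
    1.539905868, 0.1051171797, 0.07050794255, 0.6747772451, 0.2870683714,
    0.1374525119, 0.05312852387, 0.1092082767,
])


def build(region: str) -> CellModelSpec:
    if region == "central":
        cm_pf = _CM_CENTRAL
        dens = dict(_DENS_CENTRAL)
        y0 = INITIAL_STATE_CENTRAL
        k_naca = 3.44e-5
        i_nakmax = 3.6e-3 * cm_pf  # 3.6 pA/pF -> nA
    elif region == "peripheral":
        cm_pf = _CM_PERIPH
        dens = {k: v * _PERIPH_GRADIENT.get(k, 1.0) for k, v in _DENS_CENTRAL.items()}
        y0 = INITIAL_STATE_PERIPHERAL
        k_naca = 3.44e-5 * cm_pf / _CM_CENTRAL
        i_nakmax = 3.6e-3 * cm_pf
    else:  # pragma: no cover
        raise ValueError(f"unknown region {region!r}")
    params = {
        "cm": cm_pf * 1e-3,  # nF
        **{k: v * cm_pf * 1e-3 for k, v in dens.items()},  # nS/pF -> uS
        "k_naca": k_naca,
        "i_nakmax": i_nakmax,
        **_common_params(),
        **_volumes(cm_pf),
    }
    return CellModelSpec(
        name=f"kurata-{region}",
        family="kurata",
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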