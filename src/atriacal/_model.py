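"""Core ionic-model equations (scalar, numba-jitted).

The model is the Courtemanche-Ramirez-Nattel (CRN) human atrial cell with the
transient-outward current gating replaced by the Maleckar r/s kinetics, a
fixed 2.0 ms time constant for the Ca-dependent inactivation gate of I_CaL,
and the L-type conductance expressed as a wild-type/mutant mixture.  All
constants live in ``data/model_parameters.yaml`` and are loaded once at
import; the jitted functions freeze them at compile time.

State vector layout (length 21)::

    0  Vm    5  s     10 d     15 w       20 Ca_rel
    1  m     6  ua    11 f     16 Na_i
    2  h     7  ui    12 hCa   17 K_i
    3  j     8  xr    13 u     18 Ca_i
    4  r     9  xs    14 v     19 Ca_up

Effective per-cell parameter vector (length 12) -- maximal conductances /
pump rates after regional scaling and the I_CaL mixture factor::

    0 g_Na  1 g_K1  2 g_to  3 g_Kur_scale  4 g_Kr  5 g_Ks  6 g_CaL_eff
    7 g_bCa 8 g_bNa 9 I_NaK_max 10 I_NaCa_max 11 I_pCa_max
"""

from __future__ import annotations

import hashlib
import importlib.resources as _res
import math

import numba
import numpy as np
import yaml

N_STATE = 21
N_EFF = 12

# index aliases
IV, IM, IH, IJ, IR, IS, IUA, IUI, IXR, IXS, ID, IF, IHCA, IU, IVG, IW = range(16)
INAI, IKI, ICAI, ICAUP, ICAREL = 16, 17, 18, 19, 20


def _load_manifest() -> dict:
    with _res.files("atriacal.data").joinpath("model_parameters.yaml").open() as fh:
        return yaml.safe_load(fh)


MANIFEST = _load_manifest()


def manifest_checksum() -> str:
    """SHA-256 of the parameter manifest, for embedding in result files."""
    raw = _res.files("atriacal.data").joinpath("model_parameters.yaml").read_bytes()
    return hashlib.sha256(raw).hexdigest()


_P = MANIFEST
R = float(_P["physical"]["R"])
T = float(_P["physical"]["T"])
F = float(_P["physical"]["F"])
RT_F = R * T / F

CM = float(_P["geometry"]["Cm"])
V_I = float(_P["geometry"]["V_i"])
V_UP = float(_P["geometry"]["V_up"])
V_REL = float(_P["geometry"]["V_rel"])

NA_O = float(_P["external_concentrations"]["Na_o"])
K_O = float(_P["external_concentrations"]["K_o"])
CA_O = float(_P["external_concentrations"]["Ca_o"])

G_NA = float(_P["max_conductances"]["g_Na"])
G_K1 = float(_P["max_conductances"]["g_K1"])
G_TO = float(_P["max_conductances"]["g_to"])
G_KR = float(_P["max_conductances"]["g_Kr"])
G_KS = float(_P["max_conductances"]["g_Ks"])
G_CAL = float(_P["max_conductances"]["g_CaL"])
G_BCA = float(_P["max_conductances"]["g_bCa"])
G_BNA = float(_P["max_conductances"]["g_bNa"])

I_NAK_MAX = float(_P["pumps_exchangers"]["I_NaK_max"])
KM_NA_I = float(_P["pumps_exchangers"]["Km_Na_i"])
KM_K_O = float(_P["pumps_exchangers"]["Km_K_o"])
I_NACA_MAX = float(_P["pumps_exchangers"]["I_NaCa_max"])
K_MNA = float(_P["pumps_exchangers"]["K_mNa"])
K_MCA = float(_P["pumps_exchangers"]["K_mCa"])
K_SAT = float(_P["pumps_exchangers"]["k_sat"])
GAMMA = float(_P["pumps_exchangers"]["gamma"])
I_PCA_MAX = float(_P["pumps_exchangers"]["I_pCa_max"])

E_CA_L = float(_P["ca_handling"]["E_Ca_L"])
TAU_HCA = float(_P["ca_handling"]["tau_hCa"])
K_REL = float(_P["ca_handling"]["K_rel"])
I_UP_MAX = float(_P["ca_handling"]["I_up_max"])
K_UP = float(_P["ca_handling"]["K_up"])
CA_UP_MAX = float(_P["ca_handling"]["Ca_up_max"])
TAU_TR = float(_P["ca_handling"]["tau_tr"])
TAU_U = float(_P["ca_handling"]["tau_u"])
CMDN_MAX = float(_P["ca_handling"]["CMDN_max"])
TRPN_MAX = float(_P["ca_handling"]["TRPN_max"])
CSQN_MAX = float(_P["ca_handling"]["CSQN_max"])
KM_CMDN = float(_P["ca_handling"]["Km_CMDN"])
KM_TRPN = float(_P["ca_handling"]["Km_TRPN"])
KM_CSQN = float(_P["ca_handling"]["Km_CSQN"])
K_Q10 = float(_P["ca_handling"]["K_Q10"])

SIGMA_NAK = (math.exp(NA_O / 67.3) - 1.0) / 7.0
NACA_DENOM0 = (K_MNA ** 3 + NA_O ** 3) * (K_MCA + CA_O)

# V-dependent gate ordering used by rate tables: the 12 Hodgkin-Huxley gates
# whose steady state / time constant depend on Vm only.
N_VGATES = 12
VGATE_STATE_IDX = np.array([IM, IH, IJ, IR, IS, IUA, IUI, IXR, IXS, ID, IF, IW])


def initial_state() -> np.ndarray:
    s0 = _P["initial_state"]
    y = np.empty(N_STATE)
    order = ["Vm", "m", "h", "j", "r", "s", "ua", "ui", "xr", "xs", "d", "f",
             "hCa", "u", "v", "w", "Na_i", "K_i", "Ca_i", "Ca_up", "Ca_rel"]
    for k, name in enumerate(order):
        y[k] = float(s0[name])
    return y


@numba.njit(cache=True)
def _safe_ratio(num, den):
    # removable singularities of the alpha/beta rate expressions
    if abs(den) < 1e-12:
        return 0.0
    return num / den


@numba.njit(cache=True)
def gate_rates(V, inf, tau):
    """Steady states and time constants of the 12 V-dependent gates."""
    # INa m gate (singularity at V = -47.13)
    dv = V + 47.13
    if abs(dv) < 1e-10:
        a_m = 3.2
    else:
        a_m = 0.32 * dv / (1.0 - math.exp(-0.1 * dv))
    b_m = 0.08 * math.exp(-V / 11.0)
    inf[0] = a_m / (a_m + b_m)
    tau[0] = 1.0 / (a_m + b_m)

    # INa h, j gates (piecewise at -40 mV)
    if V >= -40.0:
        a_h = 0.0
        b_h = 1.0 / (0.13 * (1.0 + math.exp(-(V + 10.66) / 11.1)))
        a_j = 0.0
        b_j = 0.3 * math.exp(-2.535e-7 * V) / (1.0 + math.exp(-0.1 * (V + 32.0)))
    else:
        a_h = 0.135 * math.exp(-(V + 80.0) / 6.8)
        b_h = 3.56 * math.exp(0.079 * V) + 3.1e5 * math.exp(0.35 * V)
        a_j = ((-1.2714e5 * math.exp(0.2444 * V) - 3.474e-5 * math.exp(-0.04391 * V))
               * (V + 37.78) / (1.0 + math.exp(0.311 * (V + 79.23))))
        b_j = 0.1212 * math.exp(-0.01052 * V) / (1.0 + math.exp(-0.1378 * (V + 40.14)))
    inf[1] = a_h / (a_h + b_h)
    tau[1] = 1.0 / (a_h + b_h)
    inf[2] = a_j / (a_j + b_j)
    tau[2] = 1.0 / (a_j + b_j)

    # Ito r (activation) and s (inactivation), Maleckar kinetics (ms)
    inf[3] = 1.0 / (1.0 + math.exp(-(V - 1.0) / 11.0))
    tau[3] = 3.5 * math.exp(-(V / 30.0) ** 2) + 1.5
    inf[4] = 1.0 / (1.0 + math.exp((V + 40.5) / 11.5))
    tau[4] = 25.635 * math.exp(-((V + 52.45) / 15.8827) ** 2) + 14.14

    # IKur ua, ui
    a_ua = 0.65 / (math.exp(-(V + 10.0) / 8.5) + math.exp(-(V - 30.0) / 59.0))
    b_ua = 0.65 / (2.5 + math.exp((V + 82.0) / 17.0))
    inf[5] = 1.0 / (1.0 + math.exp(-(V + 30.3) / 9.6))
    tau[5] = 1.0 / ((a_ua + b_ua) * K_Q10)
    a_ui = 1.0 / (21.0 + math.exp(-(V - 185.0) / 28.0))
    b_ui = math.exp((V - 158.0) / 16.0)
    inf[6] = 1.0 / (1.0 + math.exp((V - 99.45) / 27.48))
    tau[6] = 1.0 / ((a_ui + b_ui) * K_Q10)

    # IKr xr
    dv = V + 14.1
    if abs(dv) < 1e-10:
        a_xr = 0.0015
    else:
        a_xr = 0.0003 * dv / (1.0 - math.exp(-dv / 5.0))
    dv = V - 3.3328
    if abs(dv) < 1e-10:
        b_xr = 3.7836118e-4
    else:
        b_xr = 7.3898e-5 * dv / (math.exp(dv / 5.1237) - 1.0)
    inf[7] = 1.0 / (1.0 + math.exp(-(V + 14.1) / 6.5))
    tau[7] = 1.0 / (a_xr + b_xr)

    # IKs xs
    dv = V - 19.9
    if abs(dv) < 1e-10:
        a_xs = 0.00068
        b_xs = 0.000315
    else:
        a_xs = 4e-5 * dv / (1.0 - math.exp(-dv / 17.0))
        b_xs = 3.5e-5 * dv / (math.exp(dv / 9.0) - 1.0)
    inf[8] = 1.0 / math.sqrt(1.0 + math.exp(-(V - 19.9) / 12.7))
    tau[8] = 0.5 / (a_xs + b_xs)

    # ICaL d, f
    dv = V + 10.0
    if abs(dv) < 1e-10:
        tau[9] = 4.579 / (1.0 + math.exp(-dv / 6.24))
    else:
        tau[9] = (1.0 - math.exp(-dv / 6.24)) / (0.035 * dv * (1.0 + math.exp(-dv / 6.24)))
    inf[9] = 1.0 / (1.0 + math.exp(-dv / 8.0))
    inf[10] = 1.0 / (1.0 + math.exp((V + 28.0) / 6.9))
    tau[10] = 9.0 / (0.0197 * math.exp(-(0.0337 ** 2) * dv * dv) + 0.02)

    # SR release w gate
    dv = V - 7.9
    if abs(dv) < 1e-10:
        tau[11] = 6.0 * 0.2 / 1.3
    else:
        tau[11] = 6.0 * (1.0 - math.exp(-dv / 5.0)) / ((1.0 + 0.3 * math.exp(-dv / 5.0)) * dv)
    inf[11] = 1.0 - 1.0 / (1.0 + math.exp(-(V - 40.0) / 17.0))


@numba.njit(cache=True)
def compute_currents_arr(y, eff, out):
    """All membrane current densities (pA/pF) plus SR fluxes.

    ``out`` (length 18): 0 ICaL, 1 INa, 2 IK1, 3 Ito, 4 IKur, 5 IKr, 6 IKs,
    7 INaCa, 8 INaK, 9 IbNa, 10 IbCa, 11 IpCa, 12 Iion_tot,
    13 Irel, 14 Itr, 15 Iup, 16 Iupleak, 17 Fn.
    """
    V = y[IV]
    na_i = y[INAI]
    k_i = y[IKI]
    ca_i = y[ICAI]

    e_na = RT_F * math.log(NA_O / na_i)
    e_k = RT_F * math.log(K_O / k_i)
    e_ca = 0.5 * RT_F * math.log(CA_O / ca_i)

    i_na = eff[0] * y[IM] ** 3 * y[IH] * y[IJ] * (V - e_na)
    i_k1 = eff[1] * (V - e_k) / (1.0 + math.exp(0.07 * (V + 80.0)))
    i_to = eff[2] * y[IR] * y[IS] * (V - e_k)
    g_kur = 0.005 + 0.05 / (1.0 + math.exp(-(V - 15.0) / 13.0))
    i_kur = eff[3] * g_kur * y[IUA] ** 3 * y[IUI] * (V - e_k)
    i_kr = eff[4] * y[IXR] * (V - e_k) / (1.0 + math.exp((V + 15.0) / 22.4))
    i_ks = eff[5] * y[IXS] ** 2 * (V - e_k)
    i_cal = eff[6] * y[ID] * y[IF] * y[IHCA] * (V - E_CA_L)

    f_nak = 1.0 / (1.0 + 0.1245 * math.exp(-0.1 * V / RT_F)
                   + 0.0365 * SIGMA_NAK * math.exp(-V / RT_F))
    i_nak = eff[9] * f_nak * (K_O / (K_O + KM_K_O)) / (1.0 + (KM_NA_I / na_i) ** 1.5)

    ex1 = math.exp(GAMMA * V / RT_F)
    ex2 = math.exp((GAMMA - 1.0) * V / RT_F)
    denom = NACA_DENOM0 * (1.0 + K_SAT * ex2)
    i_naca = eff[10] * (ex1 * na_i ** 3 * CA_O - ex2 * NA_O ** 3 * ca_i) / denom

    i_bna = eff[8] * (V - e_na)
    i_bca = eff[7] * (V - e_ca)
    i_pca = eff[11] * ca_i / (0.0005 + ca_i)

    i_rel = K_REL * y[IU] ** 2 * y[IVG] * y[IW] * (y[ICAREL] - ca_i)
    i_tr = (y[ICAUP] - y[ICAREL]) / TAU_TR
    i_up = I_UP_MAX / (1.0 + K_UP / ca_i)
    i_upleak = I_UP_MAX * y[ICAUP] / CA_UP_MAX
    fn = 1e-12 * V_REL * i_rel - (5e-13 / F) * (0.5 * i_cal - 0.2 * i_naca) * CM

    out[0] = i_cal
    out[1] = i_na
    out[2] = i_k1
    out[3] = i_to
    out[4] = i_kur
    out[5] = i_kr
    out[6] = i_ks
    out[7] = i_naca
    out[8] = i_nak
    out[9] = i_bna
    out[10] = i_bca
    out[11] = i_pca
    out[12] = (i_cal + i_na + i_k1 + i_to + i_kur + i_kr + i_ks + i_naca
               + i_nak + i_bna + i_bca + i_pca)
    out[13] = i_rel
    out[14] = i_tr
    out[15] = i_up
    out[16] = i_upleak
    out[17] = fn


@numba.njit(cache=True)
def derivatives(y, eff, i_st):
    """Time derivative of the full state (for adaptive reference solves).

    ``i_st`` is the stimulus current density with the membrane-equation sign
    convention (negative = depolarising).
    """
    cur = np.empty(18)
    compute_currents_arr(y, eff, cur)
    inf = np.empty(N_VGATES)
    tau = np.empty(N_VGATES)
    gate_rates(y[IV], inf, tau)

    dy = np.empty(N_STATE)
    dy[IV] = -(cur[12] + i_st)

    # V-dependent HH gates
    dy[IM] = (inf[0] - y[IM]) / tau[0]
    dy[IH] = (inf[1] - y[IH]) / tau[1]
    dy[IJ] = (inf[2] - y[IJ]) / tau[2]
    dy[IR] = (inf[3] - y[IR]) / tau[3]
    dy[IS] = (inf[4] - y[IS]) / tau[4]
    dy[IUA] = (inf[5] - y[IUA]) / tau[5]
    dy[IUI] = (inf[6] - y[IUI]) / tau[6]
    dy[IXR] = (inf[7] - y[IXR]) / tau[7]
    dy[IXS] = (inf[8] - y[IXS]) / tau[8]
    dy[ID] = (inf[9] - y[ID]) / tau[9]
    dy[IF] = (inf[10] - y[IF]) / tau[10]
    dy[IW] = (inf[11] - y[IW]) / tau[11]

    # Ca-dependent inactivation, fixed time constant
    hca_inf = 1.0 / (1.0 + y[ICAI] / 0.00035)
    dy[IHCA] = (hca_inf - y[IHCA]) / TAU_HCA

    # SR release u, v gates driven by Fn
    fn = cur[17]
    e1 = math.exp(-(fn - 3.4175e-13) / 13.67e-16)
    u_inf = 1.0 / (1.0 + e1)
    tau_v = 1.91 + 2.09 / (1.0 + e1)
    v_inf = 1.0 - 1.0 / (1.0 + math.exp(-(fn - 6.835e-14) / 13.67e-16))
    dy[IU] = (u_inf - y[IU]) / TAU_U
    dy[IVG] = (v_inf - y[IVG]) / tau_v

    # concentrations
    i_cal, i_na, i_k1, i_to, i_kur, i_kr, i_ks = (cur[0], cur[1], cur[2], cur[3],
                                                  cur[4], cur[5], cur[6])
    i_naca, i_nak, i_bna, i_bca, i_pca = cur[7], cur[8], cur[9], cur[10], cur[11]
    i_rel, i_tr, i_up, i_upleak = cur[13], cur[14], cur[15], cur[16]

    dy[INAI] = (-3.0 * i_nak - 3.0 * i_naca - i_bna - i_na) * CM / (F * V_I)
    dy[IKI] = (2.0 * i_nak - i_k1 - i_to - i_kur - i_kr - i_ks) * CM / (F * V_I)

    ca_i = y[ICAI]
    b1 = ((2.0 * i_naca - i_pca - i_cal - i_bca) * CM / (2.0 * F * V_I)
          + (V_UP * (i_upleak - i_up) + i_rel * V_REL) / V_I)
    b2 = (1.0 + TRPN_MAX * KM_TRPN / (ca_i + KM_TRPN) ** 2
          + CMDN_MAX * KM_CMDN / (ca_i + KM_CMDN) ** 2)
    dy[ICAI] = b1 / b2
    dy[ICAUP] = i_up - i_upleak - i_tr * V_REL / V_UP
    ca_rel = y[ICAREL]
    dy[ICAREL] = (i_tr - i_rel) / (1.0 + CSQN_MAX * KM_CSQN / (ca_rel + KM_CSQN) ** 2)
    return dy


@numba.njit(cache=True)
def step_rl(y, eff, stim_amp, dt):
    """One forward-Euler / Rush-Larsen step in place.

    ``stim_amp`` is a positive depolarising stimulus magnitude (pA/pF); the
    sign flip of the membrane equation is applied internally.
    """
    cur = np.empty(18)
    compute_currents_arr(y, eff, cur)
    inf = np.empty(N_VGATES)
    tau = np.empty(N_VGATES)
    gate_rates(y[IV], inf, tau)

    # Rush-Larsen exponential update of HH gates
    for k in range(N_VGATES):
        idx = VGATE_STATE_IDX[k]
        y[idx] = inf[k] + (y[idx] - inf[k]) * math.exp(-dt / tau[k])

    hca_inf = 1.0 / (1.0 + y[ICAI] / 0.00035)
    y[IHCA] = hca_inf + (y[IHCA] - hca_inf) * math.exp(-dt / TAU_HCA)

    fn = cur[17]
    e1 = math.exp(-(fn - 3.4175e-13) / 13.67e-16)
    u_inf = 1.0 / (1.0 + e1)
    tau_v = 1.91 + 2.09 / (1.0 + e1)
    v_inf = 1.0 - 1.0 / (1.0 + math.exp(-(fn - 6.835e-14) / 13.67e-16))
    y[IU] = u_inf + (y[IU] - u_inf) * math.exp(-dt / TAU_U)
    y[IVG] = v_inf + (y[IVG] - v_inf) * math.exp(-dt / tau_v)

    i_naca, i_nak, i_bna, i_bca, i_pca = cur[7], cur[8], cur[9], cur[10], cur[11]
    i_rel, i_tr, i_up, i_upleak = cur[13], cur[14], cur[15], cur[16]
    y[INAI] += dt * (-3.0 * i_nak - 3.0 * i_naca - i_bna - cur[1]) * CM / (F * V_I)
    y[IKI] += dt * (2.0 * i_nak - cur[2] - cur[3] - cur[4] - cur[5] - cur[6]) * CM / (F * V_I)

    ca_i = y[ICAI]
    b1 = ((2.0 * i_naca - i_pca - cur[0] - i_bca) * CM / (2.0 * F * V_I)
          + (V_UP * (i_upleak - i_up) + i_rel * V_REL) / V_I)
    b2 = (1.0 + TRPN_MAX * KM_TRPN / (ca_i + KM_TRPN) ** 2
          + CMDN_MAX * KM_CMDN / (ca_i + KM_CMDN) ** 2)
    y[ICAI] += dt * b1 / b2
    y[ICAUP] += dt * (i_up - i_upleak - i_tr * V_REL / V_UP)
    ca_rel = y[ICAREL]
    y[ICAREL] += dt * (i_tr - i_rel) / (1.0 + CSQN_MAX * KM_CSQN / (ca_rel + KM_CSQN) ** 2)

    y[IV] += dt * (-(cur[12] - stim_amp))
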