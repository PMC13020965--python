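"""Courtemanche–Ramirez–Nattel human atrial ionic model (21 state variables).

State layout (per node): Vm (mV), 15 Hodgkin–Huxley-type gates in [0, 1]
(m, h, j, oa, oi, ua, ui, xr, xs, d, f, fCa, u, v, w), and 5 concentrations
in mM (Nai, Ki, Cai, Caup, Carel). Current densities are in pA/pF, which with
Cm = 1 μF/cm² equal μA/cm² numerically, and dV/dt is in mV/ms.

Two entry points:

- :func:`courtemanche_rhs` — full right-hand side (all time derivatives),
  used for reference integrations and oracle tests;
- :func:`ionic_step` / :func:`step_nodes` — the production update: gates by
  Rush–Larsen exponential integration, Vm and concentrations by forward
  Euler. Fully explicit; stable at dt = 0.01–0.02 ms for tissue runs and can
  be pushed down to 0.001 ms.

A depolarizing stimulus is passed as a positive amplitude in pA/pF.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit, prange

__all__ = [
    "NSTATE",
    "GATE_IDX",
    "initial_state",
    "courtemanche_rhs",
    "ionic_step",
    "step_nodes",
]

NSTATE = 21
# state indices
IV = 0
IM, IH, IJ = 1, 2, 3
IOA, IOI = 4, 5
IUA, IUI = 6, 7
IXR, IXS = 8, 9
ID, IF, IFCA = 10, 11, 12
IU, IVG, IW = 13, 14, 15
INAI, IKI, ICAI, ICAUP, ICAREL = 16, 17, 18, 19, 20

GATE_IDX = (IM, IH, IJ, IOA, IOI, IUA, IUI, IXR, IXS, ID, IF, IFCA, IU, IVG, IW)

# physical constants
R_GAS = 8.3143  # J/(mol K)
TEMP = 310.0  # K
FARADAY = 96.4867  # C/mmol
CM_CELL = 100.0  # pF, model cell capacitance
V_I = 13668.0  # μm³ intracellular volume
V_UP = 1109.52  # μm³ SR uptake compartment
V_REL = 96.48  # μm³ SR release compartment
K_O, NA_O, CA_O = 5.4, 140.0, 1.8  # mM external

G_NA = 7.8  # nS/pF
G_K1 = 0.09
G_TO = 0.1652
G_KR = 0.029411765
G_KS = 0.12941176
G_CAL = 0.12375
G_B_CA = 0.001131
G_B_NA = 0.0006744375
I_NAK_MAX = 0.59933874  # pA/pF
I_NACA_MAX = 1600.0
I_PCA_MAX = 0.275
I_UP_MAX = 0.005  # mM/ms
K_Q10 = 3.0
GAMMA = 0.35
KM_NAI, KM_KO = 10.0, 1.5
KM_NA, KM_CA, K_SAT = 87.5, 1.38, 0.1
K_REL = 30.0  # ms^-1
K_UP = 0.00092  # mM
CA_UP_MAX = 15.0
CMDN_MAX, TRPN_MAX, CSQN_MAX = 0.05, 0.07, 10.0
KM_CMDN, KM_TRPN, KM_CSQN = 0.00238, 0.0005, 0.8
TAU_TR, TAU_F_CA, TAU_U = 180.0, 2.0, 8.0


def initial_state() -> np.ndarray:
    """Published resting-state initial conditions (quiescent cell)."""
    y = np.empty(NSTATE)
    y[IV] = -81.18
    y[IM], y[IH], y[IJ] = 2.908e-3, 9.649e-1, 9.775e-1
    y[IOA], y[IOI] = 3.043e-2, 9.992e-1
    y[IUA], y[IUI] = 4.966e-3, 9.986e-1
    y[IXR], y[IXS] = 3.296e-5, 1.869e-2
    y[ID], y[IF], y[IFCA] = 1.367e-4, 9.996e-1, 7.755e-1
    y[IU], y[IVG], y[IW] = 0.0, 1.0, 9.992e-1
    y[INAI], y[IKI], y[ICAI] = 1.117e1, 1.39e2, 1.013e-4
    y[ICAUP], y[ICAREL] = 1.488, 1.488
    return y


@njit(cache=True, fastmath=True)
def _cell_rates(y, istim, inf, tau, dy):
    """Gate steady states/time constants + non-gate derivatives.

    Fills ``inf``/``tau`` at gate indices and ``dy`` at Vm/concentration
    indices; returns the total ionic current density Iion (pA/pF). ``istim``
    is a depolarizing stimulus density (pA/pF, positive inward).
    """
    V = y[IV]
    m, h, j = y[IM], y[IH], y[IJ]
    oa, oi = y[IOA], y[IOI]
    ua, ui = y[IUA], y[IUI]
    xr, xs = y[IXR], y[IXS]
    d, f, fca = y[ID], y[IF], y[IFCA]
    u, vg, w = y[IU], y[IVG], y[IW]
    Nai, Ki, Cai = y[INAI], y[IKI], y[ICAI]
    Caup, Carel = y[ICAUP], y[ICAREL]

    RT_F = R_GAS * TEMP / FARADAY
    E_Na = RT_F * math.log(NA_O / Nai)
    E_K = RT_F * math.log(K_O / Ki)
    E_Ca = 0.5 * RT_F * math.log(CA_O / Cai)

    # fast sodium current
    i_Na = G_NA * m * m * m * h * j * (V - E_Na)
    if abs(V + 47.13) < 1e-10:
        a_m = 3.2
    else:
        a_m = 0.32 * (V + 47.13) / (1.0 - math.exp(-0.1 * (V + 47.13)))
    b_m = 0.08 * math.exp(-V / 11.0)
    if V >= -40.0:
        a_h = 0.0
        b_h = 1.0 / (0.13 * (1.0 + math.exp(-(V + 10.66) / 11.1)))
        a_j = 0.0
        b_j = 0.3 * math.exp(-2.535e-7 * V) / (1.0 + math.exp(-0.1 * (V + 32.0)))
    else:
        a_h = 0.135 * math.exp(-(V + 80.0) / 6.8)
        b_h = 3.56 * math.exp(0.079 * V) + 3.1e5 * math.exp(0.35 * V)
        a_j = (
            (-1.2714e5 * math.exp(0.2444 * V) - 3.474e-5 * math.exp(-0.04391 * V))
            * (V + 37.78)
            / (1.0 + math.exp(0.311 * (V + 79.23)))
        )
        b_j = 0.1212 * math.exp(-0.01052 * V) / (1.0 + math.exp(-0.1378 * (V + 40.14)))
    inf[IM] = a_m / (a_m + b_m)
    tau[IM] = 1.0 / (a_m + b_m)
    inf[IH] = a_h / (a_h + b_h)
    tau[IH] = 1.0 / (a_h + b_h)
    inf[IJ] = a_j / (a_j + b_j)
    tau[IJ] = 1.0 / (a_j + b_j)

    # inward rectifier
    i_K1 = G_K1 * (V - E_K) / (1.0 + math.exp(0.07 * (V + 80.0)))

    # transient outward
    i_to = G_TO * oa * oa * oa * oi * (V - E_K)
    a_oa = 0.65 / (math.exp(-(V + 10.0) / 8.5) + math.exp(-(V - 30.0) / 59.0))
    b_oa = 0.65 / (2.5 + math.exp((V + 82.0) / 17.0))
    tau[IOA] = 1.0 / ((a_oa + b_oa) * K_Q10)
    inf[IOA] = 1.0 / (1.0 + math.exp(-(V + 20.47) / 17.54))
    a_oi = 1.0 / (18.53 + math.exp((V + 113.7) / 10.95))
    b_oi = 1.0 / (35.56 + math.exp(-(V + 1.26) / 7.44))
    tau[IOI] = 1.0 / ((a_oi + b_oi) * K_Q10)
    inf[IOI] = 1.0 / (1.0 + math.exp((V + 43.1) / 5.3))

    # ultrarapid delayed rectifier
    g_Kur = 0.005 + 0.05 / (1.0 + math.exp(-(V - 15.0) / 13.0))
    i_Kur = g_Kur * ua * ua * ua * ui * (V - E_K)
    a_ua = 0.65 / (math.exp(-(V + 10.0) / 8.5) + math.exp(-(V - 30.0) / 59.0))
    b_ua = 0.65 / (2.5 + math.exp((V + 82.0) / 17.0))
    tau[IUA] = 1.0 / ((a_ua + b_ua) * K_Q10)
    inf[IUA] = 1.0 / (1.0 + math.exp(-(V + 30.3) / 9.6))
    a_ui = 1.0 / (21.0 + math.exp(-(V - 185.0) / 28.0))
    b_ui = math.exp((V - 158.0) / 16.0)
    tau[IUI] = 1.0 / ((a_ui + b_ui) * K_Q10)
    inf[IUI] = 1.0 / (1.0 + math.exp((V - 99.45) / 27.48))

    # rapid delayed rectifier
    i_Kr = G_KR * xr * (V - E_K) / (1.0 + math.exp((V + 15.0) / 22.4))
    if abs(V + 14.1) < 1e-10:
        a_xr = 0.0015
    else:
        a_xr = 0.0003 * (V + 14.1) / (1.0 - math.exp(-(V + 14.1) / 5.0))
    if abs(V - 3.3328) < 1e-10:
        b_xr = 3.7836118e-4
    else:
        b_xr = (
            7.3898e-5 * (V - 3.3328) / (math.exp((V - 3.3328) / 5.1237) - 1.0)
        )
    tau[IXR] = 1.0 / (a_xr + b_xr)
    inf[IXR] = 1.0 / (1.0 + math.exp(-(V + 14.1) / 6.5))

    # slow delayed rectifier
    i_Ks = G_KS * xs * xs * (V - E_K)
    if abs(V - 19.9) < 1e-10:
        a_xs = 0.00068
        b_xs = 0.000315
    else:
        a_xs = 4e-5 * (V - 19.9) / (1.0 - math.exp(-(V - 19.9) / 17.0))
        b_xs = 3.5e-5 * (V - 19.9) / (math.exp((V - 19.9) / 9.0) - 1.0)
    tau[IXS] = 0.5 / (a_xs + b_xs)
    inf[IXS] = 1.0 / math.sqrt(1.0 + math.exp(-(V - 19.9) / 12.7))

    # L-type calcium
    i_CaL = G_CAL * d * f * fca * (V - 65.0)
    if abs(V + 10.0) < 1e-10:
        tau[ID] = 4.579 / (1.0 + math.exp(-(V + 10.0) / 6.24))
    else:
        tau[ID] = (1.0 - math.exp(-(V + 10.0) / 6.24)) / (
            0.035 * (V + 10.0) * (1.0 + math.exp(-(V + 10.0) / 6.24))
        )
    inf[ID] = 1.0 / (1.0 + math.exp(-(V + 10.0) / 8.0))
    inf[IF] = 1.0 / (1.0 + math.exp((V + 28.0) / 6.9))
    tau[IF] = 9.0 / (0.0197 * math.exp(-0.0337 * 0.0337 * (V + 10.0) * (V + 10.0)) + 0.02)
    inf[IFCA] = 1.0 / (1.0 + Cai / 0.00035)
    tau[IFCA] = TAU_F_CA

    # pumps and exchangers
    sigma_nak = (math.exp(NA_O / 67.3) - 1.0) / 7.0
    f_nak = 1.0 / (
        1.0
        + 0.1245 * math.exp(-0.1 * V / RT_F)
        + 0.0365 * sigma_nak * math.exp(-V / RT_F)
    )
    i_NaK = (
        I_NAK_MAX
        * f_nak
        / (1.0 + (KM_NAI / Nai) ** 1.5)
        * K_O
        / (K_O + KM_KO)
    )
    expg = math.exp(GAMMA * V / RT_F)
    expg1 = math.exp((GAMMA - 1.0) * V / RT_F)
    i_NaCa = (
        I_NACA_MAX
        * (expg * Nai**3 * CA_O - expg1 * NA_O**3 * Cai)
        / (
            (KM_NA**3 + NA_O**3)
            * (KM_CA + CA_O)
            * (1.0 + K_SAT * expg1)
        )
    )
    i_B_Na = G_B_NA * (V - E_Na)
    i_B_Ca = G_B_CA * (V - E_Ca)
    i_PCa = I_PCA_MAX * Cai / (0.0005 + Cai)

    # sarcoplasmic reticulum calcium handling (mM/ms)
    i_rel = K_REL * u * u * vg * w * (Carel - Cai)
    i_tr = (Caup - Carel) / TAU_TR
    i_up = I_UP_MAX / (1.0 + K_UP / Cai)
    i_up_leak = I_UP_MAX * Caup / CA_UP_MAX

    fn = 1e-12 * V_REL * i_rel - (5e-13 / FARADAY) * (
        0.5 * i_CaL * CM_CELL - 0.2 * i_NaCa * CM_CELL
    )
    inf[IU] = 1.0 / (1.0 + math.exp(-(fn - 3.4175e-13) / 13.67e-16))
    tau[IU] = TAU_U
    inf[IVG] = 1.0 - 1.0 / (1.0 + math.exp(-(fn - 6.835e-14) / 13.67e-16))
    tau[IVG] = 1.91 + 2.09 / (1.0 + math.exp(-(fn - 3.4175e-13) / 13.67e-16))
    inf[IW] = 1.0 - 1.0 / (1.0 + math.exp(-(V - 40.0) / 17.0))
    if abs(V - 7.9) < 1e-10:
        tau[IW] = 6.0 * 0.2 / 1.3
    else:
        tau[IW] = (
            6.0
            * (1.0 - math.exp(-(V - 7.9) / 5.0))
            / ((1.0 + 0.3 * math.exp(-(V - 7.9) / 5.0)) * (V - 7.9))
        )

    i_ion = (
        i_Na + i_K1 + i_to + i_Kur + i_Kr + i_Ks + i_CaL
        + i_PCa + i_NaK + i_NaCa + i_B_Na + i_B_Ca
    )
    # membrane potential (istim positive = depolarizing)
    dy[IV] = -i_ion + istim

    fvi = FARADAY * V_I
    dy[INAI] = CM_CELL * (-3.0 * i_NaK - 3.0 * i_NaCa - i_B_Na - i_Na) / fvi
    dy[IKI] = CM_CELL * (2.0 * i_NaK - i_K1 - i_to - i_Kur - i_Kr - i_Ks) / fvi
    b1 = (
        CM_CELL * (2.0 * i_NaCa - i_PCa - i_CaL - i_B_Ca) / (2.0 * fvi)
        + (V_UP * (i_up_leak - i_up) + i_rel * V_REL) / V_I
    )
    b2 = (
        1.0
        + TRPN_MAX * KM_TRPN / ((Cai + KM_TRPN) * (Cai + KM_TRPN))
        + CMDN_MAX * KM_CMDN / ((Cai + KM_CMDN) * (Cai + KM_CMDN))
    )
    dy[ICAI] = b1 / b2
    dy[ICAUP] = i_up - i_up_leak - i_tr * V_REL / V_UP
    dy[ICAREL] = (i_tr - i_rel) / (
        1.0 + CSQN_MAX * KM_CSQN / ((Carel + KM_CSQN) * (Carel + KM_CSQN))
    )
    return i_ion


@njit(cache=True, fastmath=True)
def _rhs_single(y, istim):
    inf = np.zeros(NSTATE)
    tau = np.ones(NSTATE)
    dy = np.zeros(NSTATE)
    _cell_rates(y, istim, inf, tau, dy)
    for g in GATE_IDX:
        dy[g] = (inf[g] - y[g]) / tau[g]
    return dy


def courtemanche_rhs(state: np.ndarray, istim: float = 0.0) -> np.ndarray:
    """All 21 time derivatives for one cell (dVm/dt in mV/ms, gates 1/ms,
    concentrations mM/ms). ``istim`` in pA/pF, positive = depolarizing."""
    state = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(state)):
        raise ValueError("non-finite ionic state")
    return _rhs_single(state, float(istim))


@njit(cache=True, fastmath=True)
def _step_single(y, dt, istim):
    """One Rush–Larsen/Euler step in place; returns Iion (pA/pF)."""
    inf = np.zeros(NSTATE)
    tau = np.ones(NSTATE)
    dy = np.zeros(NSTATE)
    i_ion = _cell_rates(y, istim, inf, tau, dy)
    for g in GATE_IDX:
        # exponential (Rush–Larsen) gate update: exact for frozen inf/tau
        y[g] = inf[g] + (y[g] - inf[g]) * math.exp(-dt / tau[g])
        if y[g] < 0.0:
            y[g] = 0.0
        elif y[g] > 1.0:
            y[g] = 1.0
    y[IV] += dt * dy[IV]
    y[INAI] += dt * dy[INAI]
    y[IKI] += dt * dy[IKI]
    y[ICAI] += dt * dy[ICAI]
    y[ICAUP] += dt * dy[ICAUP]
    y[ICAREL] += dt * dy[ICAREL]
    return i_ion


def ionic_step(state: np.ndarray, dt: float, istim: float = 0.0):
    """Advance one cell by dt (ms). Returns (new_state, iion_density).

    Gates use the Rush–Larsen exponential update (so they stay in [0, 1]);
    Vm and concentrations use forward Euler.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    state = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(state)):
        raise ValueError("non-finite ionic state")
    y = state.copy()
    i_ion = _step_single(y, float(dt), float(istim))
    return y, float(i_ion)


@njit(cache=True, fastmath=True, parallel=True)
def step_nodes(states, dt, istim):
    """Advance all nodes by one step in place.

    ``states`` is (n_nodes, 21); ``istim`` (n_nodes,) in pA/pF. Returns the
    per-node Iion density (pA/pF) evaluated at the step start.
    """
    n = states.shape[0]
    iion = np.empty(n)
    for i in prange(n):
        iion[i] = _step_single(states[i], dt, istim[i])
    return iion
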