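"""Cell-scale human atrial membrane kinetics with AFib and fibrotic remodeling.

Implements the standard human atrial action-potential model (21 state
variables: voltage, 15 gating variables, Na+/K+/Ca2+ concentrations and the
two-compartment sarcoplasmic reticulum) together with the two remodeled
parameterizations used throughout the package:

* ``afib`` — chronic-AFib electrical remodeling: I_Kur and I_to reduced by
  50%, I_CaL reduced by 70%.
* ``fibrotic`` — fibrosis-associated (TGF-beta1) remodeling applied on top of
  the AFib variant: I_CaL reduced by a further 50% (net 15% of baseline),
  I_Na by 40% and I_K1 by 50%.

Gating variables are advanced with the Rush-Larsen exponential update;
voltage and concentrations with a forward step.  A classical 4th-order
Runge-Kutta integrator at arbitrary (small) step size is provided as an
independent oracle for validating the production integrator.

Units: mV, ms, mM, pA, pF.  Current densities are pA/pF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# Model constants
# ---------------------------------------------------------------------------

R = 8.3143          # J/(mol K)
T = 310.0           # K
F = 96.4867         # C/mmol
RTF = R * T / F

CM = 100.0          # pF, whole-cell capacitance
V_I = 13668.0       # um^3, intracellular volume
V_UP = 1109.52      # um^3, SR uptake compartment
V_REL = 96.48       # um^3, SR release compartment

NA_O = 140.0        # mM
K_O = 5.4
CA_O = 1.8

G_NA = 7.8          # nS/pF
G_K1 = 0.09
G_TO = 0.1652
G_KR = 0.029411765
G_KS = 0.12941176
G_CAL = 0.12375

I_NAK_MAX = 0.59933874
KM_NA_I = 10.0
KM_K_O = 1.5
I_NACA_MAX = 1600.0
KM_NA = 87.5
KM_CA = 1.38
K_SAT = 0.1
GAMMA = 0.35
G_B_CA = 0.001131
G_B_NA = 0.0006744375
I_PCA_MAX = 0.275

K_REL = 30.0
TAU_TR = 180.0
I_UP_MAX = 0.005
K_UP = 0.00092
CA_UP_MAX = 15.0

CMDN_MAX = 0.05
TRPN_MAX = 0.07
CSQN_MAX = 10.0
KM_CMDN = 0.00238
KM_TRPN = 0.0005
KM_CSQN = 0.8

KQ10 = 3.0

N_STATE = 21
# state vector layout
IV, IM, IH, IJ, IOA, IOI, IUA, IUI, IXR, IXS, ID, IF, IFCA, IU, IVV, IW, \
    INAI, IKI, ICAI, ICAUP, ICAREL = range(N_STATE)

#: published resting initial condition
INITIAL_STATE = np.array([
    -81.18,        # V
    2.908e-3,      # m
    9.649e-1,      # h
    9.775e-1,      # j
    3.043e-2,      # oa
    9.992e-1,      # oi
    4.966e-3,      # ua
    9.986e-1,      # ui
    3.296e-5,      # xr
    1.869e-2,      # xs
    1.367e-4,      # d
    9.996e-1,      # f
    7.755e-1,      # f_Ca
    2.35e-112,     # u
    1.0,           # v
    9.992e-1,      # w
    1.117e1,       # Na_i
    1.39e2,        # K_i
    1.013e-4,      # Ca_i
    1.488,         # Ca_up
    1.488,         # Ca_rel
])

# conductance-scaling vector layout: [I_Na, I_K1, I_to, I_Kur, I_CaL]
SCAL_CURRENTS = ("I_Na", "I_K1", "I_to", "I_Kur", "I_CaL")

_VARIANT_SCALINGS = {
    "baseline": {},
    "afib": {"I_Kur": 0.5, "I_to": 0.5, "I_CaL": 0.3},
    # fibrotic remodeling composes multiplicatively with the AFib scalings
    "fibrotic": {"I_Kur": 0.5, "I_to": 0.5, "I_CaL": 0.3 * 0.5,
                 "I_Na": 0.6, "I_K1": 0.5},
}


@dataclass(frozen=True)
class MembraneModel:
    """A named parameterization of the atrial ionic model."""

    name: str
    conductance_scalings: dict = field(default_factory=dict)

    def scaling_vector(self) -> np.ndarray:
        return np.array([self.conductance_scalings.get(c, 1.0)
                         for c in SCAL_CURRENTS])

    @property
    def baseline_parameters(self) -> dict:
        """Maximal conductances (nS/pF) and exchanger/pump constants."""
        return {
            "g_Na": G_NA, "g_K1": G_K1, "g_to": G_TO, "g_Kr": G_KR,
            "g_Ks": G_KS, "g_CaL": G_CAL, "I_NaK_max": I_NAK_MAX,
            "I_NaCa_max": I_NACA_MAX, "g_b_Ca": G_B_CA, "g_b_Na": G_B_NA,
            "I_pCa_max": I_PCA_MAX, "Cm_pF": CM,
        }


def make_model(variant: str) -> MembraneModel:
    """Build the baseline, AFib-remodeled or fibrotic-remodeled cell model.

    ``afib``: I_Kur x0.5, I_to x0.5, I_CaL x0.3.  ``fibrotic``: the AFib
    scalings composed with I_CaL x0.5 (net x0.15), I_Na x0.6, I_K1 x0.5.
    """
    try:
        scal = _VARIANT_SCALINGS[variant]
    except KeyError:
        raise ValueError(
            f"unknown membrane variant {variant!r}; "
            f"expected one of {sorted(_VARIANT_SCALINGS)}") from None
    for k, v in scal.items():
        if not (0.0 < v <= 1.0):
            raise ValueError(f"scaling for {k} out of (0, 1]: {v}")
    return MembraneModel(name=variant, conductance_scalings=dict(scal))


@dataclass
class MembraneState:
    """Full ionic state at a point in time."""

    y: np.ndarray            # length-21 state vector
    time: float = 0.0        # ms

    @property
    def vm(self) -> float:
        return float(self.y[IV])


# ---------------------------------------------------------------------------
# Rate formulas (shared by the production integrator, the lookup-table
# builder and the RK4 oracle)
# ---------------------------------------------------------------------------

N_GATE = 12  # voltage-gated: m h j oa oi ua ui xr xs d f w


@njit(cache=True)
def gate_rates(V, inf, tau):
    """Steady states and time constants of the 12 voltage-dependent gates."""
    # m
    if abs(V + 47.13) < 1e-10:
        a = 3.2
    else:
        a = 0.32 * (V + 47.13) / (1.0 - math.exp(-0.1 * (V + 47.13)))
    b = 0.08 * math.exp(-V / 11.0)
    inf[0] = a / (a + b)
    tau[0] = 1.0 / (a + b)
    # h, j (fast Na inactivation, two-branch formulation)
    if V >= -40.0:
        ah = 0.0
        bh = 1.0 / (0.13 * (1.0 + math.exp(-(V + 10.66) / 11.1)))
        aj = 0.0
        bj = 0.3 * math.exp(-2.535e-7 * V) / (1.0 + math.exp(-0.1 * (V + 32.0)))
    else:
        ah = 0.135 * math.exp(-(V + 80.0) / 6.8)
        bh = 3.56 * math.exp(0.079 * V) + 3.1e5 * math.exp(0.35 * V)
        aj = ((-1.2714e5 * math.exp(0.2444 * V)
               - 3.474e-5 * math.exp(-0.04391 * V)) * (V + 37.78)
              / (1.0 + math.exp(0.311 * (V + 79.23))))
        bj = (0.1212 * math.exp(-0.01052 * V)
              / (1.0 + math.exp(-0.1378 * (V + 40.14))))
    inf[1] = ah / (ah + bh)
    tau[1] = 1.0 / (ah + bh)
    inf[2] = aj / (aj + bj)
    tau[2] = 1.0 / (aj + bj)
    # oa, oi (transient outward)
    a = 0.65 / (math.exp(-(V + 10.0) / 8.5) + math.exp(-(V - 30.0) / 59.0))
    b = 0.65 / (2.5 + math.exp((V + 82.0) / 17.0))
    inf[3] = 1.0 / (1.0 + math.exp(-(V + 20.47) / 17.54))
    tau[3] = 1.0 / ((a + b) * KQ10)
    ai = 1.0 / (18.53 + math.exp((V + 113.7) / 10.95))
    bi = 1.0 / (35.56 + math.exp(-(V + 1.26) / 7.44))
    inf[4] = 1.0 / (1.0 + math.exp((V + 43.1) / 5.3))
    tau[4] = 1.0 / ((ai + bi) * KQ10)
    # ua, ui (ultra-rapid delayed rectifier)
    inf[5] = 1.0 / (1.0 + math.exp(-(V + 30.3) / 9.6))
    tau[5] = 1.0 / ((a + b) * KQ10)       # same a, b as oa
    au = 1.0 / (21.0 + math.exp(-(V - 185.0) / 28.0))
    bu = math.exp((V - 158.0) / 16.0)
    inf[6] = 1.0 / (1.0 + math.exp((V - 99.45) / 27.48))
    tau[6] = 1.0 / ((au + bu) * KQ10)
    # xr
    if abs(V + 14.1) < 1e-10:
        a = 0.0015
    else:
        a = 0.0003 * (V + 14.1) / (1.0 - math.exp(-(V + 14.1) / 5.0))
    if abs(V - 3.3328) < 1e-10:
        b = 3.7836118e-4
    else:
        b = (7.3898e-5 * (V - 3.3328)
             / (math.exp((V - 3.3328) / 5.1237) - 1.0))
    inf[7] = 1.0 / (1.0 + math.exp(-(V + 14.1) / 6.5))
    tau[7] = 1.0 / (a + b)
    # xs
    if abs(V - 19.9) < 1e-10:
        a = 0.00068
        b = 0.000315
    else:
        a = 4e-5 * (V - 19.9) / (1.0 - math.exp(-(V - 19.9) / 17.0))
        b = 3.5e-5 * (V - 19.9) / (math.exp((V - 19.9) / 9.0) - 1.0)
    inf[8] = 1.0 / math.sqrt(1.0 + math.exp(-(V - 19.9) / 12.7))
    tau[8] = 0.5 / (a + b)
    # d (L-type Ca activation)
    inf[9] = 1.0 / (1.0 + math.exp(-(V + 10.0) / 8.0))
    if abs(V + 10.0) < 1e-10:
        tau[9] = 4.579 / (1.0 + math.exp(-(V + 10.0) / 6.24))
    else:
        e = math.exp(-(V + 10.0) / 6.24)
        tau[9] = (1.0 - e) / (0.035 * (V + 10.0) * (1.0 + e))
    # f (L-type Ca inactivation)
    inf[10] = 1.0 / (1.0 + math.exp((V + 28.0) / 6.9))
    tau[10] = 9.0 / (0.0197 * math.exp(-0.0337 ** 2 * (V + 10.0) ** 2) + 0.02)
    # w (SR release, voltage-dependent)
    inf[11] = 1.0 - 1.0 / (1.0 + math.exp(-(V - 40.0) / 17.0))
    if abs(V - 7.9) < 1e-10:
        tau[11] = 6.0 * 0.2 / 1.3
    else:
        e = math.exp(-(V - 7.9) / 5.0)
        tau[11] = 6.0 * (1.0 - e) / ((1.0 + 0.3 * e) * (V - 7.9))


N_FACT = 6  # voltage-only current factors


@njit(cache=True)
def v_factors(V, out):
    """Voltage-only factors of I_Kur, I_K1, I_Kr, I_NaK and I_NaCa."""
    out[0] = 0.005 + 0.05 / (1.0 + math.exp(-(V - 15.0) / 13.0))  # g_Kur(V)
    out[1] = 1.0 / (1.0 + math.exp(0.07 * (V + 80.0)))            # I_K1 rect.
    out[2] = 1.0 / (1.0 + math.exp((V + 15.0) / 22.4))            # I_Kr rect.
    sig = (math.exp(NA_O / 67.3) - 1.0) / 7.0
    out[3] = 1.0 / (1.0 + 0.1245 * math.exp(-0.1 * V / RTF)
                    + 0.0365 * sig * math.exp(-V / RTF))          # f_NaK
    out[4] = math.exp(GAMMA * V / RTF)                            # NaCa fwd
    out[5] = math.exp((GAMMA - 1.0) * V / RTF)                    # NaCa rev


@njit(cache=True, inline="always", fastmath=True)
def _currents_core(y, fac, sc, dy, ena, ek, eca):
    """Total ionic current (pA/pF) and concentration/SR derivatives.

    ``fac`` are the six voltage-only factors, ``sc`` the five conductance
    scalings, ``ena``/``ek``/``eca`` the (possibly cached) Nernst
    potentials.  Fills dy for the concentration states and returns
    (i_ion_density, fca_inf, u_inf, v_inf, tau_v).
    """
    V = y[IV]
    nai = y[INAI]
    cai = y[ICAI]
    caup = y[ICAUP]
    carel = y[ICAREL]

    ina = CM * G_NA * sc[0] * y[IM] ** 3 * y[IH] * y[IJ] * (V - ena)
    ik1 = CM * G_K1 * sc[1] * fac[1] * (V - ek)
    ito = CM * G_TO * sc[2] * y[IOA] ** 3 * y[IOI] * (V - ek)
    ikur = CM * fac[0] * sc[3] * y[IUA] ** 3 * y[IUI] * (V - ek)
    ikr = CM * G_KR * y[IXR] * fac[2] * (V - ek)
    iks = CM * G_KS * y[IXS] ** 2 * (V - ek)
    ical = CM * G_CAL * sc[4] * y[ID] * y[IF] * y[IFCA] * (V - 65.0)
    rnai = KM_NA_I / nai
    inak = (CM * I_NAK_MAX * fac[3] * (K_O / (K_O + KM_K_O))
            / (1.0 + rnai * math.sqrt(rnai)))
    inaca = (CM * I_NACA_MAX
             * (fac[4] * nai ** 3 * CA_O - fac[5] * NA_O ** 3 * cai)
             / ((KM_NA ** 3 + NA_O ** 3) * (KM_CA + CA_O)
                * (1.0 + K_SAT * fac[5])))
    ibna = CM * G_B_NA * (V - ena)
    ibca = CM * G_B_CA * (V - eca)
    ipca = CM * I_PCA_MAX * cai / (0.0005 + cai)

    irel = K_REL * y[IU] ** 2 * y[IVV] * y[IW] * (carel - cai)
    itr = (caup - carel) / TAU_TR
    iup = I_UP_MAX / (1.0 + K_UP / cai)
    iupleak = I_UP_MAX * caup / CA_UP_MAX

    fn = 1e3 * (1e-15 * V_REL * irel
                - 1e-15 / (2.0 * F) * (0.5 * ical - 0.2 * inaca))
    # SR-release sigmoids with saturated arguments: the raw argument is
    # ~ +250 at rest, which would drive exp() through its slow
    # overflow-handling path on every quiescent node; the sigmoids are
    # indistinguishable from 0/1 beyond |45| anyway
    arg = -(fn - 3.4175e-13) / 13.67e-16
    if arg > 45.0:
        u_inf = 0.0
    elif arg < -45.0:
        u_inf = 1.0
    else:
        u_inf = 1.0 / (1.0 + math.exp(arg))
    bv = arg - 200.0            # exact shift between the two sigmoids
    if bv > 45.0:
        v_inf = 1.0
    elif bv < -45.0:
        v_inf = 0.0
    else:
        v_inf = 1.0 - 1.0 / (1.0 + math.exp(bv))
    tau_v = 1.91 + 2.09 * u_inf
    fca_inf = 1.0 / (1.0 + cai / 0.00035)

    dy[INAI] = (-3.0 * inak - 3.0 * inaca - ibna - ina) / (F * V_I)
    dy[IKI] = (2.0 * inak - ik1 - ito - ikur - ikr - iks) / (F * V_I)
    b1 = ((2.0 * inaca - ipca - ical - ibca) / (2.0 * F * V_I)
          + (V_UP * (iupleak - iup) + irel * V_REL) / V_I)
    b2 = (1.0 + TRPN_MAX * KM_TRPN / (cai + KM_TRPN) ** 2
          + CMDN_MAX * KM_CMDN / (cai + KM_CMDN) ** 2)
    dy[ICAI] = b1 / b2
    dy[ICAUP] = iup - iupleak - itr * V_REL / V_UP
    dy[ICAREL] = (itr - irel) / (1.0 + CSQN_MAX * KM_CSQN
                                 / (carel + KM_CSQN) ** 2)

    i_ion = (ina + ik1 + ito + ikur + ikr + iks + ical + inak + inaca
             + ibna + ibca + ipca) / CM
    return i_ion, fca_inf, u_inf, v_inf, tau_v


@njit(cache=True)
def _currents_and_slow(y, fac, sc, dy):
    """As :func:`_currents_core` with Nernst potentials computed in place."""
    ena = RTF * math.log(NA_O / y[INAI])
    ek = RTF * math.log(K_O / y[IKI])
    eca = 0.5 * RTF * math.log(CA_O / y[ICAI])
    return _currents_core(y, fac, sc, dy, ena, ek, eca)


_GATE_IDX = np.array([IM, IH, IJ, IOA, IOI, IUA, IUI, IXR, IXS, ID, IF, IW])


@njit(cache=True)
def rhs(y, istim, sc, dy):
    """Full time derivative of the state vector (for the RK4 oracle)."""
    inf = np.empty(N_GATE)
    tau = np.empty(N_GATE)
    fac = np.empty(N_FACT)
    gate_rates(y[IV], inf, tau)
    v_factors(y[IV], fac)
    i_ion, fca_inf, u_inf, v_inf, tau_v = _currents_and_slow(y, fac, sc, dy)
    for g in range(N_GATE):
        dy[_GATE_IDX[g]] = (inf[g] - y[_GATE_IDX[g]]) / tau[g]
    dy[IFCA] = (fca_inf - y[IFCA]) / 2.0
    dy[IU] = (u_inf - y[IU]) / 8.0
    dy[IVV] = (v_inf - y[IVV]) / tau_v
    dy[IV] = -i_ion + istim


@njit(cache=True)
def step_rl(y, dt, istim, sc):
    """One Rush-Larsen / forward-Euler step, in place."""
    inf = np.empty(N_GATE)
    tau = np.empty(N_GATE)
    fac = np.empty(N_FACT)
    dy = np.zeros(N_STATE)
    gate_rates(y[IV], inf, tau)
    v_factors(y[IV], fac)
    i_ion, fca_inf, u_inf, v_inf, tau_v = _currents_and_slow(y, fac, sc, dy)
    for g in range(N_GATE):
        k = _GATE_IDX[g]
        y[k] = inf[g] + (y[k] - inf[g]) * math.exp(-dt / tau[g])
    y[IFCA] = fca_inf + (y[IFCA] - fca_inf) * math.exp(-dt / 2.0)
    y[IU] = u_inf + (y[IU] - u_inf) * math.exp(-dt / 8.0)
    y[IVV] = v_inf + (y[IVV] - v_inf) * math.exp(-dt / tau_v)
    y[INAI] += dt * dy[INAI]
    y[IKI] += dt * dy[IKI]
    y[ICAI] += dt * dy[ICAI]
    y[ICAUP] += dt * dy[ICAUP]
    y[ICAREL] += dt * dy[ICAREL]
    y[IV] += dt * (-i_ion + istim)


@njit(cache=True)
def _run_cell(y, dt, n_steps, stim_onsets, stim_dur, stim_amp, sc, stride):
    """Advance a single cell, recording V every ``stride`` steps."""
    n_rec = n_steps // stride + 1
    vout = np.empty(n_rec)
    vout[0] = y[IV]
    k = 1
    for s in range(n_steps):
        t = s * dt
        istim = 0.0
        for o in stim_onsets:
            if o <= t < o + stim_dur:
                istim = stim_amp
        step_rl(y, dt, istim, sc)
        if (s + 1) % stride == 0:
            vout[k] = y[IV]
            k += 1
    return vout[:k]


@njit(cache=True)
def _run_cell_rk4(y, dt, n_steps, stim_onsets, stim_dur, stim_amp, sc, stride):
    """Classical RK4 reference integrator (oracle; use a small dt)."""
    n_rec = n_steps // stride + 1
    vout = np.empty(n_rec)
    vout[0] = y[IV]
    k1 = np.empty(N_STATE)
    k2 = np.empty(N_STATE)
    k3 = np.empty(N_STATE)
    k4 = np.empty(N_STATE)
    k = 1
    for s in range(n_steps):
        t = s * dt
        def _stim(tt):
            v = 0.0
            for o in stim_onsets:
                if o <= tt < o + stim_dur:
                    v = stim_amp
            return v
        rhs(y, _stim(t), sc, k1)
        rhs(y + 0.5 * dt * k1, _stim(t + 0.5 * dt), sc, k2)
        rhs(y + 0.5 * dt * k2, _stim(t + 0.5 * dt), sc, k3)
        rhs(y + dt * k3, _stim(t + dt), sc, k4)
        y += dt / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if (s + 1) % stride == 0:
            vout[k] = y[IV]
            k += 1
    return vout[:k]


# ---------------------------------------------------------------------------
# Lookup tables for the tissue-scale kernels
# ---------------------------------------------------------------------------

V_TAB_MIN = -120.0
V_TAB_MAX = 80.0
V_TAB_STEP = 0.02


def build_tables(dt: float):
    """Tabulate gate updates and voltage-only factors on a fine V grid.

    Returns ``(tab_inf, tab_rl, tab_fac)`` where ``tab_rl`` holds
    ``exp(-dt/tau)`` for the given reaction step ``dt`` (tables are therefore
    dt-locked).  The tissue kernels sample them nearest-neighbor at 0.02 mV,
    which perturbs gate steady states by < 1e-3.
    """
    nv = int(round((V_TAB_MAX - V_TAB_MIN) / V_TAB_STEP)) + 1
    vgrid = V_TAB_MIN + V_TAB_STEP * np.arange(nv)
    tab_inf = np.empty((nv, N_GATE))
    tab_rl = np.empty((nv, N_GATE))
    tab_fac = np.empty((nv, N_FACT))
    ugrid = np.linspace(0.0, 1.0, 1025)
    tab_rlv = np.exp(-dt / (1.91 + 2.09 * ugrid))
    inf = np.empty(N_GATE)
    tau = np.empty(N_GATE)
    fac = np.empty(N_FACT)
    for i, v in enumerate(vgrid):
        gate_rates(v, inf, tau)
        v_factors(v, fac)
        tab_inf[i] = inf
        tab_rl[i] = np.exp(-dt / tau)
        tab_fac[i] = fac
    return tab_inf, tab_rl, tab_fac, tab_rlv


@njit(cache=True, fastmath=True)
def refresh_nernst(S, ena, ek, eca):
    """Recompute cached per-node Nernst potentials from concentrations."""
    for i in range(S.shape[0]):
        ena[i] = RTF * math.log(NA_O / S[i, INAI])
        ek[i] = RTF * math.log(K_O / S[i, IKI])
        eca[i] = 0.5 * RTF * math.log(CA_O / S[i, ICAI])


# ---------------------------------------------------------------------------
# Action-potential metrics and limit-cycle pacing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class APMetrics:
    """Scalar descriptors of one action potential."""

    apd: float        # ms, at the requested repolarization level
    dvdt_max: float   # mV/ms
    v_rest: float     # mV
    v_peak: float     # mV


def measure_ap_metrics(t: np.ndarray, v: np.ndarray,
                       repol_level: float = 0.9,
                       stim_amp: float = 0.0,
                       stim_dur: float = 0.0) -> APMetrics:
    """AP duration, upstroke velocity and voltage extrema of a single beat.

    APD is the time from the maximum-upstroke instant to the downward
    crossing of ``v_peak - repol_level * (v_peak - v_rest)`` (linearly
    interpolated between samples).  If the stimulus profile is given
    (``stim_amp`` in pA/pF over ``[0, stim_dur)``), its direct contribution
    to dV/dt is subtracted so that ``dvdt_max`` is the intrinsic ionic
    upstroke rate rather than a stimulus artifact.
    """
    if not (0.0 < repol_level < 1.0):
        raise ValueError("repol_level must be in (0, 1)")
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    if t.shape != v.shape or t.size < 4:
        raise ValueError("trace must be 1D arrays of equal length >= 4")
    dv = np.diff(v) / np.diff(t)
    dv_int = dv - np.where(t[:-1] < stim_dur, stim_amp, 0.0)
    iup = int(np.argmax(dv_int))
    dvdt_max = float(dv_int[iup])
    if dvdt_max <= 0:
        raise ValueError("no measurable AP: trace has no positive upstroke")
    ipk = iup + int(np.argmax(v[iup:]))
    v_peak = float(v[ipk])
    v_rest = float(np.min(v))
    thr = v_peak - repol_level * (v_peak - v_rest)
    below = np.nonzero(v[ipk:] < thr)[0]
    if below.size == 0:
        raise ValueError("unrepolarized trace: no crossing of the "
                         "repolarization threshold after the peak")
    ic = ipk + below[0]
    # linear interpolation of the crossing time
    t_cross = t[ic - 1] + (thr - v[ic - 1]) / (v[ic] - v[ic - 1]) \
        * (t[ic] - t[ic - 1])
    return APMetrics(apd=float(t_cross - t[iup]), dvdt_max=dvdt_max,
                     v_rest=v_rest, v_peak=v_peak)


#: default cell-scale stimulus: 2 ms at 30 pA/pF — the smallest round
#: amplitude giving robust 1:1 capture and limit-cycle convergence for every
#: variant at BCL 500 ms (about 2.7x the non-fibrotic diastolic threshold).
DEFAULT_CELL_STIM = 30.0
DEFAULT_CELL_STIM_DUR = 2.0


def equilibrate(model: MembraneModel, duration: float = 10000.0,
                dt: float = 0.005) -> np.ndarray:
    """Quiescent (stimulus-free) equilibrium state vector of a variant.

    Ten unstimulated seconds from the published resting state; this is the
    initialization used before limit-cycle pacing, and it is what makes the
    fibrotic variant's depolarized diastole (about -75 mV) visible.
    """
    sc = model.scaling_vector()
    y = INITIAL_STATE.copy()
    n = int(round(duration / dt))
    _run_cell(y, dt, n, np.array([-1e9]), 1.0, 0.0, sc, n)
    return y


def find_capture_threshold(model: MembraneModel, dt: float = 0.005,
                           pulse_ms: float = 2.0,
                           y0: np.ndarray | None = None) -> float:
    """Diastolic capture threshold (pA/pF) for a 2 ms pulse, by bisection.

    Capture = voltage exceeds 0 mV within 50 ms of pulse onset, starting
    from the model's quiescent equilibrium (or a supplied state).
    """
    sc = model.scaling_vector()
    if y0 is None:
        y0 = equilibrate(model)

    def fires(amp):
        y = y0.copy()
        n = int(round(50.0 / dt))
        v = _run_cell(y, dt, n, np.array([5.0]), pulse_ms, amp, sc, 1)
        return float(np.max(v)) > 0.0

    lo, hi = 0.0, 8.0
    while not fires(hi):
        hi *= 2.0
        if hi > 1024.0:
            raise RuntimeError("cell refuses to fire at any amplitude")
    for _ in range(20):
        mid = 0.5 * (lo + hi)
        if fires(mid):
            hi = mid
        else:
            lo = mid
    return hi


def pace_to_limit_cycle(model: MembraneModel, bcl: float = 500.0,
                        max_beats: int = 200, tol: float = 0.1,
                        dt: float = 0.005, stim_amp: float = DEFAULT_CELL_STIM,
                        stim_dur: float = DEFAULT_CELL_STIM_DUR,
                        repol_level: float = 0.9,
                        y0: np.ndarray | None = None):
    """Pace a single cell at fixed BCL until the APD stops changing.

    Starts from the variant's own quiescent equilibrium, applies the default
    fixed 2 ms / 30 pA/pF stimulus, and stops when the successive-beat APD
    difference falls below ``tol`` (ms).

    Returns ``(state, (t, v), info)`` where ``(t, v)`` is the final beat's
    voltage trace and ``info`` carries the convergence flag, beat count,
    per-beat APDs and the metrics of the converged beat (with the stimulus
    contribution to dV/dt removed).
    """
    if bcl <= 0:
        raise ValueError("bcl must be positive")
    if max_beats < 1:
        raise ValueError("max_beats must be >= 1")
    sc = model.scaling_vector()
    y = equilibrate(model, dt=dt) if y0 is None else y0.copy()
    n_per_beat = int(round(bcl / dt))
    onsets = np.array([0.0])
    apds = []
    converged = False
    t_beat = None
    v_beat = None
    m = None
    for beat in range(max_beats):
        v_beat = _run_cell(y, dt, n_per_beat, onsets, stim_dur, stim_amp,
                           sc, 1)
        t_beat = dt * np.arange(v_beat.size)
        try:
            m = measure_ap_metrics(t_beat, v_beat, repol_level,
                                   stim_amp=stim_amp, stim_dur=stim_dur)
        except ValueError as e:
            raise ValueError(f"no measurable AP on beat {beat + 1}: {e}")
        apds.append(m.apd)
        if beat > 0 and abs(apds[-1] - apds[-2]) < tol:
            converged = True
            break
    info = {"converged": converged, "beats": len(apds),
            "apds": np.array(apds), "stim_amp": stim_amp,
            "metrics": m}
    state = MembraneState(y=y, time=len(apds) * bcl)
    return state, (t_beat, v_beat), info


@lru_cache(maxsize=8)
def _limit_cycle_state_cached(variant: str, bcl: float, dt: float):
    state, _, info = pace_to_limit_cycle(make_model(variant), bcl=bcl, dt=dt)
    if not info["converged"]:
        raise RuntimeError(f"{variant} did not reach a limit cycle")
    return state.y


def limit_cycle_state(variant: str, bcl: float = 500.0,
                      dt: float = 0.005) -> np.ndarray:
    """Converged state vector for a variant (convenience for tissue setup).

    Cached: the limit cycle is a pure function of (variant, bcl, dt).
    """
    return _limit_cycle_state_cached(variant, bcl, dt).copy()


def trace_final_beat_rk4(model: MembraneModel, y0: np.ndarray,
                         bcl: float = 500.0, dt: float = 0.005,
                         stim_amp: float = 40.0, stim_dur: float = 2.0):
    """High-resolution RK4 trace of one beat from a given state (oracle)."""
    sc = model.scaling_vector()
    y = y0.copy()
    n = int(round(bcl / dt))
    stride = max(1, int(round(0.025 / dt)))
    v = _run_cell_rk4(y, dt, n, np.array([0.0]), stim_dur, stim_amp, sc,
                      stride)
    t = dt * stride * np.arange(v.size)
    return t, v
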