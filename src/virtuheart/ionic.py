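"""Human ventricular myocyte model with late sodium current and HCM remodeling.

The membrane kinetics follow the 2006 ten Tusscher–Panfilov human ventricular
formulation (epicardial parameter set by default), extended with a late sodium
current I_NaL of the standard two-gate form (activation gate sharing the fast
sodium activation kinetics, slowly inactivating gate with a 200 ms time
constant).  Two parameter variants are provided:

``normal``
    the nonfibrotic myocyte, with the I_NaL maximal conductance calibrated so
    that steady 1 Hz pacing yields the target baseline APD90 (280 ms);

``remodeled``
    the diffuse-fibrosis myocyte, obtained from ``normal`` by scaling eight
    maximal conductances/fluxes: I_NaL x2.07, I_CaL x1.19, I_Kr x0.66,
    I_Ks x0.73, I_to x0.15, I_K1 x0.85, Na/Ca exchanger x1.34 and SERCA
    uptake x0.57.  The net electrophysiological effect is a prolonged action
    potential (~+18% APD90) and a diminished phase-1 notch.

Integration uses Rush–Larsen exponential updates for Hodgkin–Huxley gates and
forward Euler for the membrane potential and ionic concentrations, with the
rapid-buffering quadratic update for the calcium compartments.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from . import config

__all__ = [
    "CellState", "IonicParams", "REMODELING_FACTORS",
    "make_params", "initial_state", "step_cell", "pace", "apd90",
    "apd90_trace", "notch_depth", "calibrate_baseline", "calibrate_g_nal",
    "IntegrationError",
]

# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

#: Multiplicative remodeling of the diffuse-fibrosis myocyte relative to the
#: nonfibrotic baseline (maximal conductances / maximal fluxes).
REMODELING_FACTORS = {
    "g_nal": 2.07,    # late Na+ current, +107%
    "g_cal": 1.19,    # L-type Ca2+ current, +19%
    "g_kr": 0.66,     # rapid delayed rectifier, -34%
    "g_ks": 0.73,     # slow delayed rectifier, -27%
    "g_to": 0.15,     # transient outward, -85%
    "g_k1": 0.85,     # inward rectifier, -15%
    "k_naca": 1.34,   # Na+/Ca2+ exchanger, +34%
    "v_maxup": 0.57,  # SERCA uptake, -43%
}

_CELLTYPES = ("epi", "endo", "mid")


@dataclass(frozen=True)
class IonicParams:
    """Maximal conductances and fluxes of the myocyte model.

    Conductances in nS/pF, fluxes in mM/ms, exchanger/pump scalings in the
    units of the base formulation.
    """
    g_na: float = 14.838
    g_k1: float = 5.405
    g_to: float = 0.294          # epicardial
    g_kr: float = 0.153
    g_ks: float = 0.392          # epicardial
    g_cal: float = 3.98e-5
    k_naca: float = 1000.0
    p_nak: float = 2.724
    g_pca: float = 0.1238
    g_pk: float = 0.0146
    g_bna: float = 0.00029
    g_bca: float = 0.000592
    v_maxup: float = 0.006375
    v_rel: float = 0.102
    v_leak: float = 0.00036
    v_xfer: float = 0.0038
    g_nal: float = 0.0
    celltype: str = "epi"
    variant: str = "normal"

    def to_vector(self) -> np.ndarray:
        return np.array([
            self.g_na, self.g_k1, self.g_to, self.g_kr, self.g_ks,
            self.g_cal, self.k_naca, self.p_nak, self.g_pca, self.g_pk,
            self.g_bna, self.g_bca, self.v_maxup, self.v_rel, self.v_leak,
            self.v_xfer, self.g_nal,
        ], dtype=np.float64)

    @property
    def celltype_code(self) -> int:
        return _CELLTYPES.index(self.celltype)


def make_params(variant: str, celltype: str = "epi",
                g_nal: float | None = None,
                repol_scale: float | None = None) -> IonicParams:
    """Build the parameter set for a model variant.

    Parameters
    ----------
    variant : {"normal", "remodeled"}
        ``normal`` is the calibrated nonfibrotic baseline; ``remodeled``
        applies the eight diffuse-fibrosis scaling factors on top of it.
    celltype : {"epi", "endo", "mid"}
        Transmural cell type of the base formulation (epicardial default).
    g_nal : float, optional
        Baseline late-sodium maximal conductance; defaults to the standard
        published value recorded in :mod:`virtuheart.config`.
    repol_scale : float, optional
        Joint multiplier on the delayed-rectifier conductances G_Kr and G_Ks
        of the baseline cell; defaults to the calibrated value that sets the
        baseline APD90 to its target (see :func:`calibrate_baseline`).
    """
    if variant not in ("normal", "remodeled"):
        raise ValueError(f"unknown variant {variant!r}")
    if celltype not in _CELLTYPES:
        raise ValueError(f"unknown celltype {celltype!r}")
    if g_nal is None:
        g_nal = config.G_NAL_CALIBRATED
    if repol_scale is None:
        repol_scale = config.REPOL_SCALE_CALIBRATED
    base = IonicParams(celltype=celltype, variant="normal", g_nal=g_nal)
    if celltype == "endo":
        base = replace(base, g_to=0.073)
    elif celltype == "mid":
        base = replace(base, g_ks=0.098)
    base = replace(base, g_kr=base.g_kr * repol_scale,
                   g_ks=base.g_ks * repol_scale)
    if variant == "normal":
        return base
    scaled = {k: getattr(base, k) * f for k, f in REMODELING_FACTORS.items()}
    return replace(base, variant="remodeled", **scaled)


# ---------------------------------------------------------------------------
# State
# ---------------------------------------------------------------------------

#: Order of state variables in the packed state vector.
STATE_NAMES = (
    "V", "m", "h", "j", "d", "f", "f2", "fcass", "r", "s",
    "xr1", "xr2", "xs", "mL", "hL",
    "Nai", "Ki", "Cai", "CaSR", "CaSS", "Rbar",
)
N_STATE = len(STATE_NAMES)
_GATE_SLICE = slice(1, 15)


@dataclass
class CellState:
    """Packed myocyte state: membrane potential, gates and concentrations."""
    y: np.ndarray = field(default_factory=lambda: _default_state_vector())
    t: float = 0.0

    @property
    def V(self) -> float:
        return float(self.y[0])

    def __getattr__(self, name):
        try:
            return float(self.y[STATE_NAMES.index(name)])
        except ValueError:
            raise AttributeError(name) from None

    def copy(self) -> "CellState":
        return CellState(self.y.copy(), self.t)


def _default_state_vector() -> np.ndarray:
    """Resting-state initial conditions of the base formulation."""
    y = np.zeros(N_STATE)
    y[0] = -86.2      # V (mV)
    y[1] = 0.0        # m
    y[2] = 0.75       # h
    y[3] = 0.75       # j
    y[4] = 0.0        # d
    y[5] = 1.0        # f
    y[6] = 1.0        # f2
    y[7] = 1.0        # fcass
    y[8] = 0.0        # r
    y[9] = 1.0        # s
    y[10] = 0.0       # xr1
    y[11] = 1.0       # xr2
    y[12] = 0.0       # xs
    y[13] = 0.0       # mL
    y[14] = 0.6       # hL
    y[15] = 7.67      # Nai (mM)
    y[16] = 138.3     # Ki (mM)
    y[17] = 0.00007   # Cai (mM)
    y[18] = 1.3       # CaSR (mM)
    y[19] = 0.00007   # CaSS (mM)
    y[20] = 1.0       # Rbar
    return y


def initial_state() -> CellState:
    return CellState()


# ---------------------------------------------------------------------------
# Kernels
# ---------------------------------------------------------------------------

_RTF = 8314.472 * 310.0 / 96485.3415   # RT/F in mV
_F = 96485.3415
_KO, _CAO, _NAO = 5.4, 2.0, 140.0
_VC, _VSR, _VSS = 0.016404, 0.001094, 0.00005468
_CAP = 0.185
_INV_VCF = 1.0 / (_VC * _F) * _CAP
_INV_VCF2 = 1.0 / (2.0 * _VC * _F) * _CAP
_INV_VSSF2 = 1.0 / (2.0 * _VSS * _F) * _CAP


@njit(cache=True, fastmath=True)
def gate_tables(V, celltype):
    """Steady states and time constants of the 14 gating variables at V.

    Returns (inf, tau) arrays ordered as in STATE_NAMES[1:15]; the entry for
    fcass (index 6 of the slice) is a placeholder since that gate depends on
    subspace calcium, not voltage.
    """
    inf = np.empty(14)
    tau = np.empty(14)
    # INa gates
    m_inf = 1.0 / (1.0 + np.exp((-56.86 - V) / 9.03)) ** 2
    am = 1.0 / (1.0 + np.exp((-60.0 - V) / 5.0))
    bm = 0.1 / (1.0 + np.exp((V + 35.0) / 5.0)) + 0.1 / (1.0 + np.exp((V - 50.0) / 200.0))
    tau_m = am * bm
    h_inf = 1.0 / (1.0 + np.exp((V + 71.55) / 7.43)) ** 2
    if V >= -40.0:
        ah = 0.0
        bh = 0.77 / (0.13 * (1.0 + np.exp(-(V + 10.66) / 11.1)))
    else:
        ah = 0.057 * np.exp(-(V + 80.0) / 6.8)
        bh = 2.7 * np.exp(0.079 * V) + 3.1e5 * np.exp(0.3485 * V)
    tau_h = 1.0 / (ah + bh)
    j_inf = h_inf
    if V >= -40.0:
        aj = 0.0
        bj = 0.6 * np.exp(0.057 * V) / (1.0 + np.exp(-0.1 * (V + 32.0)))
    else:
        aj = ((-2.5428e4 * np.exp(0.2444 * V) - 6.948e-6 * np.exp(-0.04391 * V))
              * (V + 37.78) / (1.0 + np.exp(0.311 * (V + 79.23))))
        bj = 0.02424 * np.exp(-0.01052 * V) / (1.0 + np.exp(-0.1378 * (V + 40.14)))
    tau_j = 1.0 / (aj + bj)
    # ICaL gates
    d_inf = 1.0 / (1.0 + np.exp((-8.0 - V) / 7.5))
    ad = 1.4 / (1.0 + np.exp((-35.0 - V) / 13.0)) + 0.25
    bd = 1.4 / (1.0 + np.exp((V + 5.0) / 5.0))
    gd = 1.0 / (1.0 + np.exp((50.0 - V) / 20.0))
    tau_d = ad * bd + gd
    f_inf = 1.0 / (1.0 + np.exp((V + 20.0) / 7.0))
    tau_f = (1102.5 * np.exp(-(V + 27.0) ** 2 / 225.0)
             + 200.0 / (1.0 + np.exp((13.0 - V) / 10.0))
             + 180.0 / (1.0 + np.exp((V + 30.0) / 10.0)) + 20.0)
    f2_inf = 0.67 / (1.0 + np.exp((V + 35.0) / 7.0)) + 0.33
    tau_f2 = (562.0 * np.exp(-(V + 27.0) ** 2 / 240.0)
              + 31.0 / (1.0 + np.exp((25.0 - V) / 10.0))
              + 80.0 / (1.0 + np.exp((V + 30.0) / 10.0)))
    # Ito gates
    r_inf = 1.0 / (1.0 + np.exp((20.0 - V) / 6.0))
    tau_r = 9.5 * np.exp(-(V + 40.0) ** 2 / 1800.0) + 0.8
    if celltype == 1:  # endocardial
        s_inf = 1.0 / (1.0 + np.exp((V + 28.0) / 5.0))
        tau_s = 1000.0 * np.exp(-(V + 67.0) ** 2 / 1000.0) + 8.0
    else:
        s_inf = 1.0 / (1.0 + np.exp((V + 20.0) / 5.0))
        tau_s = (85.0 * np.exp(-(V + 45.0) ** 2 / 320.0)
                 + 5.0 / (1.0 + np.exp((V - 20.0) / 5.0)) + 3.0)
    # IKr gates
    xr1_inf = 1.0 / (1.0 + np.exp((-26.0 - V) / 7.0))
    axr1 = 450.0 / (1.0 + np.exp((-45.0 - V) / 10.0))
    bxr1 = 6.0 / (1.0 + np.exp((V + 30.0) / 11.5))
    tau_xr1 = axr1 * bxr1
    xr2_inf = 1.0 / (1.0 + np.exp((V + 88.0) / 24.0))
    axr2 = 3.0 / (1.0 + np.exp((-60.0 - V) / 20.0))
    bxr2 = 1.12 / (1.0 + np.exp((V - 60.0) / 20.0))
    tau_xr2 = axr2 * bxr2
    # IKs gate
    xs_inf = 1.0 / (1.0 + np.exp((-5.0 - V) / 14.0))
    axs = 1400.0 / np.sqrt(1.0 + np.exp((5.0 - V) / 6.0))
    bxs = 1.0 / (1.0 + np.exp((V - 35.0) / 15.0))
    tau_xs = axs * bxs + 80.0
    # INaL gates: activation shares the fast-sodium activation time constant,
    # inactivation is slow (200 ms)
    mL_inf = 1.0 / (1.0 + np.exp(-(V + 42.85) / 5.264))
    tau_mL = tau_m
    hL_inf = 1.0 / (1.0 + np.exp((V + 87.61) / 7.488))
    tau_hL = 200.0

    inf[0], tau[0] = m_inf, tau_m
    inf[1], tau[1] = h_inf, tau_h
    inf[2], tau[2] = j_inf, tau_j
    inf[3], tau[3] = d_inf, tau_d
    inf[4], tau[4] = f_inf, tau_f
    inf[5], tau[5] = f2_inf, tau_f2
    inf[6], tau[6] = 0.0, 1.0       # fcass: handled separately
    inf[7], tau[7] = r_inf, tau_r
    inf[8], tau[8] = s_inf, tau_s
    inf[9], tau[9] = xr1_inf, tau_xr1
    inf[10], tau[10] = xr2_inf, tau_xr2
    inf[11], tau[11] = xs_inf, tau_xs
    inf[12], tau[12] = mL_inf, tau_mL
    inf[13], tau[13] = hL_inf, tau_hL
    return inf, tau


@njit(cache=True, fastmath=True)
def ionic_step(y, p, celltype, dt, i_stim):
    """Advance the packed state one step in place; returns total ionic current.

    Gates use Rush–Larsen exponential integration, V and concentrations
    forward Euler with the quadratic rapid-buffering calcium update.
    """
    V = y[0]
    Nai, Ki, Cai, CaSR, CaSS, Rbar = y[15], y[16], y[17], y[18], y[19], y[20]

    inf, tau = gate_tables(V, celltype)
    for k in range(14):
        if k == 6:
            continue
        g = y[1 + k]
        y[1 + k] = inf[k] + (g - inf[k]) * np.exp(-dt / tau[k])
    # fcass gate (subspace-calcium dependent)
    fcass_inf = 0.6 / (1.0 + (CaSS / 0.05) ** 2) + 0.4
    tau_fcass = 80.0 / (1.0 + (CaSS / 0.05) ** 2) + 2.0
    y[7] = fcass_inf + (y[7] - fcass_inf) * np.exp(-dt / tau_fcass)

    m, h, j = y[1], y[2], y[3]
    d, f, f2, fcass = y[4], y[5], y[6], y[7]
    r, s = y[8], y[9]
    xr1, xr2, xs = y[10], y[11], y[12]
    mL, hL = y[13], y[14]

    ena = _RTF * np.log(_NAO / Nai)
    ek = _RTF * np.log(_KO / Ki)
    eks = _RTF * np.log((_KO + 0.03 * _NAO) / (Ki + 0.03 * Nai))
    eca = 0.5 * _RTF * np.log(_CAO / Cai)

    ina = p[0] * m * m * m * h * j * (V - ena)
    inal = p[16] * mL * hL * (V - ena)
    # inward rectifier
    ak1 = 0.1 / (1.0 + np.exp(0.06 * (V - ek - 200.0)))
    bk1 = ((3.0 * np.exp(0.0002 * (V - ek + 100.0)) + np.exp(0.1 * (V - ek - 10.0)))
           / (1.0 + np.exp(-0.5 * (V - ek))))
    ik1 = p[1] * (ak1 / (ak1 + bk1)) * (V - ek)
    ito = p[2] * r * s * (V - ek)
    ikr = p[3] * np.sqrt(_KO / 5.4) * xr1 * xr2 * (V - ek)
    iks = p[4] * xs * xs * (V - eks)
    # L-type calcium current (GHK-like driving term)
    ex = np.exp(2.0 * (V - 15.0) / _RTF)
    if np.abs(V - 15.0) < 1e-6:
        # limit of the driving term as V -> 15 mV
        ical_drv = _F * (0.25 * CaSS - _CAO)
    else:
        ical_drv = (2.0 * _F * (V - 15.0) / _RTF) * (0.25 * CaSS * ex - _CAO) / (ex - 1.0)
    ical = p[5] * d * f * f2 * fcass * 2.0 * ical_drv
    # Na/Ca exchanger
    e1 = np.exp(0.35 * V / _RTF)
    e2 = np.exp(-0.65 * V / _RTF)
    inaca = (p[6] * (e1 * Nai ** 3 * _CAO - e2 * _NAO ** 3 * Cai * 2.5)
             / ((87.5 ** 3 + _NAO ** 3) * (1.38 + _CAO) * (1.0 + 0.1 * e2)))
    inak = (p[7] * _KO * Nai
            / ((_KO + 1.0) * (Nai + 40.0)
               * (1.0 + 0.1245 * np.exp(-0.1 * V / _RTF) + 0.0353 * np.exp(-V / _RTF))))
    ipca = p[8] * Cai / (0.0005 + Cai)
    ipk = p[9] * (V - ek) / (1.0 + np.exp((25.0 - V) / 5.98))
    ibna = p[10] * (V - ena)
    ibca = p[11] * (V - eca)

    itot = (ina + inal + ik1 + ito + ikr + iks + ical + inaca + inak
            + ipca + ipk + ibna + ibca + i_stim)

    # calcium dynamics
    kcasr = 2.5 - 1.5 / (1.0 + (1.5 / CaSR) ** 2)
    k1 = 0.15 / kcasr
    k2 = 0.045 * kcasr
    dRbar = (-k2 * CaSS * Rbar + 0.005 * (1.0 - Rbar)) * dt
    y[20] = Rbar + dRbar
    O = k1 * CaSS * CaSS * y[20] / (0.06 + k1 * CaSS * CaSS)
    irel = 0.102 * (p[13] / 0.102) * O * (CaSR - CaSS)
    ileak = p[14] * (CaSR - Cai)
    iup = p[12] / (1.0 + (0.00025 / Cai) ** 2)
    ixfer = p[15] * (CaSS - Cai)

    # SR calcium with calsequestrin buffering (quadratic update)
    ca_csqn = 10.0 * CaSR / (CaSR + 0.3)
    dCaSR = dt * (iup - irel - ileak)
    b = 10.0 - ca_csqn - dCaSR - CaSR + 0.3
    c = 0.3 * (ca_csqn + dCaSR + CaSR)
    y[18] = (np.sqrt(b * b + 4.0 * c) - b) * 0.5

    # subspace calcium
    ca_ssbuf = 0.4 * CaSS / (CaSS + 0.00025)
    dCaSS = dt * (-ixfer * (_VC / _VSS) + irel * (_VSR / _VSS) - ical * _INV_VSSF2)
    b = 0.4 - ca_ssbuf - dCaSS - CaSS + 0.00025
    c = 0.00025 * (ca_ssbuf + dCaSS + CaSS)
    y[19] = (np.sqrt(b * b + 4.0 * c) - b) * 0.5

    # cytosolic calcium
    ca_buf = 0.2 * Cai / (Cai + 0.001)
    dCai = dt * (-(ibca + ipca - 2.0 * inaca) * _INV_VCF2
                 - (iup - ileak) * (_VSR / _VC) + ixfer)
    b = 0.2 - ca_buf - dCai - Cai + 0.001
    c = 0.001 * (ca_buf + dCai + Cai)
    y[17] = (np.sqrt(b * b + 4.0 * c) - b) * 0.5

    y[15] = Nai - dt * (ina + inal + ibna + 3.0 * inak + 3.0 * inaca) * _INV_VCF
    y[16] = Ki - dt * (i_stim + ik1 + ito + ikr + iks - 2.0 * inak + ipk) * _INV_VCF
    y[0] = V - dt * itot
    return itot


@njit(cache=True, fastmath=True)
def _pace_kernel(y, p, celltype, cl, n_beats, dt, stim_amp, stim_dur,
                 record_beats, rec_stride):
    """Pace the cell; record (t, V) of the last `record_beats` beats.

    Returns (t_rec, v_rec, n_rec, status); status 0 ok, 1 non-finite state.
    """
    steps_per_beat = int(round(cl / dt))
    total_steps = steps_per_beat * n_beats
    rec_start = steps_per_beat * (n_beats - record_beats)
    max_rec = (total_steps - rec_start) // rec_stride + 2
    t_rec = np.empty(max_rec)
    v_rec = np.empty(max_rec)
    n_rec = 0
    stim_steps = int(round(stim_dur / dt))
    for step in range(total_steps):
        phase = step % steps_per_beat
        i_stim = stim_amp if phase < stim_steps else 0.0
        ionic_step(y, p, celltype, dt, i_stim)
        if step >= rec_start and (step - rec_start) % rec_stride == 0:
            t_rec[n_rec] = (step + 1) * dt
            v_rec[n_rec] = y[0]
            n_rec += 1
    status = 0
    for k in range(y.shape[0]):
        if not np.isfinite(y[k]):
            status = 1
            break
    return t_rec, v_rec, n_rec, status


# ---------------------------------------------------------------------------
# Public protocols
# ---------------------------------------------------------------------------

STIM_AMPLITUDE = -52.0   # pA/pF
STIM_DURATION_MS = 1.0


class IntegrationError(RuntimeError):
    """Raised when the state integration diverges (non-finite variable)."""


def step_cell(state: CellState, params: IonicParams, dt: float,
              i_stim: float = 0.0) -> CellState:
    """Advance a cell state by one time step.

    ``i_stim`` is the stimulus current in pA/pF (negative = depolarizing).
    Raises :class:`IntegrationError` naming the first divergent state
    variable if the update produces a non-finite value.
    """
    if dt > 0.05:
        raise ValueError("dt must be <= 0.05 ms for explicit integration")
    if not np.all(np.isfinite(state.y)):
        bad = STATE_NAMES[int(np.argmax(~np.isfinite(state.y)))]
        raise IntegrationError(f"integration failure: state variable {bad!r} "
                               f"is non-finite at t={state.t:.3f} ms")
    new = state.copy()
    ionic_step(new.y, params.to_vector(), params.celltype_code, dt, i_stim)
    if not np.all(np.isfinite(new.y)):
        bad = STATE_NAMES[int(np.argmax(~np.isfinite(new.y)))]
        raise IntegrationError(f"integration failure: state variable {bad!r} "
                               f"became non-finite at t={state.t + dt:.3f} ms")
    new.t = state.t + dt
    return new


def pace(params: IonicParams, cycle_length_ms: float, n_beats: int,
         dt: float = config.CELL_DT_MS, record_beats: int = 1,
         rec_stride: int = 5, state: CellState | None = None):
    """Steady pacing; returns (t, V) of the final beats and the final state."""
    y = (_default_state_vector() if state is None else state.y.copy())
    t_rec, v_rec, n, status = _pace_kernel(
        y, params.to_vector(), params.celltype_code, cycle_length_ms,
        n_beats, dt, STIM_AMPLITUDE, STIM_DURATION_MS, record_beats, rec_stride)
    if status != 0:
        raise IntegrationError("integration failure: non-finite state during pacing")
    return t_rec[:n], v_rec[:n], CellState(y, n_beats * cycle_length_ms)


def _apd90_from_trace(t: np.ndarray, v: np.ndarray) -> float:
    """APD90 from a single-beat trace: max-dV/dt upstroke to 90% repolarization."""
    dv = np.diff(v) / np.diff(t)
    i_up = int(np.argmax(dv))
    v_rest = v[0]
    v_peak = float(np.max(v[i_up:]))
    if v_peak < -40.0:
        raise RuntimeError("no action potential elicited")
    v90 = v_peak - 0.9 * (v_peak - v_rest)
    i_peak = i_up + int(np.argmax(v[i_up:]))
    below = np.nonzero(v[i_peak:] <= v90)[0]
    if below.size == 0:
        raise RuntimeError("action potential did not repolarize to 90%")
    k = i_peak + below[0]
    # linear interpolation of the crossing time
    t_cross = t[k - 1] + (t[k] - t[k - 1]) * (v[k - 1] - v90) / (v[k - 1] - v[k])
    t_up = t[i_up]
    return float(t_cross - t_up)


def apd90_trace(params: IonicParams,
                cycle_length_ms: float = config.APD_CALIBRATION_CL_MS,
                n_beats: int = config.APD_CALIBRATION_BEATS,
                dt: float = config.CELL_DT_MS):
    """Final-beat trace and its APD90 under steady pacing."""
    if n_beats < 20:
        raise ValueError("need >= 20 beats to approach steady state")
    t, v, _ = pace(params, cycle_length_ms, n_beats, dt=dt, record_beats=1,
                   rec_stride=2)
    return t, v, _apd90_from_trace(t, v)


def apd90(params: IonicParams,
          cycle_length_ms: float = config.APD_CALIBRATION_CL_MS,
          n_beats: int = config.APD_CALIBRATION_BEATS,
          dt: float = config.CELL_DT_MS) -> float:
    """Steady-state action potential duration at 90% repolarization (ms)."""
    return apd90_trace(params, cycle_length_ms, n_beats, dt)[2]


def notch_depth(params: IonicParams,
                cycle_length_ms: float = config.APD_CALIBRATION_CL_MS,
                n_beats: int = config.APD_CALIBRATION_BEATS,
                dt: float = config.CELL_DT_MS) -> float:
    """Depth of the phase-1 notch (mV) on the steady-state action potential.

    Measured as the drop from the initial spike peak to the notch minimum
    within the first 50 ms after the upstroke, before the dome.  A smaller
    value means a diminished notch.
    """
    t, v, _ = apd90_trace(params, cycle_length_ms, n_beats, dt)
    dv = np.diff(v) / np.diff(t)
    i_up = int(np.argmax(dv))
    t_rel = t - t[i_up]
    win = (t_rel >= 0.0) & (t_rel <= 50.0)
    vw = v[win]
    i_peak = int(np.argmax(vw[: max(2, np.searchsorted(t_rel[win], 10.0))]))
    v_spike = float(vw[i_peak])
    v_notch = float(np.min(vw[i_peak:]))
    return v_spike - v_notch


def calibrate_baseline(target_apd_ms: float = config.APD_BASELINE_TARGET_MS,
                       celltype: str = "epi",
                       g_nal: float | None = None,
                       cycle_length_ms: float = config.APD_CALIBRATION_CL_MS,
                       n_beats: int = config.APD_CALIBRATION_BEATS,
                       dt: float = config.CELL_DT_MS,
                       n_iter: int = 35) -> float:
    """Calibrate the baseline cell's APD90 via the repolarization reserve.

    Returns the joint multiplier on (G_Kr, G_Ks) that brings the nonfibrotic
    cell's steady-pacing APD90 to ``target_apd_ms`` with the late-sodium
    conductance held at its nominal value.  The intrinsic APD90 of the base
    formulation exceeds the target, so the calibration enlarges the
    delayed-rectifier reserve (APD90 is monotone decreasing in the scale).
    """
    lo, hi = 1.0, 3.0
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        p = make_params("normal", celltype=celltype, g_nal=g_nal,
                        repol_scale=mid)
        if apd90(p, cycle_length_ms, n_beats, dt) > target_apd_ms:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def calibrate_g_nal(target_apd_ms: float = config.APD_BASELINE_TARGET_MS,
                    celltype: str = "epi",
                    cycle_length_ms: float = config.APD_CALIBRATION_CL_MS,
                    n_beats: int = config.APD_CALIBRATION_BEATS,
                    dt: float = config.CELL_DT_MS,
                    tol_ms: float = 0.5, g_hi: float = 0.06) -> float:
    """Calibrate the baseline late-sodium conductance to a target APD90.

    Bisection on g_NaL in [0, g_hi] with the base formulation's published
    delayed-rectifier conductances (no repolarization-reserve scaling).
    Raises if the target lies outside the attainable range (APD90 is monotone
    increasing in g_NaL); for the 280 ms baseline target this is the case,
    which is why the package calibrates via :func:`calibrate_baseline`.
    """
    def f(g):
        p = make_params("normal", celltype=celltype, g_nal=g, repol_scale=1.0)
        return apd90(p, cycle_length_ms, n_beats, dt) - target_apd_ms

    lo, hi = 0.0, g_hi
    f_lo = f(lo)
    if f_lo > tol_ms:
        raise RuntimeError(
            f"baseline APD90 without I_NaL ({f_lo + target_apd_ms:.1f} ms) "
            f"already exceeds the target {target_apd_ms} ms")
    f_hi = f(hi)
    if f_hi < -tol_ms:
        raise RuntimeError("target APD90 not reachable within g_NaL bound")
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if abs(fm) <= tol_ms:
            return mid
        if fm < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
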