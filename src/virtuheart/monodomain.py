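"""Anisotropic monodomain reaction–diffusion solver on structured 2-D grids.

The transmembrane potential obeys

    dV/dt = div( D grad V ) - I_ion(V, state)/Cm + I_stim/Cm,

with D = sigma / (chi * Cm) the effective diffusivity tensor built per
element from the fiber direction, sigma_l along and sigma_t across the
fiber.  Dense fibrosis (scar) is excluded from the conducting domain (an
internal no-flux boundary); diffuse fibrosis conducts with the same tensor
but carries the remodeled myocyte variant.  External boundaries are no-flux.

Time integration is first-order operator splitting: an explicit conservative
finite-volume diffusion step and a per-node ionic step (Rush–Larsen gates,
forward-Euler V and concentrations).  Gate steady states and exponential
integrator factors are pre-tabulated on a voltage grid for speed; the table
step (0.05 mV) keeps the tabulation error well below the model error.

Activation times (upstroke crossing of -40 mV, re-armed below -60 mV) are
recorded per node during the simulation and form the ActivationRecord from
which conduction velocity and reentry are measured.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from . import config, ionic
from .fusion import LABEL_DIFFUSE
from .geometry import VentricularGrid, FiberField

__all__ = [
    "MonodomainConfig", "Stimulus", "ActivationRecord", "SimMesh",
    "assemble_conductivity", "prepare", "simulate", "measure_cv",
    "calibrate_sigma_l", "sigma_to_diffusivity", "desk_config",
]

MAX_ACTIVATIONS = 40          # recorded upstrokes per node
ACT_THRESHOLD_MV = -40.0      # upstroke detection threshold
REARM_MV = -60.0
QUIESCENT_MV = -65.0


def sigma_to_diffusivity(sigma_s_m: float, chi_per_cm: float, cm_uf_cm2: float) -> float:
    """Conductivity (S/m) to effective diffusivity (cm^2/ms)."""
    sigma_ms_cm = sigma_s_m * 10.0
    return sigma_ms_cm / (chi_per_cm * cm_uf_cm2)


def desk_config(duration_ms: float = 1000.0) -> "MonodomainConfig":
    """Scaled-down tissue configuration for the 2-D substrate studies."""
    sig = config.SIGMA_L_S_M * config.DESK_SIGMA_SCALE
    return MonodomainConfig(sigma_l=sig, sigma_t=sig,
                            dt_ms=config.DESK_TISSUE_DT_MS,
                            duration_ms=duration_ms)


@dataclass(frozen=True)
class MonodomainConfig:
    """Tissue-scale physical and numerical parameters."""
    sigma_l: float = config.SIGMA_L_S_M   # S/m, along fiber (calibrated 0.6 m/s)
    sigma_t: float = config.SIGMA_L_S_M / config.ANISOTROPY_SIGMA_RATIO
    chi_per_cm: float = 1400.0      # surface-to-volume ratio
    cm_uf_cm2: float = 1.0          # membrane capacitance
    dt_ms: float = config.TISSUE_DT_MS
    duration_ms: float = 1000.0
    abort_mv: float = 200.0         # |V| beyond this aborts with diagnostics

    def __post_init__(self):
        if not (self.sigma_l >= self.sigma_t > 0):
            raise ValueError("need sigma_l >= sigma_t > 0")
        if self.dt_ms <= 0:
            raise ValueError("dt must be positive")

    @property
    def d_l(self) -> float:
        return sigma_to_diffusivity(self.sigma_l, self.chi_per_cm, self.cm_uf_cm2)

    @property
    def d_t(self) -> float:
        return sigma_to_diffusivity(self.sigma_t, self.chi_per_cm, self.cm_uf_cm2)


@dataclass(frozen=True)
class Stimulus:
    """Transmembrane stimulus on a node set (amplitude in pA/pF, negative =
    depolarizing)."""
    nodes: np.ndarray
    onset_ms: float
    duration_ms: float = 2.0
    amplitude: float = -52.0

    def __post_init__(self):
        object.__setattr__(self, "nodes", np.asarray(self.nodes, dtype=np.int64))
        if self.nodes.size == 0:
            raise ValueError("stimulus node set is empty")
        if self.duration_ms <= 0:
            raise ValueError("stimulus duration must be positive")


def assemble_conductivity(grid: VentricularGrid, fibers: FiberField,
                          cfg: MonodomainConfig) -> np.ndarray:
    """Per-element in-plane diffusivity tensors (M, 3): (Dxx, Dyy, Dxy).

    D = d_l f f^T + d_t (I - f f^T) restricted to the slice plane; dense
    elements get the zero tensor (excluded from the conducting domain).
    Raises on non-unit fibers.
    """
    f = fibers.fibers
    if f.shape[0] != grid.n_elements:
        raise ValueError("fiber field does not match grid")
    norms = np.linalg.norm(f, axis=1)
    if np.any(np.abs(1.0 - norms) >= 1e-9):
        raise ValueError("fiber vectors must be unit-norm")
    fx, fy = f[:, 0], f[:, 1]
    dl, dtt = cfg.d_l, cfg.d_t
    tens = np.stack([
        dtt + (dl - dtt) * fx * fx,
        dtt + (dl - dtt) * fy * fy,
        (dl - dtt) * fx * fy,
    ], axis=1)
    tens[~grid.conducting] = 0.0
    return tens


# ---------------------------------------------------------------------------
# Mesh preparation
# ---------------------------------------------------------------------------

@dataclass
class SimMesh:
    """Compact conducting-node representation of a tissue problem."""
    grid: VentricularGrid
    coords: np.ndarray            # (n, 2) mm
    active_ids: np.ndarray        # grid node index of each sim node
    grid_to_sim: np.ndarray       # inverse map (-1 where not simulated)
    nbr: np.ndarray               # (n, 4) axis neighbors (-1 none)
    gcoef: np.ndarray             # (n, 4) edge conductances / h^2 (1/ms)
    dnbr: np.ndarray              # (n, 4) diagonal neighbors
    dcoef: np.ndarray             # (n, 4) cross-term coefficients (1/ms)
    variant: np.ndarray           # (n,) 0 normal, 1 remodeled
    celltype: int
    params2: np.ndarray           # (2, 17) ionic parameter rows

    @property
    def n_nodes(self) -> int:
        return self.coords.shape[0]

    def nodes_within(self, center_mm, radius_mm: float) -> np.ndarray:
        d = np.linalg.norm(self.coords - np.asarray(center_mm), axis=1)
        return np.nonzero(d <= radius_mm)[0]

    def sim_nodes_of(self, grid_node_ids) -> np.ndarray:
        s = self.grid_to_sim[np.asarray(grid_node_ids, dtype=int)]
        return s[s >= 0]


def prepare(grid: VentricularGrid, fibers: FiberField, cfg: MonodomainConfig,
            variant_map: dict | None = None,
            normal_params: ionic.IonicParams | None = None,
            remodeled_params: ionic.IonicParams | None = None) -> SimMesh:
    """Build the compact conducting-node problem from grid + fibers.

    ``variant_map`` maps tissue labels to myocyte variants; by default normal
    myocardium uses the nonfibrotic variant and diffuse fibrosis the
    remodeled one.  A node is remodeled when any adjacent conducting element
    is diffuse-labeled.
    """
    tens = assemble_conductivity(grid, fibers, cfg)
    ny1, nx1 = grid.node_id.shape
    ney, nex = ny1 - 1, nx1 - 1

    # element-grid tensor images (0 where absent or dense)
    exx = np.zeros((ney, nex)); eyy = np.zeros((ney, nex)); exy = np.zeros((ney, nex))
    er, ec = grid.elem_ij[:, 0], grid.elem_ij[:, 1]
    exx[er, ec] = tens[:, 0]
    eyy[er, ec] = tens[:, 1]
    exy[er, ec] = tens[:, 2]
    cond = np.zeros((ney, nex), dtype=bool)
    cond[er, ec] = grid.conducting

    if variant_map is None:
        variant_map = {LABEL_DIFFUSE: "remodeled"}
    remod = np.zeros((ney, nex), dtype=bool)
    lab = grid.elem_label
    for label, var in variant_map.items():
        if var == "remodeled":
            remod |= cond & (lab == label)

    # active nodes: adjacent to >= 1 conducting element
    node_active = np.zeros((ny1, nx1), dtype=bool)
    node_remod = np.zeros((ny1, nx1), dtype=bool)
    for dr in (0, 1):
        for dc in (0, 1):
            node_active[dr:ney + dr, dc:nex + dc] |= cond
            node_remod[dr:ney + dr, dc:nex + dc] |= remod
    sim_of = np.full((ny1, nx1), -1, dtype=np.int64)
    rr, cc = np.nonzero(node_active)
    n = rr.size
    sim_of[rr, cc] = np.arange(n)

    h_cm = grid.h_mm / 10.0
    inv_h2 = 1.0 / (h_cm * h_cm)

    def elem_at(r, c, arr):
        if 0 <= r < ney and 0 <= c < nex and cond[r, c]:
            return arr[r, c]
        return 0.0

    nbr = np.full((n, 4), -1, dtype=np.int64)
    gcoef = np.zeros((n, 4))
    dnbr = np.full((n, 4), -1, dtype=np.int64)
    dcoef = np.zeros((n, 4))
    # axis neighbor offsets: +x, -x, +y, -y ; diagonals: (+1,+1),(+1,-1),(-1,+1),(-1,-1)
    for idx in range(n):
        r, c = rr[idx], cc[idx]
        # +x edge between (r,c)-(r,c+1); flanking elements (r-1,c) and (r,c)
        steps = (
            (0, (r, c + 1), 0.5 * (elem_at(r - 1, c, exx) + elem_at(r, c, exx))),
            (1, (r, c - 1), 0.5 * (elem_at(r - 1, c - 1, exx) + elem_at(r, c - 1, exx))),
            (2, (r + 1, c), 0.5 * (elem_at(r, c - 1, eyy) + elem_at(r, c, eyy))),
            (3, (r - 1, c), 0.5 * (elem_at(r - 1, c - 1, eyy) + elem_at(r - 1, c, eyy))),
        )
        for k, (r2, c2), g in steps:
            if g > 0 and 0 <= r2 < ny1 and 0 <= c2 < nx1 and sim_of[r2, c2] >= 0:
                nbr[idx, k] = sim_of[r2, c2]
                gcoef[idx, k] = g * inv_h2
        diags = (
            ((+1, +1), elem_at(r, c, exy), +1.0),
            ((+1, -1), elem_at(r, c - 1, exy), -1.0),
            ((-1, +1), elem_at(r - 1, c, exy), -1.0),
            ((-1, -1), elem_at(r - 1, c - 1, exy), +1.0),
        )
        for k, ((dr, dc), dxy, sign) in enumerate(diags):
            r2, c2 = r + dr, c + dc
            if dxy != 0.0 and 0 <= r2 < ny1 and 0 <= c2 < nx1 and sim_of[r2, c2] >= 0:
                dnbr[idx, k] = sim_of[r2, c2]
                dcoef[idx, k] = sign * dxy * 0.5 * inv_h2

    if normal_params is None:
        normal_params = ionic.make_params("normal")
    if remodeled_params is None:
        remodeled_params = ionic.make_params("remodeled",
                                             celltype=normal_params.celltype)
    params2 = np.stack([normal_params.to_vector(), remodeled_params.to_vector()])

    return SimMesh(
        grid=grid,
        coords=np.stack([cc * grid.h_mm, rr * grid.h_mm], axis=1).astype(float),
        active_ids=grid.node_id[rr, cc],
        grid_to_sim=_grid_to_sim(grid, sim_of),
        nbr=nbr, gcoef=gcoef, dnbr=dnbr, dcoef=dcoef,
        variant=node_remod[rr, cc].astype(np.uint8),
        celltype=normal_params.celltype_code,
        params2=params2,
    )


def _grid_to_sim(grid: VentricularGrid, sim_of: np.ndarray) -> np.ndarray:
    out = np.full(grid.n_nodes, -1, dtype=np.int64)
    rr, cc = np.nonzero(grid.node_id >= 0)
    out[grid.node_id[rr, cc]] = sim_of[rr, cc]
    return out


# ---------------------------------------------------------------------------
# Gate lookup tables
# ---------------------------------------------------------------------------

_TAB_VMIN, _TAB_VMAX, _TAB_DV = -100.0, 100.0, 0.05
_RTF = 26.713760659695652
_F = 96485.3415
_table_cache: dict = {}


def _gate_lut(dt: float, celltype: int):
    """Voltage tables: gate steady states, Rush-Larsen factors, and the
    voltage-dependent current factors (exchanger/pump/ICaL/IpK/IK1)."""
    key = (round(dt, 9), celltype)
    if key not in _table_cache:
        nv = int(round((_TAB_VMAX - _TAB_VMIN) / _TAB_DV)) + 1
        inf_tab = np.empty((nv, 14))
        b_tab = np.empty((nv, 14))
        cur_tab = np.empty((nv, 6))
        tau_tab = np.empty((nv, 14))
        v = _TAB_VMIN + _TAB_DV * np.arange(nv)
        for i in range(nv):
            inf, tau = ionic.gate_tables(v[i], celltype)
            inf_tab[i] = inf
            tau_tab[i] = tau
            b_tab[i] = np.exp(-dt / tau)
        cur_tab[:, 0] = np.exp(0.35 * v / _RTF)             # NCX forward
        cur_tab[:, 1] = np.exp(-0.65 * v / _RTF)            # NCX reverse
        ex = np.exp(2.0 * (v - 15.0) / _RTF)
        with np.errstate(invalid="ignore", divide="ignore"):
            a = 2.0 * _F * (v - 15.0) / _RTF / (ex - 1.0)   # ICaL driving
        sing = np.abs(v - 15.0) < 1e-9
        a[sing] = _F
        cur_tab[:, 2] = a * 0.25 * ex                        # * CaSS term
        cur_tab[:, 3] = a * 2.0                              # * Cao term
        cur_tab[:, 4] = 1.0 / (1.0 + 0.1245 * np.exp(-0.1 * v / _RTF)
                               + 0.0353 * np.exp(-v / _RTF))  # INaK factor
        cur_tab[:, 5] = 1.0 / (1.0 + np.exp((25.0 - v) / 5.98))  # IpK factor
        # inward-rectifier gate on u = V - EK
        nu = int(round((_U_MAX - _U_MIN) / _TAB_DV)) + 1
        u = _U_MIN + _TAB_DV * np.arange(nu)
        ak1 = 0.1 / (1.0 + np.exp(0.06 * (u - 200.0)))
        bk1 = ((3.0 * np.exp(0.0002 * (u + 100.0)) + np.exp(0.1 * (u - 10.0)))
               / (1.0 + np.exp(-0.5 * u)))
        xk1_tab = ak1 / (ak1 + bk1)
        _table_cache[key] = (inf_tab, b_tab, cur_tab, xk1_tab, tau_tab)
    return _table_cache[key]


_U_MIN, _U_MAX = -150.0, 200.0


# ---------------------------------------------------------------------------
# Kernel
# ---------------------------------------------------------------------------

_VC_VSS = 0.016404 / 0.00005468
_VSR_VSS = 0.001094 / 0.00005468
_VSR_VC = 0.001094 / 0.016404
_INV_VSSF2T = 1.0 / (2.0 * 0.00005468 * 96485.3415) * 0.185
_INV_VCF2T = 1.0 / (2.0 * 0.016404 * 96485.3415) * 0.185
_INV_VCFT = 1.0 / (0.016404 * 96485.3415) * 0.185


@njit(cache=True, fastmath=True)
def _node_ionic_lut(y, i, p, dt, i_stim, inf_tab, b_tab, cur_tab, xk1_tab,
                    ena_c, ek_c, eks_c, eca_c):
    """Tissue-node ionic update using tabulated gate and current kinetics.

    Mirrors ionic.ionic_step (cross-checked in the test suite); Nernst
    potentials are supplied from a periodically refreshed per-node cache.
    """
    V = y[0, i]
    Nai, Ki, Cai = y[15, i], y[16, i], y[17, i]
    CaSR, CaSS, Rbar = y[18, i], y[19, i], y[20, i]

    x = (V - _TAB_VMIN) / _TAB_DV
    if x < 0.0:
        x = 0.0
    elif x > inf_tab.shape[0] - 1.001:
        x = inf_tab.shape[0] - 1.001
    i0 = int(x)
    w = x - i0
    for k in range(14):
        if k == 6:
            continue
        inf = inf_tab[i0, k] * (1.0 - w) + inf_tab[i0 + 1, k] * w
        b = b_tab[i0, k] * (1.0 - w) + b_tab[i0 + 1, k] * w
        y[1 + k, i] = inf + (y[1 + k, i] - inf) * b
    fcass_inf = 0.6 / (1.0 + (CaSS / 0.05) ** 2) + 0.4
    tau_fcass = 80.0 / (1.0 + (CaSS / 0.05) ** 2) + 2.0
    y[7, i] = fcass_inf + (y[7, i] - fcass_inf) * np.exp(-dt / tau_fcass)

    m, h, j = y[1, i], y[2, i], y[3, i]
    d, f, f2, fcass = y[4, i], y[5, i], y[6, i], y[7, i]
    r, s = y[8, i], y[9, i]
    xr1, xr2, xs = y[10, i], y[11, i], y[12, i]
    mL, hL = y[13, i], y[14, i]

    ena, ek, eks, eca = ena_c[i], ek_c[i], eks_c[i], eca_c[i]

    c0 = cur_tab[i0, 0] * (1.0 - w) + cur_tab[i0 + 1, 0] * w
    c1 = cur_tab[i0, 1] * (1.0 - w) + cur_tab[i0 + 1, 1] * w
    c2 = cur_tab[i0, 2] * (1.0 - w) + cur_tab[i0 + 1, 2] * w
    c3 = cur_tab[i0, 3] * (1.0 - w) + cur_tab[i0 + 1, 3] * w
    c4 = cur_tab[i0, 4] * (1.0 - w) + cur_tab[i0 + 1, 4] * w
    c5 = cur_tab[i0, 5] * (1.0 - w) + cur_tab[i0 + 1, 5] * w

    ina = p[0] * m * m * m * h * j * (V - ena)
    inal = p[16] * mL * hL * (V - ena)
    u = (V - ek - _U_MIN) / _TAB_DV
    if u < 0.0:
        u = 0.0
    elif u > xk1_tab.shape[0] - 1.001:
        u = xk1_tab.shape[0] - 1.001
    j0 = int(u)
    wu = u - j0
    xk1 = xk1_tab[j0] * (1.0 - wu) + xk1_tab[j0 + 1] * wu
    ik1 = p[1] * xk1 * (V - ek)
    ito = p[2] * r * s * (V - ek)
    ikr = p[3] * xr1 * xr2 * (V - ek)
    iks = p[4] * xs * xs * (V - eks)
    ical = p[5] * d * f * f2 * fcass * 2.0 * (c2 * CaSS - c3)
    inaca = (p[6] * (c0 * Nai ** 3 * 2.0 - c1 * 140.0 ** 3 * Cai * 2.5)
             / ((87.5 ** 3 + 140.0 ** 3) * (1.38 + 2.0) * (1.0 + 0.1 * c1)))
    inak = p[7] * 5.4 * Nai / ((5.4 + 1.0) * (Nai + 40.0)) * c4
    ipca = p[8] * Cai / (0.0005 + Cai)
    ipk = p[9] * (V - ek) * c5
    ibna = p[10] * (V - ena)
    ibca = p[11] * (V - eca)

    itot = (ina + inal + ik1 + ito + ikr + iks + ical + inaca + inak
            + ipca + ipk + ibna + ibca + i_stim)

    kcasr = 2.5 - 1.5 / (1.0 + (1.5 / CaSR) ** 2)
    k1 = 0.15 / kcasr
    k2 = 0.045 * kcasr
    y[20, i] = Rbar + (-k2 * CaSS * Rbar + 0.005 * (1.0 - Rbar)) * dt
    O = k1 * CaSS * CaSS * y[20, i] / (0.06 + k1 * CaSS * CaSS)
    irel = p[13] * O * (CaSR - CaSS)
    ileak = p[14] * (CaSR - Cai)
    iup = p[12] / (1.0 + (0.00025 / Cai) ** 2)
    ixfer = p[15] * (CaSS - Cai)

    ca_csqn = 10.0 * CaSR / (CaSR + 0.3)
    dCaSR = dt * (iup - irel - ileak)
    b = 10.0 - ca_csqn - dCaSR - CaSR + 0.3
    c = 0.3 * (ca_csqn + dCaSR + CaSR)
    y[18, i] = (np.sqrt(b * b + 4.0 * c) - b) * 0.5

    ca_ssbuf = 0.4 * CaSS / (CaSS + 0.00025)
    dCaSS = dt * (-ixfer * (_VC_VSS) + irel * (_VSR_VSS) - ical * _INV_VSSF2T)
    b = 0.4 - ca_ssbuf - dCaSS - CaSS + 0.00025
    c = 0.00025 * (ca_ssbuf + dCaSS + CaSS)
    y[19, i] = (np.sqrt(b * b + 4.0 * c) - b) * 0.5

    ca_buf = 0.2 * Cai / (Cai + 0.001)
    dCai = dt * (-(ibca + ipca - 2.0 * inaca) * _INV_VCF2T
                 - (iup - ileak) * (_VSR_VC) + ixfer)
    b = 0.2 - ca_buf - dCai - Cai + 0.001
    c = 0.001 * (ca_buf + dCai + Cai)
    y[17, i] = (np.sqrt(b * b + 4.0 * c) - b) * 0.5

    y[15, i] = Nai - dt * (ina + inal + ibna + 3.0 * inak + 3.0 * inaca) * _INV_VCFT
    y[16, i] = Ki - dt * (i_stim + ik1 + ito + ikr + iks - 2.0 * inak + ipk) * _INV_VCFT
    y[0, i] = V - dt * itot
    return itot


# sleeping-node thresholds: a node may sleep when fully repolarized with a
# negligible net membrane current and no diffusive drive; it wakes as soon as
# a neighbor depolarizes (or a stimulus arrives), with its gates advanced by
# the exact constant-voltage Rush-Larsen solution over the slept interval.
_SLEEP_VMIN, _SLEEP_VMAX = -89.0, -83.0
_SLEEP_ITOT = 0.002      # pA/pF
_SLEEP_DIFF = 0.005      # mV/ms
_WAKE_DIFF = 0.05        # mV/ms


@njit(cache=True, fastmath=True)
def _wake_node(y, i, slept_ms, inf_tab, tau_tab):
    """Fast-forward a slept node's gates (V and concentrations held)."""
    V = y[0, i]
    x = (V - _TAB_VMIN) / _TAB_DV
    if x < 0.0:
        x = 0.0
    elif x > inf_tab.shape[0] - 1.001:
        x = inf_tab.shape[0] - 1.001
    i0 = int(x)
    w = x - i0
    for k in range(14):
        if k == 6:
            continue
        inf = inf_tab[i0, k] * (1.0 - w) + inf_tab[i0 + 1, k] * w
        tau = tau_tab[i0, k] * (1.0 - w) + tau_tab[i0 + 1, k] * w
        y[1 + k, i] = inf + (y[1 + k, i] - inf) * np.exp(-slept_ms / tau)
    CaSS = y[19, i]
    fcass_inf = 0.6 / (1.0 + (CaSS / 0.05) ** 2) + 0.4
    tau_fcass = 80.0 / (1.0 + (CaSS / 0.05) ** 2) + 2.0
    y[7, i] = fcass_inf + (y[7, i] - fcass_inf) * np.exp(-slept_ms / tau_fcass)
    # ryanodine-receptor recovery gate: linear ODE at constant subspace Ca
    kcasr = 2.5 - 1.5 / (1.0 + (1.5 / y[18, i]) ** 2)
    k2 = 0.045 * kcasr * CaSS
    tau_r = 1.0 / (k2 + 0.005)
    r_inf = 0.005 * tau_r
    y[20, i] = r_inf + (y[20, i] - r_inf) * np.exp(-slept_ms / tau_r)


@njit(cache=True, fastmath=True)
def _tissue_kernel(y, variant, params2, nbr, gcoef, dnbr, dcoef,
                   inf_tab, b_tab, cur_tab, xk1_tab, tau_tab, dt, n_steps, t0,
                   stim_start, stim_count, stim_nodes_flat,
                   stim_onset, stim_dur, stim_amp,
                   act_times, act_counts, armed,
                   stop_quiescent, quiet_after, stop_acts, stop_min_nodes,
                   abort_mv, check_every):
    """Main explicit time-stepping loop.  Returns (status, t_end):
    status 0 = completed, 1 = quiescent stop, 2 = reentry stop, 3 = aborted.
    """
    n = y.shape[1]
    diff = np.empty(n)
    stim_cur = np.zeros(n)
    n_stim = stim_onset.shape[0]
    status = 0
    t_end = t0 + n_steps * dt
    asleep = np.zeros(n, dtype=np.uint8)
    sleep_step = np.zeros(n, dtype=np.int64)
    sub_thresh = False
    # Nernst-potential cache, refreshed every 10 steps (concentrations drift
    # on a much slower time scale than the refresh interval)
    ena_c = np.empty(n)
    ek_c = np.empty(n)
    eks_c = np.empty(n)
    eca_c = np.empty(n)
    for step in range(n_steps):
        t = t0 + step * dt
        if step % 10 == 0:
            for i in range(n):
                if asleep[i] == 0:
                    ena_c[i] = _RTF * np.log(140.0 / y[15, i])
                    ek_c[i] = _RTF * np.log(5.4 / y[16, i])
                    eks_c[i] = _RTF * np.log((5.4 + 4.2) / (y[16, i] + 0.03 * y[15, i]))
                    eca_c[i] = 0.5 * _RTF * np.log(2.0 / y[17, i])
        # stimulus currents
        any_stim = False
        for si in range(n_stim):
            if stim_onset[si] <= t < stim_onset[si] + stim_dur[si]:
                any_stim = True
        if any_stim:
            for i in range(n):
                stim_cur[i] = 0.0
            for si in range(n_stim):
                if stim_onset[si] <= t < stim_onset[si] + stim_dur[si]:
                    for k in range(stim_start[si], stim_start[si] + stim_count[si]):
                        stim_cur[stim_nodes_flat[k]] = stim_amp[si]
        # diffusion from current V
        for i in range(n):
            vi = y[0, i]
            acc = 0.0
            for k in range(4):
                jn = nbr[i, k]
                if jn >= 0:
                    acc += gcoef[i, k] * (y[0, jn] - vi)
                jn = dnbr[i, k]
                if jn >= 0:
                    acc += dcoef[i, k] * (y[0, jn] - vi)
            diff[i] = acc
        # ionic + combine
        for i in range(n):
            s_i = stim_cur[i] if any_stim else 0.0
            if asleep[i] == 1:
                if abs(diff[i]) > _WAKE_DIFF or s_i != 0.0:
                    _wake_node(y, i, (step - sleep_step[i]) * dt,
                               inf_tab, tau_tab)
                    asleep[i] = 0
                else:
                    continue
            itot = _node_ionic_lut(y, i, params2[variant[i]], dt, s_i, inf_tab,
                                   b_tab, cur_tab, xk1_tab,
                                   ena_c, ek_c, eks_c, eca_c)
            y[0, i] += dt * diff[i]
            vi = y[0, i]
            if armed[i]:
                if vi >= ACT_THRESHOLD_MV:
                    cnt = act_counts[i]
                    if cnt < act_times.shape[1]:
                        act_times[i, cnt] = t + dt
                        act_counts[i] = cnt + 1
                    armed[i] = False
                elif (s_i == 0.0 and _SLEEP_VMIN < vi < _SLEEP_VMAX
                        and abs(itot) < _SLEEP_ITOT
                        and abs(diff[i]) < _SLEEP_DIFF):
                    asleep[i] = 1
                    sleep_step[i] = step + 1
            elif vi <= REARM_MV:
                armed[i] = True
        if step % check_every == check_every - 1:
            vmax = -1e30
            vabs = 0.0
            for i in range(n):
                if y[0, i] > vmax:
                    vmax = y[0, i]
                a = abs(y[0, i])
                if a > vabs:
                    vabs = a
                if not np.isfinite(y[0, i]):
                    vabs = 1e30
            if vabs > abort_mv:
                status = 3
                t_end = t + dt
                break
            # quiescence: either fully repolarized, or no node above the
            # upstroke threshold on two consecutive checks -- without a
            # suprathreshold source no further activation is possible
            if stop_quiescent and t > quiet_after:
                if vmax < QUIESCENT_MV or (vmax < ACT_THRESHOLD_MV and sub_thresh):
                    status = 1
                    t_end = t + dt
                    break
                sub_thresh = vmax < ACT_THRESHOLD_MV
            else:
                sub_thresh = False
            if stop_acts > 0:
                nn = 0
                for i in range(n):
                    if act_counts[i] >= stop_acts:
                        nn += 1
                if nn >= stop_min_nodes:
                    status = 2
                    t_end = t + dt
                    break
    # wake remaining sleepers so the returned state is fully advanced
    end_step = int(round((t_end - t0) / dt))
    for i in range(n):
        if asleep[i] == 1:
            _wake_node(y, i, (end_step - sleep_step[i]) * dt, inf_tab, tau_tab)
    return status, t_end


# ---------------------------------------------------------------------------
# Public simulation API
# ---------------------------------------------------------------------------

@dataclass
class ActivationRecord:
    """Per-node activation-time history of a simulation segment."""
    times: np.ndarray          # (n, MAX_ACTIVATIONS) ms (nan-padded)
    counts: np.ndarray         # (n,)
    coords: np.ndarray         # (n, 2) mm
    t_start: float
    t_end: float
    last_stim_end: float
    status: int                # kernel status code
    final_state: np.ndarray    # (21, n) state at t_end

    @property
    def activated(self) -> np.ndarray:
        return self.counts > 0

    def first_activation(self) -> np.ndarray:
        out = np.full(self.counts.shape, np.nan)
        sel = self.counts > 0
        out[sel] = self.times[sel, 0]
        return out


class SimulationError(RuntimeError):
    pass


def initial_tissue_state(mesh: SimMesh) -> np.ndarray:
    """Resting state for every conducting node."""
    y0 = ionic._default_state_vector()
    return np.repeat(y0[:, None], mesh.n_nodes, axis=1)


def simulate(mesh: SimMesh, stimuli, cfg: MonodomainConfig,
             duration_ms: float | None = None,
             y0: np.ndarray | None = None, t0: float = 0.0,
             stop_quiescent: bool = False,
             stop_acts: int = 0, stop_min_nodes: int = 5,
             check_every_ms: float = 20.0) -> ActivationRecord:
    """Run the monodomain model and collect the activation record.

    Early-exit options: ``stop_quiescent`` ends the run once all nodes are
    repolarized below -65 mV after the last stimulus; ``stop_acts`` > 0 ends
    it once at least ``stop_min_nodes`` nodes have accumulated that many
    upstrokes (used by the induction protocol to cut short both failed and
    clearly reentrant attempts).  Aborts (status 3) on numerical instability.
    """
    if duration_ms is None:
        duration_ms = cfg.duration_ms
    dt = cfg.dt_ms
    # CFL-type stability guard for the explicit diffusion step
    h_cm = mesh.grid.h_mm / 10.0
    d_max = max(cfg.d_l, cfg.d_t)
    dt_stable = h_cm * h_cm / (4.0 * d_max)
    if dt > dt_stable:
        raise SimulationError(
            f"dt={dt} ms unstable for dx={mesh.grid.h_mm} mm "
            f"(explicit limit {dt_stable:.3f} ms)")
    y = initial_tissue_state(mesh) if y0 is None else y0.copy()
    if y.shape != (ionic.N_STATE, mesh.n_nodes):
        raise ValueError("state array shape mismatch")

    stimuli = list(stimuli)
    for s in stimuli:
        if np.any(s.nodes >= mesh.n_nodes) or np.any(s.nodes < 0):
            raise ValueError("stimulus node outside the conducting domain")
    if stimuli:
        starts = np.cumsum([0] + [s.nodes.size for s in stimuli])[:-1]
        stim_nodes_flat = np.concatenate([s.nodes for s in stimuli])
        stim_start = np.asarray(starts, dtype=np.int64)
        stim_count = np.array([s.nodes.size for s in stimuli], dtype=np.int64)
        stim_onset = np.array([s.onset_ms for s in stimuli])
        stim_dur = np.array([s.duration_ms for s in stimuli])
        stim_amp = np.array([s.amplitude for s in stimuli])
        last_stim_end = max(s.onset_ms + s.duration_ms for s in stimuli)
    else:
        stim_nodes_flat = np.zeros(0, dtype=np.int64)
        stim_start = np.zeros(0, dtype=np.int64)
        stim_count = np.zeros(0, dtype=np.int64)
        stim_onset = np.zeros(0)
        stim_dur = np.zeros(0)
        stim_amp = np.zeros(0)
        last_stim_end = t0

    n = mesh.n_nodes
    act_times = np.full((n, MAX_ACTIVATIONS), np.nan)
    act_counts = np.zeros(n, dtype=np.int64)
    armed = y[0] <= REARM_MV

    inf_tab, b_tab, cur_tab, xk1_tab, tau_tab = _gate_lut(dt, mesh.celltype)
    n_steps = int(round(duration_ms / dt))
    check_every = max(int(round(check_every_ms / dt)), 1)
    status, t_end = _tissue_kernel(
        y, mesh.variant, mesh.params2, mesh.nbr, mesh.gcoef, mesh.dnbr,
        mesh.dcoef, inf_tab, b_tab, cur_tab, xk1_tab, tau_tab, dt, n_steps, t0,
        stim_start, stim_count, stim_nodes_flat, stim_onset, stim_dur,
        stim_amp, act_times, act_counts, armed,
        stop_quiescent, last_stim_end + 50.0, stop_acts, stop_min_nodes,
        cfg.abort_mv, check_every)
    if status == 3:
        raise SimulationError(
            f"monodomain instability: |V| exceeded {cfg.abort_mv} mV at "
            f"t={t_end:.1f} ms (dt={dt}, dx={mesh.grid.h_mm} mm)")
    return ActivationRecord(times=act_times, counts=act_counts,
                            coords=mesh.coords, t_start=t0, t_end=t_end,
                            last_stim_end=last_stim_end, status=status,
                            final_state=y)


def measure_cv(record: ActivationRecord, direction=(1.0, 0.0),
               trim: float = 0.2) -> float:
    """Conduction velocity (m/s) of a planar wave from the activation record.

    Least-squares slope of first-activation time against distance along
    ``direction``, using the central (1 - 2*trim) fraction of the span to
    avoid boundary effects; the inverted slope (mm/ms) is numerically m/s.
    """
    d = np.asarray(direction, dtype=float)
    d /= np.linalg.norm(d)
    t = record.first_activation()
    sel = np.isfinite(t)
    if sel.sum() < 3:
        raise ValueError("need at least 3 activated nodes to measure CV")
    x = record.coords[sel] @ d
    t = t[sel]
    lo, hi = np.quantile(x, [trim, 1.0 - trim])
    band = (x >= lo) & (x <= hi)
    if band.sum() < 3:
        raise ValueError("too few nodes in the central band")
    slope = np.polyfit(x[band], t[band], 1)[0]
    if slope <= 0:
        raise ValueError("wave does not propagate along the given direction")
    return 1.0 / slope


def calibrate_sigma_l(target_m_s: float = config.CV_LONGITUDINAL_TARGET_M_S,
                      dx_um: float = config.CV_CALIBRATION_DX_UM,
                      n_iter: int = 20) -> float:
    """Calibrate sigma_l (S/m) for the target planar longitudinal CV.

    Bisection on a fiber-aligned strip at the calibration resolution.
    """
    def cv_of(sigma):
        cfg = MonodomainConfig(sigma_l=sigma, sigma_t=sigma / 4.0,
                               dt_ms=config.TISSUE_DT_MS)
        return _strip_cv(cfg, dx_um)

    lo, hi = 0.05, 1.0
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        if cv_of(mid) < target_m_s:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _strip_cv(cfg: MonodomainConfig, dx_um: float, length_mm: float = 20.0,
              direction="l") -> float:
    """Planar CV on a thin strip with fibers along x."""
    from .fusion import TissueLabelMap
    from .geometry import build_grid, FiberField

    h = dx_um / 1000.0
    ncols = int(round(length_mm / h))
    labels = np.ones((3, ncols), dtype=np.int8)
    grid = build_grid(TissueLabelMap(labels, (h, h)), dx_um)
    m = grid.n_elements
    fib = np.tile(np.array([1.0, 0.0, 0.0]), (m, 1))
    if direction == "t":
        fib = np.tile(np.array([0.0, 1.0, 0.0]), (m, 1))
    fibers = FiberField(fibers=fib, angles_deg=np.zeros(m),
                        sheet_normal=np.tile(np.array([0.0, 1.0, 0.0]), (m, 1)))
    mesh = prepare(grid, fibers, cfg)
    left = np.nonzero(mesh.coords[:, 0] <= 2 * h)[0]
    stim = Stimulus(nodes=left, onset_ms=5.0, duration_ms=2.0, amplitude=-52.0)
    rec = simulate(mesh, [stim], cfg, duration_ms=5.0 + length_mm / 0.15)
    return measure_cv(rec, direction=(1.0, 0.0))
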