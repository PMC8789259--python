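"""Rapid-pacing arrhythmia induction: 7-site protocol and reentry detection.

Each virtual heart is paced sequentially from seven endocardial sites, one
per AHA-style sector of the short-axis slice.  From every site an S1 drive
train is delivered, followed by progressively premature extrastimuli (S2,
optionally S3) until reentry is induced, capture is lost, or the schedule is
exhausted.  Reentry is declared when, after the last stimulus, some region
of the tissue completes at least two full reactivation cycles within the
observation window (self-sustained activity).  A heart is "at risk" when at
least one of the seven sites induces reentry.

Induced reentries are summarized by a descriptor (core sector + cycle
length); descriptors from one heart are clustered into unique VA
morphologies (same core sector, cycle lengths within 10%).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import config
from .geometry import (VentricularGrid, assign_fibers, build_grid,
                       find_transmural_boundaries, solve_laplace)
from .monodomain import (ActivationRecord, MonodomainConfig, SimMesh,
                         Stimulus, prepare, simulate)


def build_substrate(labelmap, cfg: MonodomainConfig,
                    resolution_um: float = config.DESK_DX_UM):
    """Label map -> simulation-ready mesh (grid, fibers, conductivities).

    Solves the transmural Laplace problem of the annulus for the rule-based
    fiber frame and assembles the conducting-node problem.
    """
    grid = build_grid(labelmap, resolution_um)
    endo, epi = find_transmural_boundaries(grid)
    phi = solve_laplace(grid, [endo, epi], [0.0, 1.0])
    fibers = assign_fibers(grid, None, phi)
    return grid, prepare(grid, fibers, cfg)

__all__ = [
    "PacingSite", "PacingProtocol", "ReentryDescriptor", "InductionResult",
    "SECTOR_NAMES", "place_pacing_sites", "run_protocol", "run_all_sites",
    "detect_reentry", "count_unique_morphologies", "build_substrate",
]

#: Seven AHA-style sectors probed by the pacing protocol (fixed order).
SECTOR_NAMES = (
    "basal anterior", "basal inferolateral", "basal inferoseptal",
    "mid anteroseptal", "mid inferior", "mid anterolateral", "apical septal",
)
N_SECTORS = len(SECTOR_NAMES)


@dataclass(frozen=True)
class PacingSite:
    """Endocardial pacing location within one sector."""
    sector: int                   # index into SECTOR_NAMES
    name: str
    grid_nodes: np.ndarray        # grid node ids of the stimulus patch
    center_mm: np.ndarray


@dataclass(frozen=True)
class PacingProtocol:
    """S1 drive train plus decremental premature-beat schedule."""
    s1_count: int = 6
    s1_cycle_ms: float = 600.0
    s2_initial_fraction: float = 0.9
    s2_decrement_ms: float = 10.0
    s2_minimum_ms: float = 200.0
    max_extrastimuli: int = 2
    observation_window_ms: float = 2000.0

    def __post_init__(self):
        if self.s1_count < 1 or self.s1_cycle_ms <= 0:
            raise ValueError("invalid S1 train")
        if not (0 < self.s2_initial_fraction <= 1):
            raise ValueError("s2_initial_fraction must lie in (0, 1]")
        if self.s2_decrement_ms <= 0 or self.s2_minimum_ms <= 0:
            raise ValueError("schedule steps must be positive")

    def couplings(self, start_ms: float) -> np.ndarray:
        """Strictly decreasing premature couplings from ``start_ms`` down."""
        vals = np.arange(start_ms, self.s2_minimum_ms - 1e-9,
                         -self.s2_decrement_ms)
        return np.round(vals, 6)

    def s2_couplings(self) -> np.ndarray:
        """First-extrastimulus schedule: start at a fraction of the S1 cycle."""
        return self.couplings(self.s1_cycle_ms * self.s2_initial_fraction)

    @classmethod
    def full(cls) -> "PacingProtocol":
        return cls(**config.PROTOCOL_FULL)

    @classmethod
    def desk(cls) -> "PacingProtocol":
        return cls(**config.PROTOCOL_DESK)


@dataclass(frozen=True)
class ReentryDescriptor:
    """Signature of an induced reentrant arrhythmia."""
    cycle_length_ms: float
    core_sector: int
    core_xy: tuple[float, float]
    inducing_site: int            # sector index of the pacing site


@dataclass
class InductionResult:
    """Outcome of the pacing protocol at one site."""
    site: PacingSite
    induced: bool
    descriptor: ReentryDescriptor | None = None
    coupling_ms: tuple | None = None     # couplings of the inducing beat(s)
    s1_capture: bool = True
    n_attempts: int = 0


# ---------------------------------------------------------------------------
# Pacing sites
# ---------------------------------------------------------------------------

def _sector_of(theta: np.ndarray) -> np.ndarray:
    """Sector index of polar angles, 7 equal slices starting at -pi."""
    frac = (theta + np.pi) / (2.0 * np.pi)
    return np.minimum((frac * N_SECTORS).astype(int), N_SECTORS - 1)


def sector_of_points(points: np.ndarray, center: np.ndarray) -> np.ndarray:
    d = np.atleast_2d(points) - center
    return _sector_of(np.arctan2(d[:, 1], d[:, 0]))


def place_pacing_sites(grid: VentricularGrid, patch_radius_mm: float = 1.6):
    """One endocardial pacing site per sector of the short-axis annulus.

    The site is the endocardial node nearest the sector's central angle;
    the stimulus patch is all endocardial nodes within ``patch_radius_mm``.
    Raises if some sector has no endocardial nodes.
    """
    endo, _ = find_transmural_boundaries(grid)
    pts = grid.nodes[endo]
    center = grid.nodes.mean(axis=0)
    d = pts - center
    theta = np.arctan2(d[:, 1], d[:, 0])
    sites = []
    for k in range(N_SECTORS):
        theta_c = -np.pi + (k + 0.5) * 2.0 * np.pi / N_SECTORS
        # angular distance to the sector center
        dang = np.angle(np.exp(1j * (theta - theta_c)))
        in_sector = _sector_of(theta) == k
        if not in_sector.any():
            raise ValueError(f"sector {SECTOR_NAMES[k]!r} has no endocardial nodes")
        best = np.nonzero(in_sector)[0][np.argmin(np.abs(dang[in_sector]))]
        c = pts[best]
        patch = endo[np.linalg.norm(pts - c, axis=1) <= patch_radius_mm]
        sites.append(PacingSite(sector=k, name=SECTOR_NAMES[k],
                                grid_nodes=patch, center_mm=c))
    return sites


# ---------------------------------------------------------------------------
# Reentry detection
# ---------------------------------------------------------------------------

def detect_reentry(record: ActivationRecord, t_last_stimulus: float,
                   window_ms: float, center: np.ndarray | None = None,
                   inducing_site: int = -1,
                   min_region_nodes: int = 8):
    """Decide whether self-sustained reentry follows the last stimulus.

    A node's first post-stimulus activation is its direct response; further
    activations are reactivation cycles.  Reentry is declared iff a region of
    at least ``min_region_nodes`` completes >= 2 reactivation cycles and the
    activity persists through the observation window (last activation beyond
    its midpoint, or the simulation was stopped early on accumulating
    upstrokes).  Returns (bool, ReentryDescriptor | None).
    """
    if record.t_end < t_last_stimulus:
        raise ValueError("record does not extend past the last stimulus")
    if record.status == 0 and record.t_end < t_last_stimulus + window_ms - 1e-6:
        raise ValueError("record shorter than the observation window")
    post = np.where(np.isfinite(record.times) & (record.times > t_last_stimulus),
                    record.times, np.nan)
    n_post = np.sum(np.isfinite(post), axis=1)
    region = n_post >= 3          # direct response + >= 2 reactivations
    if int(region.sum()) < min_region_nodes:
        return False, None
    last_act = np.nanmax(post[region])
    persistent = (record.status == 2) or \
        (last_act >= t_last_stimulus + 0.5 * window_ms)
    if not persistent:
        return False, None
    # cycle length: median inter-activation interval of the reentrant region
    intervals = np.diff(post[region], axis=1)
    cl = float(np.nanmedian(intervals))
    # core: earliest second post-stimulus activation (head of the circuit)
    second = np.sort(post[region], axis=1)[:, 1]
    core_idx = np.nonzero(region)[0][int(np.nanargmin(second))]
    core_xy = record.coords[core_idx]
    if center is None:
        center = record.coords.mean(axis=0)
    sector = int(sector_of_points(core_xy[None, :], np.asarray(center))[0])
    desc = ReentryDescriptor(cycle_length_ms=cl, core_sector=sector,
                             core_xy=(float(core_xy[0]), float(core_xy[1])),
                             inducing_site=inducing_site)
    return True, desc


def count_unique_morphologies(descriptors, cl_tolerance: float = 0.10) -> int:
    """Number of distinct VA morphologies among one heart's descriptors.

    Two descriptors are the same morphology when their core sectors match
    and their cycle lengths differ by less than ``cl_tolerance`` (relative
    to the mean of the pair).  Counting is by greedy clustering; the empty
    list gives 0.
    """
    reps: list[ReentryDescriptor] = []
    for d in descriptors:
        for r in reps:
            mean_cl = 0.5 * (d.cycle_length_ms + r.cycle_length_ms)
            if d.core_sector == r.core_sector and \
                    abs(d.cycle_length_ms - r.cycle_length_ms) < cl_tolerance * mean_cl:
                break
        else:
            reps.append(d)
    return len(reps)


# ---------------------------------------------------------------------------
# Protocol execution
# ---------------------------------------------------------------------------

def _captured(record: ActivationRecord, t_after: float, n_nodes: int,
              min_frac: float = 0.5) -> bool:
    """Did a stimulus delivered at t_after propagate through the tissue?

    Requires at least ``min_frac`` of the conducting nodes to activate after
    the stimulus: local capture with distal block counts as loss of capture,
    which ends the decremental schedule of that extrastimulus stage.
    """
    post = np.isfinite(record.times) & (record.times > t_after + 2.0)
    return int(np.sum(post.any(axis=1))) >= max(8, int(min_frac * n_nodes))


def run_protocol(mesh: SimMesh, site: PacingSite, protocol: PacingProtocol,
                 cfg: MonodomainConfig) -> InductionResult:
    """Deliver the rapid-pacing protocol from one site; stop at first
    induction, loss of capture, or schedule exhaustion."""
    # stimulus plug: conducting tissue around the endocardial site center
    # (a surface electrode with wall penetration; a thin arc of boundary
    # nodes cannot source enough current to capture premature beats)
    nodes = mesh.nodes_within(site.center_mm, 2.5)
    if nodes.size == 0:
        # the sector's endocardium is scar: snap to the nearest conducting
        # tissue (pacing from the scar border zone of that sector)
        d = np.linalg.norm(mesh.coords - site.center_mm, axis=1)
        nodes = mesh.nodes_within(mesh.coords[int(np.argmin(d))], 2.5)
    center = mesh.coords.mean(axis=0)
    stim_amp, stim_dur = -100.0, 2.0
    t_first = 10.0
    cl = protocol.s1_cycle_ms
    t_last_s1 = t_first + (protocol.s1_count - 1) * cl

    # drive train up to (but excluding) the final S1; checkpoint the state
    s1_stims = [Stimulus(nodes, t_first + k * cl, stim_dur, stim_amp)
                for k in range(protocol.s1_count - 1)]
    if s1_stims:
        rec = simulate(mesh, s1_stims, cfg, duration_ms=t_last_s1,
                       stop_quiescent=False)
        if not _captured(rec, t_first, mesh.n_nodes):
            return InductionResult(site=site, induced=False, s1_capture=False)
        y_ck = rec.final_state
    else:
        y_ck = None

    window = protocol.observation_window_ms
    n_attempts = 0
    last_captured: float | None = None

    def attempt(couplings: tuple) -> tuple:
        """Simulate final S1 + extrastimuli at the given couplings."""
        stims = [Stimulus(nodes, t_last_s1, stim_dur, stim_amp)]
        t_s = t_last_s1
        for c in couplings:
            t_s = t_s + c
            stims.append(Stimulus(nodes, t_s, stim_dur, stim_amp))
        dur = (t_s - t_last_s1) + stim_dur + window
        rec = simulate(mesh, stims, cfg, duration_ms=dur, y0=y_ck, t0=t_last_s1,
                       stop_quiescent=True, stop_acts=len(stims) + 4,
                       stop_min_nodes=10)
        return rec, t_s + stim_dur

    if protocol.max_extrastimuli < 1:
        # degenerate protocol: drive train only, observe, never decrement
        rec, t_stim_end = attempt(())
        induced, desc = detect_reentry(rec, t_stim_end, window, center,
                                       inducing_site=site.sector)
        return InductionResult(site=site, induced=induced, descriptor=desc,
                               coupling_ms=() if induced else None,
                               n_attempts=1)

    for c2 in protocol.s2_couplings():
        n_attempts += 1
        rec, t_stim_end = attempt((c2,))
        induced, desc = detect_reentry(rec, t_stim_end, window, center,
                                       inducing_site=site.sector)
        if induced:
            return InductionResult(site=site, induced=True, descriptor=desc,
                                   coupling_ms=(c2,), n_attempts=n_attempts)
        if not _captured(rec, t_last_s1 + c2, mesh.n_nodes):
            break                      # effective refractory period reached
        last_captured = c2

    if protocol.max_extrastimuli >= 2 and last_captured is not None:
        # second extrastimulus rides on the shortest fully propagated S2;
        # its schedule resumes one decrement below that coupling.  The state
        # up to (but excluding) the S2 is checkpointed once.
        base = last_captured
        rec_b = simulate(mesh, [Stimulus(nodes, t_last_s1, stim_dur, stim_amp)],
                         cfg, duration_ms=base, y0=y_ck, t0=t_last_s1)
        y_b = rec_b.final_state
        t_b = t_last_s1 + base
        for c3 in protocol.couplings(base - protocol.s2_decrement_ms):
            n_attempts += 1
            stims = [Stimulus(nodes, t_b, stim_dur, stim_amp),
                     Stimulus(nodes, t_b + c3, stim_dur, stim_amp)]
            t_stim_end = t_b + c3 + stim_dur
            rec = simulate(mesh, stims, cfg, duration_ms=c3 + stim_dur + window,
                           y0=y_b, t0=t_b, stop_quiescent=True,
                           stop_acts=2 + 4, stop_min_nodes=10)
            induced, desc = detect_reentry(rec, t_stim_end, window, center,
                                           inducing_site=site.sector)
            if induced:
                return InductionResult(site=site, induced=True, descriptor=desc,
                                       coupling_ms=(base, c3),
                                       n_attempts=n_attempts)
            if not _captured(rec, t_b + c3, mesh.n_nodes):
                break

    return InductionResult(site=site, induced=False, n_attempts=n_attempts)


def run_all_sites(mesh: SimMesh, protocol: PacingProtocol,
                  cfg: MonodomainConfig, sites=None) -> list[InductionResult]:
    """Run the protocol from all seven sites of the heart's grid."""
    if sites is None:
        sites = place_pacing_sites(mesh.grid)
    return [run_protocol(mesh, s, protocol, cfg) for s in sites]
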