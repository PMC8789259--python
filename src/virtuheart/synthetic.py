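"""Synthetic imaging data, substrate phantoms and the cohort-outcome fixture.

The generator emulates the inputs of the pipeline without any patient data:

* a short-axis LGE-CMR stack (2 mm in-plane, 8 mm slice spacing) of an
  annular left ventricle (truncated-ellipsoid wall) whose fibrotic texture is
  a thresholded, spatially correlated Gaussian random field — the top
  ``dense_fraction`` of the field is dense fibrosis, the next
  ``diffuse_fraction`` diffuse fibrosis;
* a single mid-ventricular postcontrast T1 map (1.5 mm in-plane) whose
  relaxation times are a strictly monotone-decreasing piecewise-linear
  transform of the noiseless LGE intensity (more gadolinium retention ->
  brighter LGE -> shorter T1) plus independent noise, with dense tissue
  mapping below 350 ms and diffuse tissue into the 350-450 ms band;
* annular 2-D substrate phantoms (homogeneous, protected-isthmus scar pair,
  contiguous diffuse patch) for electrophysiological studies;
* the 26-patient cohort-outcome fixture encoding the study's per-method
  prediction counts.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from . import config
from .fusion import (LGEStack, T1Map, TissueLabelMap,
                     LABEL_NORMAL, LABEL_DIFFUSE, LABEL_DENSE)

__all__ = [
    "SyntheticCohortSpec", "generate_lge_t1_pair", "generate_substrate_phantom",
    "generate_paired_substrates", "cohort_outcomes_fixture",
    "validate_cohort_outcomes",
]

# Intensity landmarks of the noiseless synthetic LGE signal (arbitrary units):
# remote myocardium spans [_I_LO, _I_DIFFUSE], the diffuse band ramps up to
# _I_DENSE and dense fibrosis continues to _I_HI.  Placeholders, not a claim
# about real HCM intensity distributions.
_I_LO, _I_DIFFUSE, _I_DENSE, _I_HI = 80.0, 108.0, 135.0, 160.0
_T1_AT_DENSE = config.T1_DENSE_MAX_MS     # T1 at the dense/diffuse boundary
_T1_AT_DIFFUSE = config.T1_DIFFUSE_MAX_MS  # T1 at the diffuse/normal boundary
_T1_FLOOR = 260.0
_T1_NOISE_UNIT_MS = 10.0                  # T1 noise per unit of noise_sd
_LGE_NOISE_UNIT = 4.0                     # LGE noise per unit of noise_sd


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Study conditions for synthetic patient generation.

    Default fibrosis burdens are the cohort means of the fused models
    (diffuse 40.5%, dense 3.8% of LV myocardium).
    """
    n_patients: int = 26
    dense_fraction: float = 0.038
    diffuse_fraction: float = 0.405
    correlation_length_mm: float = 8.0
    noise_sd: float = 0.5
    t1_remote_ms: float = 550.0
    seed: int = config.DEFAULT_SEED

    def __post_init__(self):
        for f in (self.dense_fraction, self.diffuse_fraction):
            if not 0.0 <= f < 1.0:
                raise ValueError("fibrosis fractions must lie in [0, 1)")
        if self.dense_fraction + self.diffuse_fraction >= 1.0:
            raise ValueError("dense_fraction + diffuse_fraction must be < 1")
        if self.correlation_length_mm <= 0:
            raise ValueError("correlation_length_mm must be positive")
        if self.t1_remote_ms <= _T1_AT_DIFFUSE:
            raise ValueError("t1_remote_ms must exceed 450 ms")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def _annular_mask(n: int, dx: float, r_outer: float, r_inner: float):
    """Boolean annulus (ny=nx=n) plus polar coordinate maps."""
    c = (n - 1) / 2.0
    y, x = np.mgrid[0:n, 0:n]
    yy = (y - c) * dx
    xx = (x - c) * dx
    r = np.hypot(yy, xx)
    theta = np.arctan2(yy, xx)
    return (r <= r_outer) & (r >= r_inner), r, theta


def _lv_mask_stack(n: int, n_slices: int, dx: float):
    """Truncated-ellipsoid LV wall: annulus per slice, tapering to the apex."""
    mask = np.zeros((n, n, n_slices), dtype=bool)
    z_apex_extent = 1.15  # apex of the ellipsoid lies just below the last slice
    for k in range(n_slices):
        frac = k / (n_slices - 1)            # 0 = base, 1 = most apical slice
        shrink = np.sqrt(max(1.0 - (frac / z_apex_extent) ** 2, 0.05))
        r_out = 30.0 * shrink
        r_in = max(r_out - 10.0, 2.0)
        mask[:, :, k] = _annular_mask(n, dx, r_out, r_in)[0]
    return mask


def _correlated_field(shape, spacing, correlation_length_mm, rng):
    """Spatially correlated Gaussian random field on the image grid."""
    white = rng.standard_normal(shape)
    sigma_pix = correlation_length_mm / 2.0 / spacing[0]
    # mild through-plane smoothing keeps fibrotic regions 3-D contiguous
    return ndimage.gaussian_filter(white, sigma=(sigma_pix, sigma_pix, 0.75))


def _intensity_from_field(u, cut_diffuse, cut_dense, u_min, u_max):
    """Strictly monotone piecewise-linear map from field value to intensity."""
    pts_u = np.array([u_min - 1e-9, cut_diffuse, cut_dense, u_max + 1e-9])
    pts_i = np.array([_I_LO, _I_DIFFUSE, _I_DENSE, _I_HI])
    return np.interp(u, pts_u, pts_i)


def _t1_from_intensity(intensity, t1_remote_ms):
    """Strictly monotone-decreasing piecewise-linear intensity -> T1 map."""
    pts_i = np.array([_I_LO, _I_DIFFUSE, _I_DENSE, _I_HI])
    pts_t = np.array([t1_remote_ms, _T1_AT_DIFFUSE, _T1_AT_DENSE, _T1_FLOOR])
    return np.interp(intensity, pts_i, pts_t)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def generate_lge_t1_pair(spec: SyntheticCohortSpec,
                         n: int = 64, n_slices: int = 10):
    """Generate one synthetic patient: LGE stack, T1 map, ground-truth labels.

    Returns ``(LGEStack, T1Map, TissueLabelMap)``.  The T1 map is the
    mid-ventricular slice on a finer (1.5 mm) grid; its noiseless relaxation
    times are a strictly decreasing transform of the noiseless LGE intensity,
    so with ``noise_sd=0`` the in-mask T1 rank order is exactly the reverse
    of the LGE intensity rank order.
    """
    if n_slices < 8:
        raise ValueError("stack must have at least 8 slices")
    rng = np.random.default_rng(spec.seed)
    dx_lge, dz = 2.0, 8.0
    mask = _lv_mask_stack(n, n_slices, dx_lge)
    u = _correlated_field((n, n, n_slices), (dx_lge, dz),
                          spec.correlation_length_mm, rng)
    u_in = u[mask]
    u_min, u_max = float(u_in.min()), float(u_in.max())
    f_fib = spec.dense_fraction + spec.diffuse_fraction
    if f_fib > 0:
        cut_diffuse = float(np.quantile(u_in, 1.0 - f_fib))
    else:
        cut_diffuse = u_max + 1.0
    if spec.dense_fraction > 0:
        cut_dense = float(np.quantile(u_in, 1.0 - spec.dense_fraction))
    else:
        cut_dense = u_max + 2.0
    cut_dense = max(cut_dense, cut_diffuse + 1e-9)

    noiseless = _intensity_from_field(u, cut_diffuse, cut_dense, u_min, u_max)
    intensities = noiseless + spec.noise_sd * _LGE_NOISE_UNIT * \
        rng.standard_normal(noiseless.shape)

    labels = np.zeros(mask.shape, dtype=np.int8)
    labels[mask] = LABEL_NORMAL
    labels[mask & (u > cut_diffuse)] = LABEL_DIFFUSE
    labels[mask & (u > cut_dense)] = LABEL_DENSE

    slice_z = np.arange(n_slices, dtype=float) * dz
    stack = LGEStack(intensities, mask, (dx_lge, dz), slice_z)

    # mid-ventricular T1 map on the finer grid, same physical field of view
    k_mid = n_slices // 2
    dx_t1 = 1.5
    n_t1 = int(round(n * dx_lge / dx_t1))
    c_l, c_t = (n - 1) / 2.0, (n_t1 - 1) / 2.0
    coords_1d = ((np.arange(n_t1) - c_t) * dx_t1) / dx_lge + c_l
    cy, cx = np.meshgrid(coords_1d, coords_1d, indexing="ij")
    t1_noiseless_src = _t1_from_intensity(noiseless[:, :, k_mid],
                                          spec.t1_remote_ms)
    t1_noiseless = ndimage.map_coordinates(t1_noiseless_src, [cy, cx],
                                           order=1, mode="nearest")
    t1_mask = ndimage.map_coordinates(mask[:, :, k_mid].astype(np.uint8),
                                      [cy, cx], order=0, mode="constant") > 0
    times = t1_noiseless + spec.noise_sd * _T1_NOISE_UNIT_MS * \
        rng.standard_normal(t1_noiseless.shape)
    times = np.maximum(times, 1.0)
    t1 = T1Map(times, t1_mask, (dx_t1, dz), float(slice_z[k_mid]))

    return stack, t1, TissueLabelMap(labels, (dx_lge, dz), slice_z)


def generate_substrate_phantom(kind: str, fraction: float = 0.362,
                               remodeled_channel: bool = False,
                               n: int = 44, dx_mm: float = 1.0,
                               r_outer: float = 20.0,
                               r_inner: float = 11.0) -> TissueLabelMap:
    """Annular 2-D substrate phantoms for reentry studies.

    Kinds
    -----
    ``homogeneous``
        all-normal annulus;
    ``scar_isthmus``
        two dense (nonconducting) blocks at the inner and outer wall of one
        angular sector, separated by a mid-wall conducting channel (protected
        isthmus); ``remodeled_channel=True`` labels the channel diffuse so it
        carries the remodeled (long-APD) myocyte variant;
    ``diffuse_patch``
        a contiguous diffuse angular sector covering ``fraction`` of the
        annulus.
    """
    mask, r, theta = _annular_mask(n, dx_mm, r_outer, r_inner)
    labels = np.zeros((n, n), dtype=np.int8)
    labels[mask] = LABEL_NORMAL
    if kind == "homogeneous":
        pass
    elif kind == "scar_isthmus":
        r_mid_lo = r_inner + (r_outer - r_inner) * 0.36
        r_mid_hi = r_inner + (r_outer - r_inner) * 0.64
        in_sector = mask & (np.abs(theta) < np.pi / 4)
        inner_block = in_sector & (r < r_mid_lo)
        outer_block = in_sector & (r > r_mid_hi)
        channel = in_sector & ~inner_block & ~outer_block
        labels[inner_block] = LABEL_DENSE
        labels[outer_block] = LABEL_DENSE
        if remodeled_channel:
            labels[channel] = LABEL_DIFFUSE
    elif kind == "diffuse_patch":
        if not 0.0 < fraction < 1.0:
            raise ValueError("fraction must lie in (0, 1)")
        # contiguous angular span whose voxel count matches the fraction
        angles = np.sort(theta[mask])
        k = int(round(fraction * angles.size))
        theta_hi = angles[min(k, angles.size - 1)]
        labels[mask & (theta < theta_hi) & (theta >= angles[0])] = LABEL_DIFFUSE
    else:
        raise ValueError(f"unknown phantom kind {kind!r}")
    return TissueLabelMap(labels, (dx_mm, dx_mm))


def generate_paired_substrates(seed: int, n: int = 44, dx_mm: float = 1.0,
                               r_outer: float = 20.0, r_inner: float = 11.0):
    """A matched substrate pair: without vs with a diffuse-fibrosis burden.

    Emulates the LGE-only / LGE-T1 model pair of one patient with little
    focal scar.  Both members share the same annular geometry (the paired
    design controls everything except the diffuse burden); the fused member
    additionally carries cohort-level diffuse fibrosis — one to two
    transmural remodeled arcs at random angular positions, jointly covering
    roughly 40% of the myocardium.  Returns ``(baseline, with_diffuse)``
    label maps.
    """
    rng = np.random.default_rng(seed)
    mask, r, theta = _annular_mask(n, dx_mm, r_outer, r_inner)
    base = np.zeros((n, n), dtype=np.int8)
    base[mask] = LABEL_NORMAL

    fused = base.copy()
    arc0 = rng.uniform(-np.pi, np.pi)
    half_w0 = rng.uniform(0.45 * np.pi / 2, 0.62 * np.pi / 2)
    dth = np.angle(np.exp(1j * (theta - arc0)))
    fused[mask & (np.abs(dth) < half_w0)] = LABEL_DIFFUSE
    if rng.random() < 0.6:
        arc1 = arc0 + np.pi + rng.uniform(-np.pi / 4, np.pi / 4)
        half_w1 = rng.uniform(0.12 * np.pi, 0.2 * np.pi) / 2
        dth1 = np.angle(np.exp(1j * (theta - arc1)))
        fused[mask & (np.abs(dth1) < half_w1)] = LABEL_DIFFUSE
    return (TissueLabelMap(base, (dx_mm, dx_mm)),
            TissueLabelMap(fused, (dx_mm, dx_mm)))


# ---------------------------------------------------------------------------
# Cohort-outcome fixture
# ---------------------------------------------------------------------------

def cohort_outcomes_fixture() -> pd.DataFrame:
    """The 26-patient outcome/verdict fixture.

    Encodes the study's prediction counts: 13 patients with clinical VA; the
    fused (LGE-T1) models mark 14 at risk of whom 11 had VA; the LGE-only
    models mark 12 of whom 9 had VA; the ACCF/AHA score is correct on 6 and
    the ESC score on 7 of the VA group (with false-positive counts implied by
    the published specificity/PPV of each method).
    """
    pid = np.arange(1, 27)
    va = pid <= 13
    lge_t1 = ((pid >= 3) & (pid <= 13)) | ((pid >= 14) & (pid <= 16))
    lge_only = ((pid >= 5) & (pid <= 13)) | ((pid >= 14) & (pid <= 16))
    accf = (pid <= 6) | ((pid >= 14) & (pid <= 20))
    esc = (pid <= 7) | ((pid >= 14) & (pid <= 21))
    df = pd.DataFrame({
        "patient_id": pid, "clinical_va": va, "accf_aha": accf,
        "esc": esc, "lge_t1": lge_t1, "lge_only": lge_only,
    })
    validate_cohort_outcomes(df)
    return df


def validate_cohort_outcomes(df: pd.DataFrame) -> None:
    """Check the fixture invariants; raises AssertionError on violation."""
    va = df["clinical_va"]
    assert int(va.sum()) == 13 and int((~va).sum()) == 13
    assert int(df["lge_t1"].sum()) == 14
    assert int((df["lge_t1"] & va).sum()) == 11
    assert int(df["lge_only"].sum()) == 12
    assert int((df["lge_only"] & va).sum()) == 9
    assert int((df["accf_aha"] & va).sum()) == 6
    assert int((df["esc"] & va).sum()) == 7
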