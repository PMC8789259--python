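"""Fusion of LGE-CMR signal-intensity thresholding with postcontrast T1 maps.

LGE-CMR is an image of *relative* intensity: fibrosis is segmented by
thresholding at multiples of the standard deviation above the mean of the
low-intensity ("remote") myocardium.  The one-size-fits-all convention uses
>3 SD for diffuse fibrosis / gray zone and >5 SD for dense fibrosis (scar).

A postcontrast T1 map is *quantitative*: relaxation times below 350 ms mark
dense fibrosis and times in 350-450 ms mark diffuse fibrosis.  Because only a
single mid-ventricular T1 slice is acquired, its information is transferred
to the whole LGE stack by re-deriving personalized thresholds (T_Diffuse,
T_Dense, in SD units): the thresholds are chosen so that the dense and
diffuse area fractions of the matching LGE slice equal the T1-derived
fractions (empirical-quantile matching), then applied to every slice.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.mixture import GaussianMixture

from . import config

__all__ = [
    "LGEStack", "LGESlice", "T1Map", "RemoteStats", "PersonalizedThresholds",
    "TissueLabelMap", "FibrosisFractions",
    "LABEL_BACKGROUND", "LABEL_NORMAL", "LABEL_DIFFUSE", "LABEL_DENSE",
    "estimate_remote_stats", "estimate_remote_stats_per_slice",
    "classify_lge", "classify_t1", "match_slice",
    "derive_personalized_thresholds", "apply_thresholds_to_stack",
    "quantify_fibrosis", "lge_only_pipeline", "fuse",
]

LABEL_BACKGROUND, LABEL_NORMAL, LABEL_DIFFUSE, LABEL_DENSE = 0, 1, 2, 3


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class LGEStack:
    """Short-axis LGE-CMR stack: intensities, LV mask and slice geometry.

    ``intensities``/``lv_mask`` are (ny, nx, nz); ``spacing`` is (in-plane mm,
    slice mm); ``slice_z`` gives the axial coordinate of each slice.
    """
    intensities: np.ndarray
    lv_mask: np.ndarray
    spacing: tuple[float, float]
    slice_z: np.ndarray

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.lv_mask = np.asarray(self.lv_mask, dtype=bool)
        self.slice_z = np.asarray(self.slice_z, dtype=float)
        if self.intensities.shape != self.lv_mask.shape or self.intensities.ndim != 3:
            raise ValueError("intensities and lv_mask must be matching 3-D arrays")
        if self.intensities.shape[2] != self.slice_z.size:
            raise ValueError("slice_z length must equal the number of slices")
        if min(self.spacing) <= 0:
            raise ValueError("spacing must be positive")
        if not self.lv_mask.any():
            raise ValueError("empty LV mask")

    @property
    def n_slices(self) -> int:
        return self.intensities.shape[2]

    def get_slice(self, k: int) -> "LGESlice":
        return LGESlice(self.intensities[:, :, k], self.lv_mask[:, :, k],
                        self.spacing, float(self.slice_z[k]))


@dataclass
class LGESlice:
    """A single short-axis LGE slice."""
    intensities: np.ndarray
    lv_mask: np.ndarray
    spacing: tuple[float, float]
    slice_z: float


@dataclass
class T1Map:
    """Single mid-ventricular short-axis postcontrast T1 relaxation-time map."""
    times_ms: np.ndarray
    lv_mask: np.ndarray
    spacing: tuple[float, float]
    slice_z: float

    def __post_init__(self):
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.lv_mask = np.asarray(self.lv_mask, dtype=bool)
        if self.times_ms.shape != self.lv_mask.shape or self.times_ms.ndim != 2:
            raise ValueError("times_ms and lv_mask must be matching 2-D arrays")
        if np.any(self.times_ms[self.lv_mask] <= 0):
            raise ValueError("relaxation times must be positive")


@dataclass(frozen=True)
class RemoteStats:
    """Mean/SD of the low-signal-intensity (remote, nonfibrotic) myocardium."""
    mean: float
    sd: float

    def __post_init__(self):
        if not self.sd > 0:
            raise ValueError("remote SD must be positive")


@dataclass(frozen=True)
class PersonalizedThresholds:
    """Segmentation thresholds in SD units above the remote mean."""
    t_diffuse: float
    t_dense: float

    def __post_init__(self):
        if not self.t_diffuse < self.t_dense:
            raise ValueError("t_diffuse must be below t_dense")


@dataclass
class TissueLabelMap:
    """Per-voxel tissue class: 0 background, 1 normal, 2 diffuse, 3 dense."""
    labels: np.ndarray
    spacing: tuple[float, float]
    slice_z: np.ndarray | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim not in (2, 3):
            raise ValueError("labels must be 2-D or 3-D")
        if not np.isin(self.labels, [0, 1, 2, 3]).all():
            raise ValueError("labels must be in {0,1,2,3}")

    @property
    def myocardium(self) -> np.ndarray:
        return self.labels > 0


@dataclass(frozen=True)
class FibrosisFractions:
    """Diffuse and dense fibrosis burden as % of LV myocardial voxels."""
    diffuse_pct: float
    dense_pct: float

    def __post_init__(self):
        for v in (self.diffuse_pct, self.dense_pct):
            if not 0.0 <= v <= 100.0:
                raise ValueError("percentages must lie in [0, 100]")
        if self.diffuse_pct + self.dense_pct > 100.0 + 1e-9:
            raise ValueError("fibrosis percentages must sum to <= 100")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def estimate_remote_stats(lge_slice: np.ndarray, mask: np.ndarray) -> RemoteStats:
    """Mean/SD of the remote (low-intensity) myocardium of one slice.

    The manual low-intensity ROI of clinical practice is replaced by a
    reproducible surrogate: a two-component Gaussian-mixture fit on the masked
    intensities; the lower-mean component defines the remote statistics.
    """
    vals = np.asarray(lge_slice, dtype=float)[np.asarray(mask, dtype=bool)]
    if vals.size < 100:
        raise ValueError("need at least 100 masked voxels for remote statistics")
    if np.ptp(vals) == 0:
        raise ValueError("degenerate (constant) slice: remote SD undefined")
    gm = GaussianMixture(n_components=2, random_state=0, n_init=2,
                         reg_covar=1e-6).fit(vals.reshape(-1, 1))
    lo = int(np.argmin(gm.means_.ravel()))
    mean = float(gm.means_.ravel()[lo])
    sd = float(np.sqrt(gm.covariances_.ravel()[lo]))
    return RemoteStats(mean=mean, sd=sd)


def estimate_remote_stats_per_slice(stack: LGEStack) -> list[RemoteStats | None]:
    """Per-slice remote statistics (None for slices without myocardium)."""
    out: list[RemoteStats | None] = []
    for k in range(stack.n_slices):
        sl = stack.get_slice(k)
        out.append(estimate_remote_stats(sl.intensities, sl.lv_mask)
                   if sl.lv_mask.any() else None)
    return out


def _classify_array(intens, mask, stats: RemoteStats,
                    thr: PersonalizedThresholds) -> np.ndarray:
    labels = np.zeros(intens.shape, dtype=np.int8)
    cut_diffuse = stats.mean + thr.t_diffuse * stats.sd
    cut_dense = stats.mean + thr.t_dense * stats.sd
    labels[mask] = LABEL_NORMAL
    labels[mask & (intens > cut_diffuse)] = LABEL_DIFFUSE
    labels[mask & (intens > cut_dense)] = LABEL_DENSE
    return labels


def classify_lge(stack: LGEStack, remote_stats: RemoteStats,
                 thresholds: PersonalizedThresholds) -> TissueLabelMap:
    """Threshold the whole stack with a single set of remote statistics.

    A voxel is dense if its intensity exceeds mean + t_dense*SD, diffuse if in
    (mean + t_diffuse*SD, mean + t_dense*SD], else normal myocardium.
    """
    labels = _classify_array(stack.intensities, stack.lv_mask,
                             remote_stats, thresholds)
    return TissueLabelMap(labels, stack.spacing, stack.slice_z.copy())


def classify_t1(t1_map: T1Map) -> np.ndarray:
    """Classify a T1 map by relaxation-time bands.

    <350 ms -> dense; 350-450 ms (closed interval) -> diffuse; >450 ms ->
    normal.  Returns a 2-D label array.
    """
    t = t1_map.times_ms
    if np.any(t[t1_map.lv_mask] <= 0):
        raise ValueError("non-positive relaxation time in the LV mask")
    labels = np.zeros(t.shape, dtype=np.int8)
    labels[t1_map.lv_mask] = LABEL_NORMAL
    labels[t1_map.lv_mask & (t <= config.T1_DIFFUSE_MAX_MS)] = LABEL_DIFFUSE
    labels[t1_map.lv_mask & (t < config.T1_DENSE_MAX_MS)] = LABEL_DENSE
    return labels


def match_slice(stack: LGEStack, t1_map: T1Map) -> int:
    """Index of the LGE slice matching the T1 map's axial position.

    Nearest slice by z coordinate; an exact tie is broken toward the lower
    index.  The T1 position must lie within the stack's z range.
    """
    z = t1_map.slice_z
    lo, hi = stack.slice_z.min(), stack.slice_z.max()
    if not (lo <= z <= hi):
        raise ValueError(f"T1 slice z={z} outside LGE stack range [{lo}, {hi}]")
    return int(np.argmin(np.abs(stack.slice_z - z)))


def _pixel_centers(n: int, dx: float) -> np.ndarray:
    """Physical coordinates of pixel centers, grid centered on the origin."""
    return (np.arange(n) - (n - 1) / 2.0) * dx


def resample_t1_labels(t1_map: T1Map, lge_slice: LGESlice) -> np.ndarray:
    """Nearest-neighbor binning of T1 band labels onto the LGE pixel grid.

    Both grids are taken to share the physical center of the field of view;
    the in-plane resolution mismatch (1.5 vs 2 mm) is handled by assigning
    each LGE pixel the label of the nearest T1 pixel.
    """
    t1_labels = classify_t1(t1_map)
    ny, nx = lge_slice.intensities.shape
    ty, tx = t1_map.times_ms.shape
    yl = _pixel_centers(ny, lge_slice.spacing[0])
    xl = _pixel_centers(nx, lge_slice.spacing[0])
    yt = _pixel_centers(ty, t1_map.spacing[0])
    xt = _pixel_centers(tx, t1_map.spacing[0])
    iy = np.clip(np.round((yl - yt[0]) / t1_map.spacing[0]).astype(int), 0, ty - 1)
    ix = np.clip(np.round((xl - xt[0]) / t1_map.spacing[0]).astype(int), 0, tx - 1)
    return t1_labels[np.ix_(iy, ix)]


def derive_personalized_thresholds(lge_slice: LGESlice,
                                   remote_stats: RemoteStats,
                                   t1_map: T1Map) -> PersonalizedThresholds:
    """Personalized (T_Diffuse, T_Dense) from the matching-slice T1 fractions.

    The T1-derived dense and dense+diffuse area fractions (after binning the
    T1 bands onto the LGE grid) are matched by empirical quantiles of the
    masked LGE-slice intensities: t_dense is the (1 - f_dense) quantile and
    t_diffuse the (1 - f_dense - f_diffuse) quantile, both expressed in SD
    units above the remote mean.
    """
    mask = lge_slice.lv_mask
    if not mask.any() or not t1_map.lv_mask.any():
        raise ValueError("empty LV mask")
    resampled = resample_t1_labels(t1_map, lge_slice)
    sel = mask & (resampled > 0)
    n_sel = int(sel.sum())
    if n_sel == 0:
        raise ValueError("T1 map and LGE slice masks do not overlap")
    f_dense = float(np.sum(resampled[sel] == LABEL_DENSE)) / n_sel
    f_diffuse = float(np.sum(resampled[sel] == LABEL_DIFFUSE)) / n_sel
    if f_dense + f_diffuse >= 1.0:
        raise ValueError("fibrotic fractions must sum to < 1")
    vals = lge_slice.intensities[mask]
    vmax = float(vals.max())
    eps = 1e-9 * max(1.0, abs(vmax))
    if f_dense > 0:
        q_dense = float(np.quantile(vals, 1.0 - f_dense))
    else:
        q_dense = vmax + eps          # no voxel strictly above -> zero dense
    if f_diffuse > 0:
        q_diffuse = float(np.quantile(vals, 1.0 - f_dense - f_diffuse))
        q_diffuse = min(q_diffuse, q_dense - eps)
    else:
        q_diffuse = q_dense - eps
    t_dense = (q_dense - remote_stats.mean) / remote_stats.sd
    t_diffuse = (q_diffuse - remote_stats.mean) / remote_stats.sd
    return PersonalizedThresholds(t_diffuse=t_diffuse, t_dense=t_dense)


def apply_thresholds_to_stack(stack: LGEStack,
                              remote_stats_per_slice,
                              thresholds: PersonalizedThresholds) -> TissueLabelMap:
    """Apply (T_Diffuse, T_Dense) to every slice with its own remote stats."""
    labels = np.zeros(stack.intensities.shape, dtype=np.int8)
    for k in range(stack.n_slices):
        stats = remote_stats_per_slice[k]
        if stats is None:
            continue
        labels[:, :, k] = _classify_array(stack.intensities[:, :, k],
                                          stack.lv_mask[:, :, k],
                                          stats, thresholds)
    return TissueLabelMap(labels, stack.spacing, stack.slice_z.copy())


def quantify_fibrosis(labelmap: TissueLabelMap) -> FibrosisFractions:
    """Diffuse/dense fibrosis burden as % of LV myocardial voxels."""
    myo = labelmap.myocardium
    n = int(myo.sum())
    if n == 0:
        raise ValueError("label map contains no myocardium")
    diffuse = 100.0 * np.sum(labelmap.labels == LABEL_DIFFUSE) / n
    dense = 100.0 * np.sum(labelmap.labels == LABEL_DENSE) / n
    return FibrosisFractions(diffuse_pct=float(diffuse), dense_pct=float(dense))


def lge_only_pipeline(stack: LGEStack,
                      remote_stats_per_slice=None) -> TissueLabelMap:
    """One-size-fits-all pipeline: thresholds fixed at (3, 5) SD."""
    if remote_stats_per_slice is None:
        remote_stats_per_slice = estimate_remote_stats_per_slice(stack)
    thr = PersonalizedThresholds(*config.LGE_ONLY_THRESHOLDS_SD)
    return apply_thresholds_to_stack(stack, remote_stats_per_slice, thr)


def fuse(stack: LGEStack, t1_map: T1Map, mode: str = "lge_t1"):
    """Full geometrical-model reconstruction.

    Returns (thresholds, labelmap, fractions).  ``mode='lge_t1'`` derives
    personalized thresholds from the T1 map; ``mode='lge_only'`` uses the
    one-size-fits-all (3, 5) SD thresholds.
    """
    stats = estimate_remote_stats_per_slice(stack)
    if mode == "lge_only":
        thr = PersonalizedThresholds(*config.LGE_ONLY_THRESHOLDS_SD)
    elif mode == "lge_t1":
        k = match_slice(stack, t1_map)
        if stats[k] is None:
            raise ValueError("matching slice has no myocardium")
        thr = derive_personalized_thresholds(stack.get_slice(k), stats[k], t1_map)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    labelmap = apply_thresholds_to_stack(stack, stats, thr)
    return thr, labelmap, quantify_fibrosis(labelmap)
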