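"""Computational grid construction and rule-based fiber orientation.

The grid is a structured 2-D quadrilateral mesh sampled from a tissue label
map at a target edge length (the mesh-convergence window for monodomain
electrophysiology is 300-400 um).  Dense-fibrosis elements are retained in
the mesh (they are myocardium for geometry purposes) but flagged
non-conducting.

Fiber orientation uses the Laplace–Dirichlet rule-based method: harmonic
fields solved between endocardial/epicardial (transmural) and basal/apical
(apicobasal) Dirichlet sets define local frames, and the fiber is the
circumferential direction rotated about the transmural gradient by a helix
angle interpolated linearly from +60 deg at the endocardium to -60 deg at
the epicardium (the convention of the standard rule set).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy import ndimage
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import spsolve

from .fusion import TissueLabelMap, LABEL_DENSE

__all__ = [
    "VentricularGrid", "FiberField", "build_grid", "solve_laplace",
    "assign_fibers", "find_transmural_boundaries",
    "DEFAULT_ANGLE_ENDO_DEG", "DEFAULT_ANGLE_EPI_DEG",
]

log = logging.getLogger(__name__)

DEFAULT_ANGLE_ENDO_DEG = 60.0
DEFAULT_ANGLE_EPI_DEG = -60.0


@dataclass
class VentricularGrid:
    """Structured quadrilateral grid over the myocardium of a label map.

    ``elem_label`` is the (ny, nx) element-grid label image (0 = no element);
    ``node_id`` maps structured node coordinates (ny+1, nx+1) to compact node
    indices (-1 where no adjacent myocardial element exists).
    """
    h_mm: float
    elem_label: np.ndarray
    node_id: np.ndarray
    nodes: np.ndarray              # (N, 2) coordinates in mm
    elements: np.ndarray           # (M, 4) node connectivity (ccw)
    element_label: np.ndarray      # (M,) tissue class of each element
    elem_ij: np.ndarray            # (M, 2) element-grid indices

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    @property
    def conducting(self) -> np.ndarray:
        """Element mask: dense fibrosis (scar) is electrically inexcitable."""
        return self.element_label != LABEL_DENSE

    @property
    def resolution_um(self) -> float:
        return self.h_mm * 1000.0

    def element_centers(self) -> np.ndarray:
        return (self.elem_ij[:, ::-1] + 0.5) * self.h_mm

    def node_ij(self) -> np.ndarray:
        """Structured (row, col) index of each compact node."""
        out = np.empty((self.n_nodes, 2), dtype=np.int64)
        rr, cc = np.nonzero(self.node_id >= 0)
        out[self.node_id[rr, cc]] = np.stack([rr, cc], axis=1)
        return out


@dataclass
class FiberField:
    """Per-element fiber direction (3-D unit vector), helix angle and frame."""
    fibers: np.ndarray            # (M, 3) unit vectors
    angles_deg: np.ndarray        # (M,)
    sheet_normal: np.ndarray      # (M, 3) transmural direction


def build_grid(labelmap: TissueLabelMap, target_resolution_um: float = 355.0,
               slice_index: int | None = None) -> VentricularGrid:
    """Structured grid at the target edge length, labels sampled nearest.

    3-D label maps are reduced to a single short-axis slice (mid-ventricular
    by default): desk-scale electrophysiology in this package runs on 2-D
    slices, where the substrate algorithms are dimension-agnostic.
    """
    if target_resolution_um <= 0:
        raise ValueError("target resolution must be positive")
    labels = labelmap.labels
    if labels.ndim == 3:
        k = labels.shape[2] // 2 if slice_index is None else slice_index
        labels = labels[:, :, k]
    if not (labels > 0).any():
        raise ValueError("label map contains no myocardium")
    dx = labelmap.spacing[0]
    h = target_resolution_um / 1000.0
    ny = max(int(round(labels.shape[0] * dx / h)), 1)
    nx = max(int(round(labels.shape[1] * dx / h)), 1)
    # nearest-voxel sampling at element centers
    cy = np.minimum(((np.arange(ny) + 0.5) * h / dx).astype(int), labels.shape[0] - 1)
    cx = np.minimum(((np.arange(nx) + 0.5) * h / dx).astype(int), labels.shape[1] - 1)
    elem_label = labels[np.ix_(cy, cx)].astype(np.int8)

    present = elem_label > 0
    node_present = np.zeros((ny + 1, nx + 1), dtype=bool)
    node_present[:-1, :-1] |= present
    node_present[:-1, 1:] |= present
    node_present[1:, :-1] |= present
    node_present[1:, 1:] |= present
    node_id = np.full((ny + 1, nx + 1), -1, dtype=np.int64)
    rr, cc = np.nonzero(node_present)
    node_id[rr, cc] = np.arange(rr.size)
    nodes = np.stack([cc * h, rr * h], axis=1).astype(float)

    er, ec = np.nonzero(present)
    elements = np.stack([
        node_id[er, ec], node_id[er, ec + 1],
        node_id[er + 1, ec + 1], node_id[er + 1, ec],
    ], axis=1)
    return VentricularGrid(h_mm=h, elem_label=elem_label, node_id=node_id,
                           nodes=nodes, elements=elements,
                           element_label=elem_label[er, ec],
                           elem_ij=np.stack([er, ec], axis=1))


def _node_adjacency(grid: VentricularGrid) -> sp.csr_matrix:
    """Graph Laplacian stencil (5-point) over nodes of myocardial elements."""
    ny1, nx1 = grid.node_id.shape
    present = grid.elem_label > 0
    rows, cols = [], []
    # an edge between two nodes exists if some myocardial element touches it
    # horizontal edges (i,j)-(i,j+1): flanking elements (i-1,j) and (i,j)
    for axis in (0, 1):
        if axis == 0:   # edges along x
            flank = np.zeros((ny1, nx1 - 1), dtype=bool)
            flank[:-1, :] |= present
            flank[1:, :] |= present
            rr, cc = np.nonzero(flank)
            a = grid.node_id[rr, cc]
            b = grid.node_id[rr, cc + 1]
        else:           # edges along y
            flank = np.zeros((ny1 - 1, nx1), dtype=bool)
            flank[:, :-1] |= present
            flank[:, 1:] |= present
            rr, cc = np.nonzero(flank)
            a = grid.node_id[rr, cc]
            b = grid.node_id[rr + 1, cc]
        ok = (a >= 0) & (b >= 0)
        rows.extend([a[ok], b[ok]])
        cols.extend([b[ok], a[ok]])
    r = np.concatenate(rows)
    c = np.concatenate(cols)
    data = np.ones(r.size)
    return sp.csr_matrix((data, (r, c)), shape=(grid.n_nodes, grid.n_nodes))


def solve_laplace(grid: VentricularGrid, boundary_sets, boundary_values) -> np.ndarray:
    """Discrete harmonic nodal field with Dirichlet boundary sets.

    ``boundary_sets`` is a sequence of node-index arrays, ``boundary_values``
    the corresponding Dirichlet values.  Non-Dirichlet boundary nodes get the
    natural no-flux condition.  The solution obeys the discrete maximum
    principle.  Raises if a connected component of the domain carries no
    Dirichlet node, or if the Dirichlet sets overlap.
    """
    if len(boundary_sets) != len(boundary_values) or len(boundary_sets) < 2:
        raise ValueError("need at least two boundary sets with values")
    adj = _node_adjacency(grid)
    n = grid.n_nodes
    fixed = np.full(n, np.nan)
    for nodes_k, val in zip(boundary_sets, boundary_values):
        nodes_k = np.asarray(nodes_k, dtype=int)
        if nodes_k.size == 0:
            raise ValueError("empty Dirichlet set")
        if np.any(np.isfinite(fixed[nodes_k])):
            raise ValueError("Dirichlet sets overlap")
        fixed[nodes_k] = val
    ncomp, comp = connected_components(adj, directed=False)
    has_bc = np.zeros(ncomp, dtype=bool)
    has_bc[comp[np.isfinite(fixed)]] = True
    if not has_bc.all():
        raise ValueError("domain component without Dirichlet boundary")

    deg = np.asarray(adj.sum(axis=1)).ravel()
    lap = sp.diags(deg) - adj
    is_fixed = np.isfinite(fixed)
    free = ~is_fixed
    phi = np.empty(n)
    phi[is_fixed] = fixed[is_fixed]
    if free.any():
        a = lap.tocsr()[free][:, free]
        b = -lap.tocsr()[free][:, is_fixed] @ fixed[is_fixed]
        phi[free] = spsolve(a, b)
    return phi


def find_transmural_boundaries(grid: VentricularGrid):
    """Endocardial and epicardial node sets of an annular short-axis grid.

    Background components of the element grid are classified by flood fill:
    the component touching the image border is outside (epicardial), interior
    components are the cavity (endocardial).  Returns (endo, epi) node-index
    arrays.
    """
    absent = grid.elem_label == 0
    comp, ncomp = ndimage.label(absent)
    border_labels = set(np.unique(np.concatenate([
        comp[0, :], comp[-1, :], comp[:, 0], comp[:, -1]]))) - {0}
    hole_labels = set(range(1, ncomp + 1)) - border_labels
    if not hole_labels:
        raise ValueError("no cavity found: grid is not annular")

    def nodes_adjacent_to(labels_set):
        sel = np.isin(comp, list(labels_set))
        node_sel = np.zeros(grid.node_id.shape, dtype=bool)
        node_sel[:-1, :-1] |= sel
        node_sel[:-1, 1:] |= sel
        node_sel[1:, :-1] |= sel
        node_sel[1:, 1:] |= sel
        # outside-the-grid is also epicardial boundary
        ids = grid.node_id[node_sel]
        return np.unique(ids[ids >= 0])

    endo = nodes_adjacent_to(hole_labels)
    epi_sel = nodes_adjacent_to(border_labels) if border_labels else np.array([], int)
    # nodes on the outer frame of the node grid are epicardial as well
    frame = np.zeros(grid.node_id.shape, dtype=bool)
    frame[0, :] = frame[-1, :] = True
    frame[:, 0] = frame[:, -1] = True
    frame_ids = grid.node_id[frame]
    epi = np.unique(np.concatenate([epi_sel, frame_ids[frame_ids >= 0]]))
    epi = np.setdiff1d(epi, endo)
    return endo, epi


def _element_gradient(grid: VentricularGrid, phi: np.ndarray) -> np.ndarray:
    """Bilinear-element gradient of a nodal field, per element (d/dx, d/dy)."""
    n0, n1, n2, n3 = (grid.elements[:, k] for k in range(4))
    h = grid.h_mm
    gx = 0.5 * ((phi[n1] - phi[n0]) + (phi[n2] - phi[n3])) / h
    gy = 0.5 * ((phi[n3] - phi[n0]) + (phi[n2] - phi[n1])) / h
    return np.stack([gx, gy], axis=1)


def assign_fibers(grid: VentricularGrid, apicobasal_field: np.ndarray | None,
                  transmural_field: np.ndarray,
                  angle_endo_deg: float = DEFAULT_ANGLE_ENDO_DEG,
                  angle_epi_deg: float = DEFAULT_ANGLE_EPI_DEG) -> FiberField:
    """Rule-based per-element fiber orientation.

    The transmural unit direction n is the normalized gradient of the
    transmural harmonic field.  The apicobasal direction (out-of-plane z for
    short-axis slices when no apicobasal field is given) is orthogonalized
    against n; their cross product is the circumferential direction c.  The
    fiber is c rotated about n by the helix angle, interpolated linearly from
    ``angle_endo_deg`` (transmural coordinate 0) to ``angle_epi_deg``
    (coordinate 1).  Elements with a vanishing transmural gradient fall back
    to the average frame of their neighbors (logged).
    """
    m = grid.n_elements
    g2 = _element_gradient(grid, transmural_field)
    n_vec = np.zeros((m, 3))
    n_vec[:, :2] = g2
    norms = np.linalg.norm(n_vec, axis=1)
    degenerate = norms < 1e-12 * max(1.0, float(norms.max()))
    if degenerate.any():
        log.warning("%d element(s) with vanishing transmural gradient; "
                    "using neighbor-average fallback", int(degenerate.sum()))
        ok = ~degenerate
        if not ok.any():
            raise ValueError("transmural field has no usable gradient")
        centers = grid.element_centers()
        for i in np.nonzero(degenerate)[0]:
            d = np.linalg.norm(centers[ok] - centers[i], axis=1)
            n_vec[i] = n_vec[ok][np.argmin(d)]
        norms = np.linalg.norm(n_vec, axis=1)
    n_hat = n_vec / norms[:, None]

    if apicobasal_field is None:
        a0 = np.tile(np.array([0.0, 0.0, 1.0]), (m, 1))
    else:
        a0 = np.zeros((m, 3))
        a0[:, :2] = _element_gradient(grid, apicobasal_field)
        bad = np.linalg.norm(a0, axis=1) < 1e-12
        a0[bad] = np.array([0.0, 0.0, 1.0])
    a0 = a0 - np.sum(a0 * n_hat, axis=1)[:, None] * n_hat
    a_norm = np.linalg.norm(a0, axis=1)
    if np.any(a_norm < 1e-12):
        raise ValueError("apicobasal direction parallel to transmural gradient")
    a_hat = a0 / a_norm[:, None]
    c_hat = np.cross(a_hat, n_hat)

    # element transmural coordinate: mean of corner values
    phi_e = transmural_field[grid.elements].mean(axis=1)
    angles = angle_endo_deg + (angle_epi_deg - angle_endo_deg) * phi_e
    alpha = np.deg2rad(angles)
    # rotation of c about n by alpha: cos(a) c + sin(a) (n x c);  n x c = a
    fibers = np.cos(alpha)[:, None] * c_hat + np.sin(alpha)[:, None] * a_hat
    fibers /= np.linalg.norm(fibers, axis=1)[:, None]
    return FiberField(fibers=fibers, angles_deg=angles, sheet_normal=n_hat)
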