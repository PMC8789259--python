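"""File formats: NIfTI images, legacy-VTK meshes, CSV tables.

Images travel as NIfTI with voxel spacing in the affine (one file per
modality, masks as separate files); tissue label maps use integer codes
{0 background, 1 normal, 2 diffuse, 3 dense}.  Grids with element data are
written as legacy ASCII VTK unstructured grids.
"""
from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .fusion import LGEStack, T1Map, TissueLabelMap

__all__ = [
    "save_lge_stack", "load_lge_stack", "save_t1_map", "load_t1_map",
    "save_labelmap", "load_labelmap", "save_outcomes_csv", "load_outcomes_csv",
    "write_grid_vtk",
]


def _affine(inplane_mm: float, slice_mm: float) -> np.ndarray:
    return np.diag([inplane_mm, inplane_mm, slice_mm, 1.0])


def save_lge_stack(stack: LGEStack, path, mask_path=None) -> None:
    aff = _affine(stack.spacing[0], stack.spacing[1])
    nib.save(nib.Nifti1Image(stack.intensities.astype(np.float32), aff), str(path))
    if mask_path is not None:
        nib.save(nib.Nifti1Image(stack.lv_mask.astype(np.uint8), aff), str(mask_path))


def load_lge_stack(path, mask_path) -> LGEStack:
    img = nib.load(str(path))
    msk = nib.load(str(mask_path))
    zooms = img.header.get_zooms()
    nz = img.shape[2]
    return LGEStack(np.asarray(img.dataobj, dtype=float),
                    np.asarray(msk.dataobj) > 0,
                    (float(zooms[0]), float(zooms[2])),
                    np.arange(nz) * float(zooms[2]))


def save_t1_map(t1: T1Map, path, mask_path=None) -> None:
    aff = _affine(t1.spacing[0], t1.spacing[1])
    aff[2, 3] = t1.slice_z
    nib.save(nib.Nifti1Image(t1.times_ms[..., None].astype(np.float32), aff),
             str(path))
    if mask_path is not None:
        nib.save(nib.Nifti1Image(t1.lv_mask[..., None].astype(np.uint8), aff),
                 str(mask_path))


def load_t1_map(path, mask_path) -> T1Map:
    img = nib.load(str(path))
    msk = nib.load(str(mask_path))
    zooms = img.header.get_zooms()
    z = float(img.affine[2, 3])
    return T1Map(np.asarray(img.dataobj, dtype=float)[:, :, 0],
                 np.asarray(msk.dataobj)[:, :, 0] > 0,
                 (float(zooms[0]), float(zooms[2])), z)


def save_labelmap(lm: TissueLabelMap, path) -> None:
    arr = lm.labels
    if arr.ndim == 2:
        arr = arr[..., None]
    slice_mm = lm.spacing[1] if len(lm.spacing) > 1 else lm.spacing[0]
    nib.save(nib.Nifti1Image(arr.astype(np.int16), _affine(lm.spacing[0], slice_mm)),
             str(path))


def load_labelmap(path) -> TissueLabelMap:
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj).astype(np.int8)
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[:, :, 0]
    zooms = img.header.get_zooms()
    nz = arr.shape[2] if arr.ndim == 3 else 1
    return TissueLabelMap(arr, (float(zooms[0]), float(zooms[2])),
                          np.arange(nz) * float(zooms[2]) if arr.ndim == 3 else None)


def save_outcomes_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def load_outcomes_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("clinical_va", "accf_aha", "esc", "lge_t1", "lge_only"):
        if col in df:
            df[col] = df[col].astype(bool)
    return df


def write_grid_vtk(grid, path, fibers=None, node_data=None) -> None:
    """Write a structured-quad grid as legacy ASCII VTK with element arrays.

    ``fibers`` adds the per-element "fiber" vector array and "label" is
    always written; ``node_data`` is a mapping of name -> per-node scalars.
    """
    path = Path(path)
    n = grid.n_nodes
    m = grid.n_elements
    with path.open("w") as f:
        f.write("# vtk DataFile Version 3.0\nvirtuheart grid\nASCII\n")
        f.write("DATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {n} float\n")
        for x, y in grid.nodes:
            f.write(f"{x:.6g} {y:.6g} 0\n")
        f.write(f"CELLS {m} {5 * m}\n")
        for quad in grid.elements:
            f.write("4 " + " ".join(str(int(q)) for q in quad) + "\n")
        f.write(f"CELL_TYPES {m}\n")
        f.write("9\n" * m)   # VTK_QUAD
        f.write(f"CELL_DATA {m}\n")
        f.write("SCALARS label int 1\nLOOKUP_TABLE default\n")
        f.write("\n".join(str(int(v)) for v in grid.element_label) + "\n")
        if fibers is not None:
            f.write("VECTORS fiber float\n")
            for v in fibers.fibers:
                f.write(f"{v[0]:.6g} {v[1]:.6g} {v[2]:.6g}\n")
        if node_data:
            f.write(f"POINT_DATA {n}\n")
            for name, vals in node_data.items():
                f.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                f.write("\n".join(f"{float(v):.6g}" for v in vals) + "\n")
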