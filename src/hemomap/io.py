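"""File I/O: NIfTI volumes, legacy-ASCII VTK PolyData, PLY, JSON sidecars.

The index-to-world map is a pure scale + offset (mm); velocity components
are stored as three 4D NIfTI volumes (x, y, z, t) in cm/s, or one 5D
volume, flag-selectable. The VTK writer emits legacy ASCII PolyData with
per-vertex scalars/vectors so meshes open directly in ParaView.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import nibabel as nib
import numpy as np

from .fields import ScalarVolume, SegMask, VelocityField4D

__all__ = [
    "save_nifti",
    "load_nifti",
    "save_velocity",
    "load_velocity",
    "save_mask",
    "load_mask",
    "write_vtk_polydata",
    "write_ply",
    "save_json",
    "load_json",
]


def _affine(spacing, origin) -> np.ndarray:
    A = np.eye(4)
    A[:3, :3] = np.diag(np.broadcast_to(np.asarray(spacing, float), (3,)))
    A[:3, 3] = np.broadcast_to(np.asarray(origin, float), (3,))
    return A


def save_nifti(data: np.ndarray, spacing, origin, path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(data), _affine(spacing, origin))
    nib.save(img, str(path))
    return path


def load_nifti(path):
    """Returns (data, spacing, origin); only scale+offset affines supported."""
    img = nib.load(str(path))
    A = img.affine
    spacing = np.abs(np.diag(A)[:3])
    origin = A[:3, 3]
    return np.asarray(img.dataobj, dtype=float), spacing, origin


def save_velocity(field: VelocityField4D, stem, split_components: bool = True) -> list[Path]:
    """Write the velocity field as <stem>_vx/vy/vz.nii.gz (4D each) or a
    single 5D <stem>_vel.nii.gz."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    out = []
    if split_components:
        for c, name in enumerate("xyz"):
            out.append(
                save_nifti(field.data[..., c], field.spacing, field.origin, f"{stem}_v{name}.nii.gz")
            )
    else:
        out.append(save_nifti(field.data, field.spacing, field.origin, f"{stem}_vel.nii.gz"))
    return out


def load_velocity(paths: Union[str, Path, list], venc: float = 150.0) -> VelocityField4D:
    """Load from three 4D component files (list) or one 5D file (single path)."""
    if isinstance(paths, (list, tuple)):
        comps, spacing, origin = [], None, None
        for p in paths:
            d, spacing, origin = load_nifti(p)
            comps.append(d)
        data = np.stack(comps, axis=-1)
    else:
        data, spacing, origin = load_nifti(paths)
    return VelocityField4D(data, spacing, origin, venc=venc)


def save_mask(mask: SegMask, path) -> Path:
    return save_nifti(mask.data.astype(np.uint8), mask.spacing, mask.origin, path)


def load_mask(path) -> SegMask:
    data, spacing, origin = load_nifti(path)
    return SegMask(data > 0.5, spacing, origin)


def save_scalar(vol: ScalarVolume, path) -> Path:
    return save_nifti(vol.data, vol.spacing, vol.origin, path)


def write_vtk_polydata(path, vertices: np.ndarray, faces: np.ndarray, point_data: Optional[dict] = None) -> Path:
    """Legacy-ASCII VTK PolyData with optional per-vertex scalars/vectors."""
    path = Path(path)
    vertices = np.asarray(vertices, float)
    faces = np.asarray(faces, int)
    lines = [
        "# vtk DataFile Version 3.0",
        "hemomap surface",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(vertices)} float",
    ]
    lines += [" ".join(f"{v:.6f}" for v in p) for p in vertices]
    lines.append(f"POLYGONS {len(faces)} {4 * len(faces)}")
    lines += ["3 " + " ".join(str(i) for i in f) for f in faces]
    if point_data:
        lines.append(f"POINT_DATA {len(vertices)}")
        for name, arr in point_data.items():
            arr = np.nan_to_num(np.asarray(arr, float))
            if arr.ndim == 1:
                lines.append(f"SCALARS {name} float 1")
                lines.append("LOOKUP_TABLE default")
                lines += [f"{v:.6f}" for v in arr]
            else:
                lines.append(f"VECTORS {name} float")
                lines += [" ".join(f"{v:.6f}" for v in row) for row in arr]
    path.write_text("\n".join(lines) + "\n")
    return path


def write_ply(path, vertices: np.ndarray, faces: np.ndarray) -> Path:
    import trimesh

    path = Path(path)
    trimesh.Trimesh(vertices, faces, process=False).export(str(path), encoding="ascii")
    return path


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        return super().default(o)


def save_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, cls=_NumpyEncoder) + "\n")
    return path


def load_json(path):
    return json.loads(Path(path).read_text())
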