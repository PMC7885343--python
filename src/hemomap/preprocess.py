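"""Velocity-field conditioning and peak-systole extraction.

Covers the standard 4D-flow preprocessing chain: background phase-offset
correction by fitting a plane through stationary tissue, PC-MRA synthesis
(magnitude x speed, averaged over the cardiac cycle), peak-systole
selection as the phase with the highest segmentation-averaged speed, and
extraction of the masked peak-systolic vector map.
"""

from __future__ import annotations

import logging
import warnings
from typing import Optional

import numpy as np

from .fields import ScalarVolume, SegMask, VelocityField4D, VoxelVectorMap

__all__ = [
    "auto_static_mask",
    "correct_background_phase",
    "compute_pcmra",
    "find_peak_systole",
    "extract_peak_vectors",
]

log = logging.getLogger(__name__)

MIN_STATIC_VOXELS = 100


def auto_static_mask(field: VelocityField4D, magnitude: Optional[np.ndarray] = None) -> SegMask:
    """Heuristic stationary-tissue mask.

    Static voxels are those whose temporal standard deviation of speed falls
    below the 20th percentile; when a magnitude image is given, voxels must
    additionally exceed its 25th percentile (suppresses air).
    """
    speed = field.speed()
    sd = speed.std(axis=-1)
    static = sd <= np.percentile(sd, 20)
    if magnitude is not None:
        mag = np.asarray(magnitude, dtype=float)
        if mag.ndim == 4:
            mag = mag.mean(axis=-1)
        static &= mag > np.percentile(mag, 25)
    return SegMask(static, field.spacing, field.origin)


def _plane_design(shape, spacing, origin) -> np.ndarray:
    idx = np.indices(shape).reshape(3, -1).T
    xyz = origin + idx * spacing
    return np.column_stack([np.ones(len(xyz)), xyz])  # columns: 1, x, y, z


def correct_background_phase(
    field: VelocityField4D,
    static_mask: Optional[SegMask] = None,
    per_frame: bool = False,
    order: int = 1,
) -> tuple[VelocityField4D, Optional[np.ndarray]]:
    """Remove background phase offsets by a least-squares plane fit.

    For each velocity component a first-order polynomial a + b x + c y + d z
    is fitted to the time-averaged component over stationary-tissue voxels
    and subtracted from every voxel and frame. Returns the corrected field
    and the (3, 4) coefficient array [a, b, c, d] per component, or None
    when too few static voxels were available and correction was skipped.

    ``per_frame`` fits and subtracts a separate plane per cardiac phase
    (coefficients then have shape (nt, 3, 4)); ``order=2`` adds quadratic
    terms behind the same interface.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    if static_mask is None:
        static_mask = auto_static_mask(field)
    static = static_mask.data
    if static.shape != field.grid_shape:
        raise ValueError("static mask grid does not match the velocity field")
    n_static = int(static.sum())
    if n_static < MIN_STATIC_VOXELS:
        warnings.warn(
            f"only {n_static} static voxels (< {MIN_STATIC_VOXELS}); "
            "background phase correction skipped",
            stacklevel=2,
        )
        return field.copy_with(data=field.data.copy()), None

    X = _plane_design(field.grid_shape, field.spacing, field.origin)
    if order == 2:
        xyz = X[:, 1:]
        X = np.column_stack([X, xyz**2, xyz[:, 0:1] * xyz[:, 1:2], xyz[:, 0:1] * xyz[:, 2:3], xyz[:, 1:2] * xyz[:, 2:3]])
    flat_static = static.ravel()
    Xs = X[flat_static]

    data = field.data.copy()
    nx, ny, nz, nt, _ = data.shape
    if per_frame:
        coeffs = np.empty((nt, 3, X.shape[1]))
        for t in range(nt):
            for c in range(3):
                comp = data[:, :, :, t, c].ravel()
                beta, *_ = np.linalg.lstsq(Xs, comp[flat_static], rcond=None)
                coeffs[t, c] = beta
                data[:, :, :, t, c] -= (X @ beta).reshape(nx, ny, nz)
    else:
        coeffs = np.empty((3, X.shape[1]))
        tmean = data.mean(axis=3)  # (nx, ny, nz, 3)
        for c in range(3):
            comp = tmean[:, :, :, c].ravel()
            beta, *_ = np.linalg.lstsq(Xs, comp[flat_static], rcond=None)
            coeffs[c] = beta
            data[:, :, :, :, c] -= (X @ beta).reshape(nx, ny, nz)[:, :, :, None]
    log.info("background phase correction: %d static voxels, order %d", n_static, order)
    return field.copy_with(data=data), coeffs


def compute_pcmra(magnitude: np.ndarray, field: VelocityField4D) -> ScalarVolume:
    """Phase-contrast MR angiogram: mean over frames of magnitude x speed."""
    mag = np.asarray(magnitude, dtype=float)
    expected = field.grid_shape + (field.n_frames,)
    if mag.shape != expected:
        raise ValueError(f"magnitude shape {mag.shape} does not match field {expected}")
    pcmra = (mag * field.speed()).mean(axis=-1)
    return ScalarVolume(pcmra, field.spacing, field.origin, units="a.u.")


def find_peak_systole(field: VelocityField4D, mask: SegMask) -> int:
    """Cardiac phase with the highest mask-averaged speed (earliest on ties)."""
    if mask.data.shape != field.grid_shape:
        raise ValueError("mask grid does not match the velocity field")
    if mask.n_voxels == 0:
        raise ValueError("mask is empty")
    mean_speed = field.speed()[mask.data].mean(axis=0)  # (nt,)
    return int(np.argmax(mean_speed))  # argmax returns the first maximum


def extract_peak_vectors(field: VelocityField4D, mask: SegMask, frame: int) -> VoxelVectorMap:
    """Peak-systolic velocity vectors restricted to the lumen mask."""
    if not 0 <= frame < field.n_frames:
        raise IndexError(f"frame {frame} out of range [0, {field.n_frames})")
    if mask.data.shape != field.grid_shape:
        raise ValueError("mask grid does not match the velocity field")
    data = field.frame(frame).copy()
    data[~mask.data] = 0.0
    return VoxelVectorMap(data, mask.data.copy(), field.spacing, field.origin, venc=field.venc)
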