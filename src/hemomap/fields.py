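"""Gridded data containers shared across the pipeline.

All volumes live on regular axis-aligned grids. World coordinates are in
millimetres: ``world = origin + index * spacing`` (no rotation in the
index-to-world map; oblique acquisitions are assumed resampled upstream).
Velocities are stored in cm/s, matching VENC conventions; SI conversion
happens inside the wall-shear-stress and vorticity computations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "VelocityField4D",
    "ScalarVolume",
    "SegMask",
    "VoxelVectorMap",
]


def _as_spacing(spacing) -> np.ndarray:
    s = np.broadcast_to(np.asarray(spacing, dtype=float), (3,)).copy()
    if np.any(s <= 0):
        raise ValueError(f"spacing must be positive, got {s}")
    return s


def _as_origin(origin) -> np.ndarray:
    return np.broadcast_to(np.asarray(origin, dtype=float), (3,)).copy()


@dataclass
class VelocityField4D:
    """Time-resolved 3-component velocity field from 4D flow CMR.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz, nt, 3)
        Velocity components in cm/s, ordered (vx, vy, vz).
    spacing : array-like of 3 floats
        Voxel spacing in mm.
    origin : array-like of 3 floats
        World coordinate (mm) of voxel (0, 0, 0).
    venc : float
        Velocity-encoding limit of the acquisition, cm/s.
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    venc: float = 150.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 5 or self.data.shape[-1] != 3:
            raise ValueError(
                f"velocity data must have shape (nx, ny, nz, nt, 3), got {self.data.shape}"
            )
        if self.data.shape[3] < 1:
            raise ValueError("velocity field needs at least one time frame")
        self.spacing = _as_spacing(self.spacing)
        self.origin = _as_origin(self.origin)
        if self.venc <= 0:
            raise ValueError("venc must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def speed(self) -> np.ndarray:
        """Per-voxel, per-frame speed ‖V‖₂ (cm/s), shape (nx, ny, nz, nt)."""
        return np.linalg.norm(self.data, axis=-1)

    def frame(self, t: int) -> np.ndarray:
        """Velocity vectors of one cardiac phase, shape (nx, ny, nz, 3)."""
        if not 0 <= t < self.n_frames:
            raise IndexError(f"frame {t} out of range [0, {self.n_frames})")
        return self.data[:, :, :, t, :]

    def copy_with(self, **kw) -> "VelocityField4D":
        return replace(self, **kw)


@dataclass
class ScalarVolume:
    """A single 3D scalar volume (e.g. the PC-MRA)."""

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    units: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"scalar volume must be 3D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("scalar volume contains non-finite values")
        self.spacing = _as_spacing(self.spacing)
        self.origin = _as_origin(self.origin)


@dataclass
class SegMask:
    """Binary lumen segmentation on a regular grid."""

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {self.data.shape}")
        self.spacing = _as_spacing(self.spacing)
        self.origin = _as_origin(self.origin)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def volume_cm3(self) -> float:
        return self.n_voxels * self.voxel_volume_mm3 / 1000.0

    def indices(self) -> np.ndarray:
        """(n, 3) integer indices of mask voxels, C-order."""
        return np.argwhere(self.data)

    def world_points(self) -> np.ndarray:
        """(n, 3) world coordinates (mm) of mask voxel centers."""
        return self.origin + self.indices() * self.spacing

    def largest_component(self) -> "SegMask":
        from scipy import ndimage

        lab, n = ndimage.label(self.data)
        if n == 0:
            raise ValueError("mask is empty")
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=range(1, n + 1))
        keep = 1 + int(np.argmax(sizes))
        return SegMask(lab == keep, self.spacing, self.origin)


@dataclass
class VoxelVectorMap:
    """A single-frame 3-vector field restricted to a voxel support.

    ``data`` is dense, shape (nx, ny, nz, 3), in cm/s; ``support`` marks the
    voxels on which the map is defined (values outside are not meaningful).
    """

    data: np.ndarray
    support: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    venc: float = 150.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.support = np.asarray(self.support).astype(bool)
        if self.data.ndim != 4 or self.data.shape[-1] != 3:
            raise ValueError(f"vector map must have shape (nx, ny, nz, 3), got {self.data.shape}")
        if self.support.shape != self.data.shape[:3]:
            raise ValueError("support shape does not match data grid")
        self.spacing = _as_spacing(self.spacing)
        self.origin = _as_origin(self.origin)

    @property
    def n_support(self) -> int:
        return int(self.support.sum())

    def vectors(self) -> np.ndarray:
        """(n, 3) vectors on the support, in C-order of the support voxels."""
        return self.data[self.support]

    def magnitudes(self) -> np.ndarray:
        return np.linalg.norm(self.vectors(), axis=-1)
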