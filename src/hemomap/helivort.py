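"""Vorticity and local normalized helicity (LNH).

Vorticity is curl V computed with fourth-order central differences (the
Richardson-extrapolated central stencil
f' ~ [-f(+2h) + 8 f(+h) - 8 f(-h) + f(-2h)] / 12h) wherever the full
5-point stencil lies inside the support, falling back to second-order
central differences where only the +/-1 neighbours exist, and flagged
invalid otherwise. LNH is the cosine of the angle between V and omega,
in [-1, 1]: +/-1 means purely helical flow (velocity aligned with the
local rotation axis), 0 a planar vortex.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .fields import VoxelVectorMap
from .geometry import RegionLabels, quantify_volume

__all__ = [
    "VorticityMap",
    "LNHMap",
    "compute_vorticity",
    "compute_lnh",
    "quantify_lnh_volume",
    "quantify_vorticity",
    "LNH_THRESHOLD_DEFAULT",
]

LNH_THRESHOLD_DEFAULT = 0.6
_EPS_OMEGA = 1e-6  # 1/s

_REGIONS = ("innerAAo", "outerAAo", "AAo", "pDAo")


@dataclass
class VorticityMap:
    """Per-voxel vorticity vectors (1/s) with stencil-validity flags."""

    omega: np.ndarray  # (nx, ny, nz, 3), 1/s; NaN where invalid
    valid: np.ndarray  # (nx, ny, nz) bool
    spacing: np.ndarray
    origin: np.ndarray

    def magnitudes(self) -> np.ndarray:
        return np.linalg.norm(self.omega, axis=-1)


@dataclass
class LNHMap:
    """Per-voxel local normalized helicity in [-1, 1] with defined-flags."""

    lnh: np.ndarray  # (nx, ny, nz); NaN where undefined
    defined: np.ndarray  # bool


def _axis_derivative(f: np.ndarray, support: np.ndarray, axis: int, h_m: float):
    """Mixed 4th/2nd-order derivative of f along axis; NaN where no stencil."""
    fp = np.pad(f, 2, mode="constant")
    sp = np.pad(support, 2, mode="constant", constant_values=False)

    def shift(a, k):
        sl = [slice(2, -2)] * a.ndim
        sl[axis] = slice(2 + k, a.shape[axis] - 2 + k)
        return a[tuple(sl)]

    s_p1, s_m1 = shift(sp, 1), shift(sp, -1)
    s_p2, s_m2 = shift(sp, 2), shift(sp, -2)
    f_p1, f_m1 = shift(fp, 1), shift(fp, -1)
    f_p2, f_m2 = shift(fp, 2), shift(fp, -2)

    ok2 = support & s_p1 & s_m1
    ok4 = ok2 & s_p2 & s_m2
    d4 = (-f_p2 + 8.0 * f_p1 - 8.0 * f_m1 + f_m2) / (12.0 * h_m)
    d2 = (f_p1 - f_m1) / (2.0 * h_m)
    out = np.full(f.shape, np.nan)
    out[ok2] = d2[ok2]
    out[ok4] = d4[ok4]
    return out, ok2


def compute_vorticity(velocity: VoxelVectorMap, spacing=None) -> VorticityMap:
    """curl V in 1/s on the velocity support (cm/s, mm grid -> SI inside)."""
    spacing = np.broadcast_to(
        np.asarray(velocity.spacing if spacing is None else spacing, dtype=float), (3,)
    )
    support = velocity.support
    v_ms = velocity.data * 0.01  # cm/s -> m/s
    h_m = spacing * 1e-3  # mm -> m

    # d[c][a] = d v_c / d x_a
    d = [[None] * 3 for _ in range(3)]
    any_valid = np.zeros(support.shape, dtype=bool)
    for c in range(3):
        for a in range(3):
            d[c][a], ok = _axis_derivative(v_ms[..., c], support, a, h_m[a])
            any_valid |= ok
    if not any_valid.any():
        warnings.warn("mask too thin for any derivative stencil; vorticity all-invalid", stacklevel=2)

    omega = np.stack(
        [
            d[2][1] - d[1][2],
            d[0][2] - d[2][0],
            d[1][0] - d[0][1],
        ],
        axis=-1,
    )
    valid = np.all(np.isfinite(omega), axis=-1)
    omega[~valid] = np.nan
    return VorticityMap(omega=omega, valid=valid, spacing=spacing.copy(), origin=velocity.origin.copy())


def compute_lnh(velocity: VoxelVectorMap, vorticity: VorticityMap) -> LNHMap:
    """LNH = V . omega / (|V| |omega|), clamped to [-1, 1].

    Undefined (NaN) where either vector is numerically zero (speed below
    1e-6 x VENC, vorticity below 1e-6 1/s) or the stencil was unavailable.
    """
    if velocity.data.shape[:3] != vorticity.omega.shape[:3]:
        raise ValueError("velocity and vorticity grids do not match")
    v = velocity.data
    w = vorticity.omega
    vnorm = np.linalg.norm(v, axis=-1)
    wnorm = np.linalg.norm(w, axis=-1)
    eps_v = 1e-6 * velocity.venc
    defined = velocity.support & vorticity.valid & (vnorm > eps_v) & (wnorm > _EPS_OMEGA)

    lnh = np.full(vnorm.shape, np.nan)
    dot = np.einsum("...i,...i->...", v, w)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = dot / (vnorm * wnorm)
    lnh[defined] = np.clip(vals[defined], -1.0, 1.0)
    return LNHMap(lnh=lnh, defined=defined)


def _region_masks(regions: Optional[RegionLabels], shape) -> dict:
    if regions is None:
        return {"all": np.ones(shape, dtype=bool)}
    return {name: regions.voxel_region(name) for name in _REGIONS}


def quantify_lnh_volume(
    lnh: LNHMap,
    regions: Optional[RegionLabels],
    spacing,
    threshold: float = LNH_THRESHOLD_DEFAULT,
) -> dict:
    """Volume (cm^3) of |LNH| > threshold per region."""
    flagged = lnh.defined & (np.abs(np.nan_to_num(lnh.lnh)) > threshold)
    return {
        name: quantify_volume(flagged & rm, spacing)
        for name, rm in _region_masks(regions, lnh.lnh.shape).items()
    }


def quantify_vorticity(
    vorticity: VorticityMap,
    regions: Optional[RegionLabels],
    integral: bool = False,
) -> dict:
    """Mean |omega| (1/s) over valid voxels per region (None if no voxels).

    ``integral=True`` returns instead the volume integral of |omega| in
    cm^3/s (magnitude x voxel volume, summed).
    """
    mag = vorticity.magnitudes()
    out = {}
    for name, rm in _region_masks(regions, vorticity.valid.shape).items():
        sel = rm & vorticity.valid
        if not sel.any():
            out[name] = None
        elif integral:
            out[name] = float(np.nansum(mag[sel]) * np.prod(vorticity.spacing) / 1000.0)
        else:
            out[name] = float(np.nanmean(mag[sel]))
    return out
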