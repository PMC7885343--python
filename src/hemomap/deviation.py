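"""Angle-deviation maps, 60/120-degree categories, regional quantification
and ensemble incidence maps.

The subject's velocity (per voxel) and WSS (per vertex) vectors v are
compared against the cohort-averaged reference u through
cos(theta) = u.v / (|u||v|), theta in [0, 180] degrees. Deviations are
categorized green (< 60), yellow (60-120) and red (> 120) with half-open
boundaries [0,60), [60,120), [120,180]; locations where either vector is
numerically zero are 'undefined' and excluded from quantification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .fields import VoxelVectorMap
from .geometry import RegionLabels, WallMesh, quantify_surface, quantify_volume

__all__ = [
    "CAT_GREEN",
    "CAT_YELLOW",
    "CAT_RED",
    "CAT_UNDEFINED",
    "DeviationMap",
    "angle_between",
    "map_deviation",
    "categorize",
    "quantify_regional",
    "IncidenceMap",
    "ensemble_incidence",
    "THRESHOLD_LOW_DEG",
    "THRESHOLD_HIGH_DEG",
]

THRESHOLD_LOW_DEG = 60.0
THRESHOLD_HIGH_DEG = 120.0

CAT_GREEN, CAT_YELLOW, CAT_RED, CAT_UNDEFINED = 0, 1, 2, 3
_CAT_NAMES = {CAT_GREEN: "G", CAT_YELLOW: "Y", CAT_RED: "R", CAT_UNDEFINED: "U"}

_ROWS = ("innerAAo", "outerAAo", "AAo", "pDAo")
_COLS = ("volume_60_120", "volume_gt120", "surface_60_120", "surface_gt120")


def angle_between(u: np.ndarray, v: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    """Angle(s) in degrees between vectors; NaN where either is ~zero.

    Symmetric and invariant to positive scaling of either argument; the
    cosine is clamped before arccos so antiparallel vectors give exactly
    180 despite rounding.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    un = np.linalg.norm(u, axis=-1)
    vn = np.linalg.norm(v, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.einsum("...i,...i->...", u, v) / (un * vn)
    theta = np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))
    return np.where((un > eps) & (vn > eps), theta, np.nan)


@dataclass
class DeviationMap:
    """Per-location deviation angle and category.

    ``kind`` is 'voxel' (velocity, on a grid with a support mask) or
    'vertex' (WSS, flat per-vertex arrays). ``theta`` is NaN and
    ``category`` is CAT_UNDEFINED where the angle is undefined.
    """

    theta: np.ndarray  # degrees
    category: np.ndarray  # int codes
    kind: str  # 'voxel' | 'vertex'
    support: Optional[np.ndarray] = None  # voxel kind: bool grid

    def category_mask(self, cat: int) -> np.ndarray:
        m = self.category == cat
        if self.support is not None:
            m &= self.support
        return m

    def counts(self) -> dict:
        return {
            name: int(self.category_mask(code).sum()) for code, name in _CAT_NAMES.items()
        }


def _eps_for(vmap) -> float:
    venc = getattr(vmap, "venc", None)
    return 1e-6 * venc if venc else 1e-12


def map_deviation(
    subject: Union[VoxelVectorMap, np.ndarray],
    reference: Union[VoxelVectorMap, np.ndarray],
) -> DeviationMap:
    """Deviation angle of the subject's vectors from the reference map.

    Both arguments are either VoxelVectorMaps on the same grid (velocity)
    or (nv, 3) per-vertex arrays (WSS; NaN rows mean no reference). The
    angle is undefined where the reference is absent or either vector is
    numerically zero.
    """
    if isinstance(subject, VoxelVectorMap) != isinstance(reference, VoxelVectorMap):
        raise ValueError("subject and reference must be the same kind of map")
    if isinstance(subject, VoxelVectorMap):
        if subject.support.shape != reference.support.shape:
            raise ValueError("subject and reference grids do not match")
        support = subject.support & reference.support
        eps = max(_eps_for(subject), _eps_for(reference))
        theta = angle_between(subject.data, reference.data, eps=eps)
        theta[~support] = np.nan
        dev = DeviationMap(theta, _cats_from_theta(theta), "voxel", support=subject.support)
    else:
        s = np.asarray(subject, dtype=float)
        rarr = np.asarray(reference, dtype=float)
        if s.shape != rarr.shape:
            raise ValueError("subject and reference vertex arrays do not match")
        with np.errstate(invalid="ignore"):
            theta = angle_between(np.nan_to_num(s), np.nan_to_num(rarr), eps=1e-12)
        theta[~np.all(np.isfinite(s), axis=-1) | ~np.all(np.isfinite(rarr), axis=-1)] = np.nan
        dev = DeviationMap(theta, _cats_from_theta(theta), "vertex")
    return dev


def _cats_from_theta(theta: np.ndarray) -> np.ndarray:
    cat = np.full(theta.shape, CAT_UNDEFINED, dtype=int)
    defined = np.isfinite(theta)
    cat[defined & (theta < THRESHOLD_LOW_DEG)] = CAT_GREEN
    cat[defined & (theta >= THRESHOLD_LOW_DEG) & (theta < THRESHOLD_HIGH_DEG)] = CAT_YELLOW
    cat[defined & (theta >= THRESHOLD_HIGH_DEG)] = CAT_RED
    return cat


def categorize(dev: DeviationMap) -> DeviationMap:
    """(Re)derive categories from theta: [0,60) green, [60,120) yellow,
    [120,180] red; undefined preserved."""
    return DeviationMap(dev.theta, _cats_from_theta(dev.theta), dev.kind, support=dev.support)


def quantify_regional(
    dev_velocity: DeviationMap,
    dev_wss: Optional[DeviationMap],
    regions: RegionLabels,
    spacing,
    mesh: Optional[WallMesh] = None,
) -> pd.DataFrame:
    """Abnormal-direction volumes (cm^3) and surfaces (cm^2) per region.

    Rows: innerAAo, outerAAo, AAo (= inner + outer, exact), pDAo.
    Columns: volume_60_120, volume_gt120, surface_60_120, surface_gt120.
    Undefined locations contribute nothing.
    """
    if dev_velocity.kind != "voxel":
        raise ValueError("dev_velocity must be a voxel map")
    rows = {}
    y_vox = dev_velocity.category_mask(CAT_YELLOW)
    r_vox = dev_velocity.category_mask(CAT_RED)
    for region in _ROWS:
        rmask = regions.voxel_region(region)
        vol_y = quantify_volume(y_vox & rmask, spacing)
        vol_r = quantify_volume(r_vox & rmask, spacing)
        surf_y = surf_r = 0.0
        if dev_wss is not None:
            if dev_wss.kind != "vertex":
                raise ValueError("dev_wss must be a vertex map")
            if mesh is None:
                raise ValueError("mesh required to quantify WSS surfaces")
            vmask = regions.vertex_region(region)
            surf_y = quantify_surface((dev_wss.category == CAT_YELLOW) & vmask, mesh)
            surf_r = quantify_surface((dev_wss.category == CAT_RED) & vmask, mesh)
        rows[region] = [vol_y, vol_r, surf_y, surf_r]
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(_COLS))


@dataclass
class IncidenceMap:
    """Per-location percentage of subjects flagged in a category."""

    percent: np.ndarray  # [0, 100]
    n_subjects: int
    category: int


def ensemble_incidence(
    category_maps: Sequence[np.ndarray],
    categories: Sequence[int] = (CAT_YELLOW, CAT_RED),
) -> dict:
    """Incidence maps over a cohort of co-registered category maps.

    Each input is a per-location integer category array on a common shared
    geometry; the output per requested category is
    100 x (number of subjects flagged) / n at every location.
    """
    if len(category_maps) < 2:
        raise ValueError("ensemble incidence needs at least 2 subjects")
    stack = np.stack([np.asarray(m) for m in category_maps])
    n = len(category_maps)
    return {
        cat: IncidenceMap(100.0 * (stack == cat).sum(axis=0) / n, n, cat) for cat in categories
    }
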