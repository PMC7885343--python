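"""Lumen surface meshing and regional quantification primitives.

The wall mesh is the 0.5-isosurface of the binary segmentation (marching
cubes) in world mm, optionally Laplacian-smoothed, with per-vertex inward
normals, one-third-area weights and a local lumen radius obtained by
halving the inward-normal chord. Regions (inner/outer ascending aorta,
proximal descending aorta) are cut by user-supplied landmark planes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import trimesh
from scipy import ndimage
from skimage import measure

from .fields import SegMask

__all__ = [
    "WallMesh",
    "RegionLabels",
    "REGION_CODES",
    "extract_surface",
    "smooth_laplacian",
    "compute_inward_normals_and_radius",
    "subdivide_regions",
    "quantify_volume",
    "quantify_surface",
]

REGION_CODES = {"other": 0, "innerAAo": 1, "outerAAo": 2, "pDAo": 3}
REGION_NAMES = {v: k for k, v in REGION_CODES.items()}


@dataclass
class WallMesh:
    """Triangulated lumen surface in world mm."""

    vertices: np.ndarray  # (nv, 3)
    faces: np.ndarray  # (nf, 3) int
    inward_normal: Optional[np.ndarray] = None  # (nv, 3) unit
    vertex_area: Optional[np.ndarray] = None  # (nv,) mm^2
    local_radius: Optional[np.ndarray] = None  # (nv,) mm; NaN = unavailable

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)

    def total_area_mm2(self) -> float:
        return float(self.to_trimesh().area)

    def enclosed_volume_mm3(self) -> float:
        return float(abs(self.to_trimesh().volume))

    def copy_with(self, **kw) -> "WallMesh":
        return replace(self, **kw)


def _vertex_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """One-third of the incident face areas per vertex (sums to total area)."""
    tri = vertices[faces]
    fa = 0.5 * np.linalg.norm(np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
    va = np.zeros(len(vertices))
    np.add.at(va, faces.ravel(), np.repeat(fa / 3.0, 3))
    return va


def extract_surface(mask: SegMask, antialias_sigma: float = 0.5) -> WallMesh:
    """Closed triangulated 0.5-isosurface of the segmentation, in world mm.

    ``antialias_sigma`` (voxels) lightly Gaussian-smooths the binary volume
    before marching cubes, which removes most of the staircase area bias of
    binary isosurfaces; 0 disables it.
    """
    if mask.n_voxels == 0:
        raise ValueError("mask is empty")
    # pad so the isosurface closes even when the mask touches the grid edge
    vol = np.pad(mask.data.astype(float), 2)
    if antialias_sigma > 0:
        vol = ndimage.gaussian_filter(vol, antialias_sigma)
    verts, faces, _, _ = measure.marching_cubes(vol, level=0.5, spacing=tuple(mask.spacing))
    verts = verts - 2 * mask.spacing + mask.origin
    tm = trimesh.Trimesh(verts, faces, process=False)
    if not tm.is_watertight:
        raise ValueError(
            "isosurface is not watertight; check the segmentation for holes "
            "or grid-edge clipping"
        )
    return WallMesh(verts, faces, vertex_area=_vertex_areas(verts, faces))


def _adjacency(n_vertices: int, faces: np.ndarray):
    from scipy.sparse import coo_matrix

    e = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    e = np.vstack([e, e[:, ::-1]])
    w = np.ones(len(e))
    A = coo_matrix((w, (e[:, 0], e[:, 1])), shape=(n_vertices, n_vertices)).tocsr()
    A.data[:] = 1.0  # dedupe repeated edges
    deg = np.asarray(A.sum(axis=1)).ravel()
    return A, deg


def smooth_laplacian(mesh: WallMesh, iterations: int = 10, lam: float = 0.5) -> WallMesh:
    """Uniform-weight Laplacian smoothing: v <- v + lam * (mean(1-ring) - v)."""
    if not 0 < lam < 1:
        raise ValueError(f"lam must be in (0, 1), got {lam}")
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if iterations == 0:
        return mesh.copy_with(vertices=mesh.vertices.copy())
    A, deg = _adjacency(mesh.n_vertices, mesh.faces)
    deg = np.maximum(deg, 1.0)
    v = mesh.vertices.copy()
    for _ in range(iterations):
        v = v + lam * (A @ v / deg[:, None] - v)
    return WallMesh(v, mesh.faces, vertex_area=_vertex_areas(v, mesh.faces))


def _sample_mask(mask: SegMask, points: np.ndarray) -> np.ndarray:
    """Nearest-neighbour lookup of the binary mask at world points."""
    idx = np.rint((points - mask.origin) / mask.spacing).astype(int)
    shape = np.array(mask.data.shape)
    in_grid = np.all((idx >= 0) & (idx < shape), axis=-1)
    out = np.zeros(len(points), dtype=bool)
    ig = idx[in_grid]
    out[in_grid] = mask.data[ig[:, 0], ig[:, 1], ig[:, 2]]
    return out


def compute_inward_normals_and_radius(mesh: WallMesh, mask: SegMask) -> WallMesh:
    """Fill per-vertex inward normals and the local lumen radius.

    Normals are area-weighted vertex normals oriented into the mask. The
    local radius is half the chord from the vertex along the inward normal
    to the opposite lumen boundary; where the ray leaves the grid without
    exiting the lumen, the Euclidean distance-transform value at the nearest
    interior voxel is used instead. Vertices where both fail get NaN radius
    and are excluded from wall shear stress downstream.
    """
    tm = mesh.to_trimesh()
    normals = np.array(tm.vertex_normals, dtype=float)
    normals /= np.maximum(np.linalg.norm(normals, axis=1, keepdims=True), 1e-12)

    # orient into the lumen: majority vote at a half-voxel probe
    probe = mesh.vertices + 0.75 * float(min(mask.spacing)) * normals
    if _sample_mask(mask, probe).mean() < 0.5:
        normals = -normals

    edt = ndimage.distance_transform_edt(mask.data, sampling=mask.spacing)
    step = float(min(mask.spacing)) / 4.0
    diag = float(np.linalg.norm(np.array(mask.data.shape) * mask.spacing))
    # a lumen chord cannot much exceed a few inscribed diameters; capping the
    # march keeps memory bounded on fine grids
    max_chord = min(diag, 8.0 * float(edt.max()) + 4.0 * float(max(mask.spacing)))
    ds = np.arange(step, max_chord, step)

    nv = mesh.n_vertices
    radius = np.full(nv, np.nan)
    for lo in range(0, nv, 4096):
        sl = slice(lo, min(lo + 4096, nv))
        pts = mesh.vertices[None, sl, :] + ds[:, None, None] * normals[None, sl, :]
        inside = _sample_mask(mask, pts.reshape(-1, 3)).reshape(len(ds), -1)
        # exit point: first outside sample after the ray has been inside
        seen_inside = np.cumsum(inside, axis=0) > 0
        exit_candidate = ~inside & seen_inside
        entered = exit_candidate.any(axis=0)
        exit_idx = np.argmax(exit_candidate, axis=0)
        block = np.full(inside.shape[1], np.nan)
        block[entered] = ds[exit_idx[entered]] / 2.0
        radius[sl] = block

    # fallback: distance transform at the nearest interior voxel
    need = ~np.isfinite(radius)
    if need.any():
        idx = np.rint((mesh.vertices[need] - mask.origin) / mask.spacing).astype(int)
        shape = np.array(mask.data.shape)
        ok = np.all((idx >= 0) & (idx < shape), axis=1)
        vals = np.full(need.sum(), np.nan)
        ii = idx[ok]
        v_edt = edt[ii[:, 0], ii[:, 1], ii[:, 2]]
        vals[ok] = np.where(v_edt > 0, v_edt, np.nan)
        radius[need] = vals

    return mesh.copy_with(
        inward_normal=normals,
        vertex_area=mesh.vertex_area if mesh.vertex_area is not None else _vertex_areas(mesh.vertices, mesh.faces),
        local_radius=radius,
    )


@dataclass
class RegionLabels:
    """Anatomic region labels on both the voxel grid and the mesh vertices.

    Codes: 0 other, 1 innerAAo, 2 outerAAo, 3 pDAo (see REGION_CODES).
    """

    voxel_label: np.ndarray
    vertex_label: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.full(3, 2.5))

    def voxel_region(self, name: str) -> np.ndarray:
        if name == "AAo":
            return (self.voxel_label == 1) | (self.voxel_label == 2)
        return self.voxel_label == REGION_CODES[name]

    def vertex_region(self, name: str) -> np.ndarray:
        if name == "AAo":
            return (self.vertex_label == 1) | (self.vertex_label == 2)
        return self.vertex_label == REGION_CODES[name]


def _between(points: np.ndarray, plane_a, plane_b) -> np.ndarray:
    """Half-open slab: on/past plane_a (inclusive), before plane_b (exclusive)."""
    pa, na = (np.asarray(q, dtype=float) for q in plane_a)
    pb, nb = (np.asarray(q, dtype=float) for q in plane_b)
    return ((points - pa) @ na >= 0) & ((points - pb) @ nb < 0)


def subdivide_regions(mask: SegMask, mesh: WallMesh, landmarks: dict) -> RegionLabels:
    """Label voxels and vertices as innerAAo / outerAAo / pDAo / other.

    The ascending aorta is the slab between ``stj_plane`` and ``bct_plane``
    (each a (point, normal) pair, normal pointing distally), split into
    inner/outer halves by the half-space of ``inner_outer_axis`` through the
    centroid of the ascending voxels; the proximal descending aorta is the
    slab between ``lsa_plane`` and ``pa_plane``.
    """
    vox_pts = mask.world_points()
    vert_pts = mesh.vertices

    def classify(points):
        lab = np.zeros(len(points), dtype=int)
        aao = _between(points, landmarks["stj_plane"], landmarks["bct_plane"])
        pdao = _between(points, landmarks["lsa_plane"], landmarks["pa_plane"]) & ~aao
        lab[pdao] = REGION_CODES["pDAo"]
        return lab, aao

    vox_lab, vox_aao = classify(vox_pts)
    if not vox_aao.any():
        raise ValueError("ascending-aorta planes (stj_plane/bct_plane) select zero voxels")
    if not (vox_lab == REGION_CODES["pDAo"]).any():
        raise ValueError("descending-aorta planes (lsa_plane/pa_plane) select zero voxels")

    axis = np.asarray(landmarks["inner_outer_axis"], dtype=float)
    axis = axis / np.linalg.norm(axis)
    centroid = vox_pts[vox_aao].mean(axis=0)

    def split(points, lab, aao):
        inner = (points - centroid) @ axis >= 0
        lab[aao & inner] = REGION_CODES["innerAAo"]
        lab[aao & ~inner] = REGION_CODES["outerAAo"]
        return lab

    vox_lab = split(vox_pts, vox_lab, vox_aao)
    vert_lab, vert_aao = classify(vert_pts)
    vert_lab = split(vert_pts, vert_lab, vert_aao)

    full = np.full(mask.data.shape, -1, dtype=int)  # -1 = outside the lumen
    full[mask.data] = vox_lab
    return RegionLabels(full, vert_lab, spacing=mask.spacing)


def quantify_volume(flagged: np.ndarray, spacing) -> float:
    """Volume in cm^3 of flagged voxels: count x voxel volume / 1000."""
    s = np.broadcast_to(np.asarray(spacing, dtype=float), (3,))
    n = int(np.asarray(flagged).sum())
    return n * float(np.prod(s)) / 1000.0


def quantify_surface(flagged_vertices: np.ndarray, mesh: WallMesh) -> float:
    """Surface in cm^2 covered by flagged vertices (one-third-area weights)."""
    if mesh.vertex_area is None:
        raise ValueError("mesh has no vertex areas; run extract_surface first")
    flags = np.asarray(flagged_vertices)
    if flags.dtype != bool:
        idx = flags
        flags = np.zeros(mesh.n_vertices, dtype=bool)
        flags[idx] = True
    return float(mesh.vertex_area[flags].sum()) / 100.0
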