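"""Cohort-averaged normal vector maps and subject registration.

The atlas is built by (1) rigid co-registration of the cohort's lumen masks
to the member with median volume and majority-overlap voting to obtain a
shared geometry, (2) affine registration of each subject to the shared
geometry, (3) transport of velocity/WSS vectors by only the rotational part
of the affine (so vector magnitudes are untouched by scaling), and
(4) nearest-neighbour interpolation to the shared geometry followed by
componentwise averaging.

Registration is intensity-based on signed distance maps of the binary
masks (correlation metric, multi-resolution, dense sampling — fully
deterministic), via SimpleITK.

The rotational part of an affine with linear part L is extracted either by
polar decomposition (default; always a true rotation) or by dividing L by
the isotropic scale factor s = det(L)^(1/3) (``paper_literal`` mode, exact
for similarities only).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import SimpleITK as sitk
from scipy.linalg import polar
from scipy.spatial import cKDTree

from .fields import SegMask, VoxelVectorMap
from .geometry import WallMesh

__all__ = [
    "AffineTransform",
    "AtlasMap",
    "register_affine",
    "rotation_component",
    "transform_vectors",
    "transform_mesh",
    "build_shared_geometry",
    "average_cohort",
    "atlas_to_subject",
    "resample_mask",
    "resample_vertex_vectors",
]

log = logging.getLogger(__name__)


@dataclass
class AffineTransform:
    """Homogeneous 4x4 affine mapping moving -> fixed world coordinates (mm)."""

    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise ValueError("affine matrix must be 4x4")
        if not np.allclose(self.matrix[3], [0, 0, 0, 1], atol=1e-10):
            raise ValueError("last row of a homogeneous affine must be (0, 0, 0, 1)")
        if np.linalg.det(self.linear) <= 0:
            raise ValueError("affine has non-positive determinant (reflections unsupported)")

    @property
    def linear(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    @property
    def scaling(self) -> float:
        return float(np.linalg.det(self.linear) ** (1.0 / 3.0))

    @property
    def rotation(self) -> np.ndarray:
        return rotation_component(self)[0]

    def apply_points(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.linear.T + self.translation

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix))

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(4))


def rotation_component(transform: AffineTransform, mode: str = "polar"):
    """Rotation matrix R and isotropic scale s of an affine's linear part.

    ``polar`` (default): R is the orthogonal factor of the polar
    decomposition L = R P — a true rotation for any positive-determinant L.
    ``paper_literal``: R = L / s with s = det(L)^(1/3); exact when L is a
    similarity, non-orthogonal otherwise. Both return s = det(L)^(1/3).
    """
    L = transform.linear
    det = np.linalg.det(L)
    if det <= 0:
        raise ValueError("det(L) must be > 0 to extract a rotation")
    s = det ** (1.0 / 3.0)
    if mode == "paper_literal":
        R = L / s
    elif mode == "polar":
        R, _ = polar(L)
    else:
        raise ValueError(f"unknown mode {mode!r}; use 'polar' or 'paper_literal'")
    return R, s


# ---------------------------------------------------------------------------
# SimpleITK bridge


def _mask_to_distance_image(mask: SegMask) -> sitk.Image:
    img = sitk.GetImageFromArray(mask.data.astype(np.uint8).transpose(2, 1, 0))
    img.SetSpacing(tuple(float(s) for s in mask.spacing))
    img.SetOrigin(tuple(float(o) for o in mask.origin))
    dist = sitk.SignedMaurerDistanceMap(
        img, insideIsPositive=False, squaredDistance=False, useImageSpacing=True
    )
    return dist


def _sitk_to_matrix(tx) -> np.ndarray:
    """4x4 world map of a sitk transform (which maps fixed -> moving points)."""
    M = np.array(tx.GetMatrix()).reshape(3, 3)
    c = np.array(tx.GetCenter())
    t = np.array(tx.GetTranslation())
    A = np.eye(4)
    A[:3, :3] = M
    A[:3, 3] = t + c - M @ c
    return A


def register_affine(
    moving: SegMask,
    fixed: SegMask,
    transform_type: str = "affine",
) -> AffineTransform:
    """Mask-overlap registration; returns the moving -> fixed world affine.

    Deterministic: dense metric sampling on signed distance maps with a
    three-level multi-resolution schedule. Falls back to the identity (with
    a warning) if optimization fails to improve the initial alignment.
    """
    if moving.n_voxels == 0 or fixed.n_voxels == 0:
        raise ValueError("cannot register empty masks")
    f_img = _mask_to_distance_image(fixed)
    m_img = _mask_to_distance_image(moving)

    if transform_type == "rigid":
        init_tx = sitk.Euler3DTransform()
    elif transform_type == "affine":
        init_tx = sitk.AffineTransform(3)
    else:
        raise ValueError(f"unknown transform_type {transform_type!r}")
    initial = sitk.CenteredTransformInitializer(
        f_img, m_img, init_tx, sitk.CenteredTransformInitializerFilter.MOMENTS
    )

    reg = sitk.ImageRegistrationMethod()
    # correlation (not mean squares): distance-map values scale with the
    # object under scaling transforms, and correlation is invariant to that
    reg.SetMetricAsCorrelation()
    reg.SetMetricSamplingStrategy(reg.NONE)  # dense -> deterministic
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0,
        minStep=1e-4,
        numberOfIterations=300,
        relaxationFactor=0.6,
        gradientMagnitudeTolerance=1e-6,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel([4, 2, 1])
    reg.SetSmoothingSigmasPerLevel([2.0, 1.0, 0.0])
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOn()
    reg.SetInitialTransform(initial, inPlace=False)

    try:
        final = reg.Execute(f_img, m_img)
    except RuntimeError as err:  # optimizer failure
        warnings.warn(f"registration failed ({err}); returning identity", stacklevel=2)
        return AffineTransform.identity()

    # sitk transform maps fixed -> moving; our convention is moving -> fixed
    final = sitk.CompositeTransform(final).GetBackTransform() if isinstance(
        final, sitk.CompositeTransform
    ) else final
    try:
        fixed_to_moving = _sitk_to_matrix(final)
    except AttributeError:
        fixed_to_moving = _sitk_to_matrix(sitk.AffineTransform(final))
    result = AffineTransform(np.linalg.inv(fixed_to_moving))

    # sanity: did registration improve overlap?
    before = _dice(moving, fixed, AffineTransform.identity())
    after = _dice(moving, fixed, result)
    if after + 1e-6 < before:
        warnings.warn(
            f"registration degraded mask overlap (Dice {before:.3f} -> {after:.3f}); "
            "returning identity",
            stacklevel=2,
        )
        return AffineTransform.identity()
    log.info("register_affine(%s): Dice %.3f -> %.3f", transform_type, before, after)
    return result


def resample_mask(mask: SegMask, transform: AffineTransform, reference: SegMask) -> SegMask:
    """Nearest-neighbour resampling of ``mask`` through moving->fixed ``transform``
    onto the grid of ``reference``."""
    inv = transform.inverse()
    ref_pts = _grid_points(reference)
    src = inv.apply_points(ref_pts)
    idx = np.rint((src - mask.origin) / mask.spacing).astype(int)
    shape = np.array(mask.data.shape)
    ok = np.all((idx >= 0) & (idx < shape), axis=1)
    out = np.zeros(len(ref_pts), dtype=bool)
    ii = idx[ok]
    out[ok] = mask.data[ii[:, 0], ii[:, 1], ii[:, 2]]
    return SegMask(out.reshape(reference.data.shape), reference.spacing, reference.origin)


def _grid_points(mask: SegMask) -> np.ndarray:
    idx = np.indices(mask.data.shape).reshape(3, -1).T
    return mask.origin + idx * mask.spacing


def _dice(moving: SegMask, fixed: SegMask, transform: AffineTransform) -> float:
    warped = resample_mask(moving, transform, fixed)
    inter = np.logical_and(warped.data, fixed.data).sum()
    denom = warped.data.sum() + fixed.data.sum()
    return 2.0 * inter / denom if denom else 0.0


def build_shared_geometry(masks: Sequence[SegMask], min_coverage: Optional[int] = None):
    """Shared lumen geometry of a cohort by rigid co-registration + voting.

    The reference is the member with median lumen volume; every other mask
    is rigidly registered to it and resampled onto its grid; the shared mask
    is the largest connected component of the voxels covered by at least
    ``min_coverage`` (default: majority, ceil(N/2)) of the registered masks.
    Returns (shared SegMask, list of rigid AffineTransforms subject->shared).
    """
    if len(masks) < 2:
        raise ValueError("shared geometry needs at least 2 masks")
    vols = [m.n_voxels * m.voxel_volume_mm3 for m in masks]
    ref_i = int(np.argsort(vols)[len(vols) // 2])
    ref = masks[ref_i]

    transforms, counts = [], np.zeros(ref.data.shape, dtype=int)
    for i, m in enumerate(masks):
        tx = AffineTransform.identity() if i == ref_i else register_affine(m, ref, "rigid")
        transforms.append(tx)
        counts += resample_mask(m, tx, ref).data

    # majority = more than half the cohort (for N=2 that is both members)
    need = max(int(np.ceil(len(masks) / 2)), 2) if min_coverage is None else min_coverage
    shared = counts >= need
    if not shared.any():
        raise ValueError("shared mask is empty — cohort masks too heterogeneous to overlap")
    shared_mask = SegMask(shared, ref.spacing, ref.origin).largest_component()
    return shared_mask, transforms


def transform_vectors(
    vmap: VoxelVectorMap,
    transform: AffineTransform,
    reference: SegMask,
    rotation_mode: str = "polar",
) -> VoxelVectorMap:
    """Carry a voxel vector map through an affine: locations by the full
    affine, vectors by its rotational part only (norms preserved).

    The result lives on the ``reference`` grid; each reference voxel takes
    the nearest-neighbour sample of the source map (support transported the
    same way)."""
    R, _ = rotation_component(transform, rotation_mode)
    inv = transform.inverse()
    ref_pts = _grid_points(reference)
    src = inv.apply_points(ref_pts)
    idx = np.rint((src - vmap.origin) / vmap.spacing).astype(int)
    shape = np.array(vmap.support.shape)
    ok = np.all((idx >= 0) & (idx < shape), axis=1)
    ii = idx[ok]
    sup_flat = np.zeros(len(ref_pts), dtype=bool)
    sup_flat[ok] = vmap.support[ii[:, 0], ii[:, 1], ii[:, 2]]
    data_flat = np.zeros((len(ref_pts), 3))
    data_flat[ok] = vmap.data[ii[:, 0], ii[:, 1], ii[:, 2]]
    data_flat = data_flat @ R.T
    data_flat[~sup_flat] = 0.0
    return VoxelVectorMap(
        data_flat.reshape(reference.data.shape + (3,)),
        sup_flat.reshape(reference.data.shape),
        reference.spacing,
        reference.origin,
        venc=vmap.venc,
    )


def transform_mesh(
    mesh: WallMesh, vectors: np.ndarray, transform: AffineTransform, rotation_mode: str = "polar"
):
    """Move mesh vertices by the full affine; rotate attached vectors only."""
    R, _ = rotation_component(transform, rotation_mode)
    new_mesh = WallMesh(transform.apply_points(mesh.vertices), mesh.faces)
    return new_mesh, np.asarray(vectors, dtype=float) @ R.T


def resample_vertex_vectors(
    src_vertices: np.ndarray,
    src_vectors: np.ndarray,
    dst_vertices: np.ndarray,
    max_dist: float,
) -> np.ndarray:
    """Nearest-neighbour vector lookup between vertex sets; NaN beyond
    ``max_dist`` (mm)."""
    finite = np.all(np.isfinite(src_vectors), axis=1)
    out = np.full((len(dst_vertices), 3), np.nan)
    if not finite.any():
        return out
    tree = cKDTree(src_vertices[finite])
    d, j = tree.query(dst_vertices, distance_upper_bound=max_dist)
    ok = np.isfinite(d)
    out[ok] = src_vectors[finite][j[ok]]
    return out


@dataclass
class AtlasMap:
    """Cohort-averaged normal velocity and WSS vectors on a shared geometry."""

    shared_mask: SegMask
    shared_mesh: Optional[WallMesh]
    mean_velocity: VoxelVectorMap  # cm/s; support where n_contrib >= 1
    n_contrib: np.ndarray  # per-voxel contributor count
    mean_wss: Optional[np.ndarray] = None  # (nv, 3) Pa; NaN = no contributor
    n_contrib_wss: Optional[np.ndarray] = None


def average_cohort(
    registered_maps: Sequence[VoxelVectorMap],
    shared_mask: SegMask,
    registered_wss: Optional[Sequence[np.ndarray]] = None,
    shared_mesh: Optional[WallMesh] = None,
) -> AtlasMap:
    """Componentwise mean of registered maps on the shared geometry.

    Each map must already live on the shared grid (see transform_vectors);
    a subject contributes at a voxel where its transported support covers
    it. Locations with zero contributors are excluded from the atlas.
    """
    if len(registered_maps) < 2:
        raise ValueError("cohort averaging needs at least 2 maps")
    shape = shared_mask.data.shape
    total = np.zeros(shape + (3,))
    n = np.zeros(shape, dtype=int)
    for m in registered_maps:
        if m.support.shape != shape:
            raise ValueError("registered map grid does not match the shared mask")
        total += np.where(m.support[..., None], m.data, 0.0)
        n += m.support
    defined = (n >= 1) & shared_mask.data
    mean = np.zeros_like(total)
    mean[defined] = total[defined] / n[defined][:, None]

    mean_vel = VoxelVectorMap(
        mean, defined, shared_mask.spacing, shared_mask.origin, venc=registered_maps[0].venc
    )

    mean_wss = n_wss = None
    if registered_wss is not None:
        stack = np.stack(registered_wss)  # (N, nv, 3)
        finite = np.all(np.isfinite(stack), axis=2)
        n_wss = finite.sum(axis=0)
        mean_wss = np.full(stack.shape[1:], np.nan)
        anyc = n_wss >= 1
        mean_wss[anyc] = np.nansum(np.where(finite[..., None], stack, 0.0), axis=0)[anyc] / n_wss[
            anyc
        ][:, None]
    return AtlasMap(
        shared_mask=shared_mask,
        shared_mesh=shared_mesh,
        mean_velocity=mean_vel,
        n_contrib=n,
        mean_wss=mean_wss,
        n_contrib_wss=n_wss,
    )


def atlas_to_subject(
    atlas: AtlasMap,
    subject_mask: SegMask,
    subject_mesh: Optional[WallMesh] = None,
    transform: Optional[AffineTransform] = None,
    min_coverage: float = 0.8,
):
    """Map the atlas onto a subject's geometry (the reference vectors u).

    The shared geometry is affinely registered to the subject (unless a
    transform shared->subject is supplied); atlas vectors are transported
    with rotation only and nearest-neighbour interpolated onto the subject
    grid/mesh. Returns (u_voxel: VoxelVectorMap, u_wss: (nv,3) or None,
    coverage: fraction of subject lumen voxels with a defined reference).
    """
    if transform is None:
        transform = register_affine(atlas.shared_mask, subject_mask, "affine")
    u_vox = transform_vectors(atlas.mean_velocity, transform, subject_mask)
    covered = u_vox.support & subject_mask.data
    u_vox = VoxelVectorMap(
        u_vox.data, covered, subject_mask.spacing, subject_mask.origin, venc=u_vox.venc
    )
    coverage = covered.sum() / max(subject_mask.n_voxels, 1)
    if coverage < min_coverage:
        warnings.warn(
            f"atlas covers only {coverage:.1%} of the subject lumen (< {min_coverage:.0%})",
            stacklevel=2,
        )

    u_wss = None
    if subject_mesh is not None and atlas.mean_wss is not None and atlas.shared_mesh is not None:
        warped_mesh, warped_wss = transform_mesh(atlas.shared_mesh, atlas.mean_wss, transform)
        u_wss = resample_vertex_vectors(
            warped_mesh.vertices, warped_wss, subject_mesh.vertices,
            max_dist=float(max(subject_mask.spacing)),
        )
    return u_vox, u_wss, float(coverage)
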