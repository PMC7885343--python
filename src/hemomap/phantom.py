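"""Synthetic aortic 4D-flow phantoms.

The phantom emulates the geometry and flow structure the pipeline assumes:
a U-shaped lumen (half-torus arch joined to a straight descending limb)
carrying Poiseuille-like axial flow, with optional azimuthal swirl, an
optional reversed-flow patch of known analytic volume, a single-peaked
systolic waveform, and additive Gaussian velocity noise. Cohorts are
generated by pushing the analytic field through random affines (vectors
rotated only), so every subject has exact, interpolation-free ground truth.

Geometry convention: the arch is the half-circle of radius ``arch_radius``
in the y=0 plane, z >= 0, traversed from (-Ra, 0, 0) up and over to
(+Ra, 0, 0); the descending limb continues straight down to
(+Ra, 0, -limb_length). "Inner curvature" is the side of the tube facing
the torus center (the origin). Flow runs ascending -> arch -> descending.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .fields import SegMask, VelocityField4D

__all__ = [
    "Centerline",
    "FlowProfileSpec",
    "ReversedPatch",
    "TubeGeometry",
    "default_waveform",
    "make_tube_subject",
    "make_cohort",
    "default_landmarks",
    "random_affine",
]

N_FRAMES_DEFAULT = 24
PEAK_FRAME_DEFAULT = 7


def default_waveform(n_frames: int = N_FRAMES_DEFAULT, peak_frame: int = PEAK_FRAME_DEFAULT) -> np.ndarray:
    """Raised-cosine systolic pulse with a unique maximum at ``peak_frame``.

    w[t] = 0.5 * (1 - cos(pi * t / peak_frame)) for t <= 2*peak_frame, 0 in
    late diastole; w[peak_frame] = 1 and no ties.
    """
    t = np.arange(n_frames, dtype=float)
    w = np.where(t <= 2 * peak_frame, 0.5 * (1.0 - np.cos(np.pi * t / peak_frame)), 0.0)
    return w


@dataclass
class Centerline:
    """Ordered polyline through the lumen with arc length and unit tangents."""

    points: np.ndarray  # (n, 3) mm
    arclen: np.ndarray  # (n,) cumulative mm, strictly increasing
    tangent: np.ndarray  # (n, 3) unit vectors

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        self.arclen = np.asarray(self.arclen, dtype=float)
        self.tangent = np.asarray(self.tangent, dtype=float)
        if len(self.points) < 2:
            raise ValueError("centerline needs at least 2 points")
        if np.any(np.diff(self.arclen) <= 0):
            raise ValueError("arc length must be strictly increasing")
        norms = np.linalg.norm(self.tangent, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("tangents must be unit-norm")

    @property
    def length(self) -> float:
        return float(self.arclen[-1] - self.arclen[0])


@dataclass
class ReversedPatch:
    """Axial-flow reversal over an arc-length window and angular sector.

    ``sector_deg`` is measured about the centerline, centered on the inner
    (torus-center-facing) side; 360 reverses the full cross-section.
    Analytic patch volume (full sector) = pi * R_lumen**2 * extent.
    """

    center_arclen: float  # mm
    extent: float  # mm along the centerline
    sector_deg: float = 360.0


@dataclass
class FlowProfileSpec:
    """Flow pattern parameters for one phantom subject."""

    v_peak: float = 100.0  # cm/s, axial peak speed
    swirl_fraction: float = 0.0  # azimuthal peak speed / axial peak speed
    reversed_patch: Optional[ReversedPatch] = None
    waveform: np.ndarray = field(default_factory=default_waveform)
    noise_sd: float = 0.0  # cm/s, per component

    def __post_init__(self):
        if self.v_peak <= 0:
            raise ValueError("v_peak must be > 0")
        if self.swirl_fraction < 0:
            raise ValueError("swirl_fraction must be >= 0")
        self.waveform = np.asarray(self.waveform, dtype=float)
        if self.waveform.ndim != 1 or len(self.waveform) < 1:
            raise ValueError("waveform needs at least 1 frame")
        if np.any(self.waveform < 0):
            raise ValueError("waveform must be non-negative")
        if np.sum(self.waveform == self.waveform.max()) != 1:
            raise ValueError("waveform must attain its maximum at exactly one frame")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def peak_frame(self) -> int:
        return int(np.argmax(self.waveform))


class TubeGeometry:
    """Closed-form U-tube geometry: half-torus arch + straight descending limb.

    Provides, for arbitrary world points, the perpendicular distance to the
    centerline, the arc-length coordinate, the local unit tangent, and the
    angular coordinate psi about the centerline (psi = 0 on the inner,
    torus-center-facing side). Points whose nearest centerline point is an
    endpoint clamp are treated as outside (flat tube ends, so the lumen
    volume is exactly pi R^2 (pi Ra + L)).
    """

    def __init__(self, arch_radius: float, lumen_radius: float, limb_length: float = 100.0):
        if arch_radius <= 2 * lumen_radius:
            raise ValueError(
                f"arch_radius must exceed 2 x lumen_radius: got arch_radius={arch_radius}, "
                f"lumen_radius={lumen_radius}"
            )
        self.arch_radius = float(arch_radius)
        self.lumen_radius = float(lumen_radius)
        self.limb_length = float(limb_length)
        self.arch_length = math.pi * self.arch_radius

    @property
    def total_length(self) -> float:
        return self.arch_length + self.limb_length

    def analytic_volume_mm3(self) -> float:
        return math.pi * self.lumen_radius**2 * self.total_length

    def frame(self, points: np.ndarray):
        """Local tube coordinates at world points, vectorized.

        Returns dict with ``r`` (perpendicular distance to centerline, mm;
        inf where off the tube's parametric range), ``s`` (arc length, mm),
        ``tangent`` (n,3), ``radial`` (n,3 unit, centerline -> point) and
        ``psi`` (deg in [-180, 180], 0 = inner side).
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        n = len(pts)
        Ra = self.arch_radius
        x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]

        # --- arch candidate: circle of radius Ra in the y=0 plane, z >= 0
        rho = np.hypot(x, z)
        safe_rho = np.where(rho > 1e-12, rho, 1.0)
        phi = np.arctan2(z, -x)  # param: p(phi) = (-Ra cos phi, 0, Ra sin phi)
        arch_ok = (phi >= 0.0) & (phi <= np.pi) & (rho > 1e-12)
        near = np.empty_like(pts)
        near[:, 0] = Ra * x / safe_rho
        near[:, 1] = 0.0
        near[:, 2] = Ra * z / safe_rho
        d_arch = np.where(arch_ok, np.sqrt((rho - Ra) ** 2 + y**2), np.inf)

        # --- descending limb candidate: segment x=Ra, y=0, z in [-L, 0]
        u = -z  # distance down the limb
        limb_ok = (u >= 0.0) & (u <= self.limb_length)
        d_limb = np.where(limb_ok, np.hypot(x - Ra, y), np.inf)

        use_arch = d_arch <= d_limb
        r = np.where(use_arch, d_arch, d_limb)
        s = np.where(use_arch, Ra * phi, self.arch_length + u)

        tangent = np.empty((n, 3))
        radial = np.empty((n, 3))
        # arch tangent: dp/ds = (sin phi, 0, cos phi)
        tangent[:, 0] = np.where(use_arch, np.sin(phi), 0.0)
        tangent[:, 1] = 0.0
        tangent[:, 2] = np.where(use_arch, np.cos(phi), -1.0)

        nearest = np.where(use_arch[:, None], near, np.column_stack([np.full(n, Ra), np.zeros(n), z]))
        nearest[~use_arch, 2] = np.clip(z[~use_arch], -self.limb_length, 0.0)
        dvec = pts - nearest
        dnorm = np.linalg.norm(dvec, axis=1)
        on_axis = dnorm < 1e-12
        radial = np.where(on_axis[:, None], 0.0, dvec / np.where(on_axis, 1.0, dnorm)[:, None])

        # inner reference direction: toward the torus center (the z-axis line
        # through the origin for the arch; (-1, 0, 0) on the limb)
        inner = np.empty((n, 3))
        inner[:, 0] = np.where(use_arch, -near[:, 0] / Ra, -1.0)
        inner[:, 1] = 0.0
        inner[:, 2] = np.where(use_arch, -near[:, 2] / Ra, 0.0)

        cos_psi = np.clip(np.einsum("ij,ij->i", radial, inner), -1.0, 1.0)
        cross = np.cross(inner, radial)
        sign = np.sign(np.einsum("ij,ij->i", tangent, cross))
        psi = np.degrees(np.arccos(cos_psi)) * np.where(sign == 0, 1.0, sign)
        psi[on_axis] = 0.0
        return {"r": r, "s": s, "tangent": tangent, "radial": radial, "psi": psi}

    def centerline(self, step: float = 1.0) -> Centerline:
        Ra = self.arch_radius
        s_arch = np.arange(0.0, self.arch_length, step)
        phi = s_arch / Ra
        p_arch = np.column_stack([-Ra * np.cos(phi), np.zeros_like(phi), Ra * np.sin(phi)])
        t_arch = np.column_stack([np.sin(phi), np.zeros_like(phi), np.cos(phi)])
        u = np.arange(0.0, self.limb_length + 0.5 * step, step)
        p_limb = np.column_stack([np.full_like(u, Ra), np.zeros_like(u), -u])
        t_limb = np.tile([0.0, 0.0, -1.0], (len(u), 1))
        points = np.vstack([p_arch, p_limb])
        tangent = np.vstack([t_arch, t_limb])
        arclen = np.concatenate([s_arch, self.arch_length + u])
        return Centerline(points, arclen, tangent)

    def centerline_point(self, s: float) -> np.ndarray:
        """World coordinates of the centerline at arc length ``s``."""
        Ra = self.arch_radius
        if s <= self.arch_length:
            phi = s / Ra
            return np.array([-Ra * math.cos(phi), 0.0, Ra * math.sin(phi)])
        return np.array([Ra, 0.0, -(s - self.arch_length)])

    def analytic_velocity(self, points: np.ndarray, profile: FlowProfileSpec) -> np.ndarray:
        """Noise-free peak-profile velocity (cm/s) at world points; 0 outside."""
        fr = self.frame(points)
        r, R = fr["r"], self.lumen_radius
        inside = r <= R
        r = np.where(inside, r, 0.0)
        axial_speed = profile.v_peak * (1.0 - (r / R) ** 2)
        sign = np.ones_like(axial_speed)
        patch = profile.reversed_patch
        if patch is not None:
            in_patch = (
                (np.abs(fr["s"] - patch.center_arclen) <= 0.5 * patch.extent)
                & (np.abs(fr["psi"]) <= 0.5 * patch.sector_deg)
            )
            sign[in_patch] = -1.0
        v = sign[:, None] * axial_speed[:, None] * fr["tangent"]
        if profile.swirl_fraction > 0:
            e_phi = np.cross(fr["tangent"], fr["radial"])
            v = v + (profile.swirl_fraction * profile.v_peak * (r / R))[:, None] * e_phi
        v[~inside] = 0.0
        return v


def _grid_for(geom: TubeGeometry, spacing: float, pad: float = 6.0):
    """Axis-aligned grid (origin, shape) covering the tube with margin."""
    Ra, R, L = geom.arch_radius, geom.lumen_radius, geom.limb_length
    lo = np.array([-Ra - R - pad, -R - pad, -L - R - pad])
    hi = np.array([Ra + R + pad, R + pad, Ra + R + pad])
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    return lo, tuple(shape)


def _voxel_centers(origin: np.ndarray, shape, spacing: float) -> np.ndarray:
    idx = np.indices(shape).reshape(3, -1).T
    return origin + idx * spacing


def make_tube_subject(
    arch_radius: float = 30.0,
    lumen_radius: float = 10.0,
    grid_spacing: float = 2.5,
    profile: Optional[FlowProfileSpec] = None,
    seed: int = 0,
    limb_length: float = 100.0,
) -> tuple[VelocityField4D, SegMask, Centerline]:
    """Generate one synthetic 4D-flow subject on a regular grid.

    The lumen mask contains the voxels whose centers lie within
    ``lumen_radius`` of the U-shaped centerline; the velocity inside is
    waveform[t] * (axial Poiseuille + swirl + reversed patch) plus Gaussian
    noise, zero outside. Deterministic for a fixed seed.
    """
    if grid_spacing <= 0:
        raise ValueError(f"grid_spacing must be > 0, got {grid_spacing}")
    if lumen_radius < 2 * grid_spacing:
        raise ValueError(
            f"lumen_radius must be >= 2 x grid_spacing: got lumen_radius={lumen_radius}, "
            f"grid_spacing={grid_spacing}"
        )
    geom = TubeGeometry(arch_radius, lumen_radius, limb_length)
    profile = profile or FlowProfileSpec()

    origin, shape = _grid_for(geom, grid_spacing)
    pts = _voxel_centers(origin, shape, grid_spacing)
    fr = geom.frame(pts)
    mask = (fr["r"] <= lumen_radius).reshape(shape)

    v_profile = geom.analytic_velocity(pts, profile).reshape(shape + (3,))
    nt = len(profile.waveform)
    data = v_profile[:, :, :, None, :] * profile.waveform[None, None, None, :, None]
    if profile.noise_sd > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, profile.noise_sd, size=data.shape)
        data = data + noise * mask[:, :, :, None, None]

    venc = max(150.0, 1.5 * profile.v_peak * (1 + profile.swirl_fraction))
    vel = VelocityField4D(data, spacing=grid_spacing, origin=origin, venc=venc)
    seg = SegMask(mask, spacing=grid_spacing, origin=origin)
    return vel, seg, geom.centerline()


def random_affine(rng: np.random.Generator, variation: dict, center: np.ndarray) -> np.ndarray:
    """Draw a 4x4 similarity within the stated bounds, acting about ``center``."""
    max_rot = math.radians(variation.get("max_rotation", 0.0))
    max_scale = variation.get("max_scale", 0.0)
    max_trans = variation.get("max_translation", 0.0)

    axis = rng.normal(size=3)
    axis /= max(np.linalg.norm(axis), 1e-12)
    angle = rng.uniform(-max_rot, max_rot)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    R = np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * (K @ K)
    s = rng.uniform(1.0 - max_scale, 1.0 + max_scale)
    t = rng.uniform(-max_trans, max_trans, size=3)

    A = np.eye(4)
    A[:3, :3] = s * R
    A[:3, 3] = center - s * R @ center + t
    return A


def make_cohort(
    n: int,
    base_spec: Optional[dict] = None,
    variation: Optional[dict] = None,
    seed: int = 0,
):
    """Generate ``n`` phantom subjects related to a base tube by random affines.

    Each subject is the base phantom carried through a random similarity
    (rotation <= max_rotation deg, isotropic scale within 1 +/- max_scale,
    translation <= max_translation mm per axis): the lumen moves with the
    full affine while velocity vectors are rotated only, so speeds are
    preserved. The analytic field is evaluated through the inverse map on
    the subject grid — no resampling error. Returns (subjects, true_affines)
    where each subject is (VelocityField4D, SegMask, Centerline) and each
    affine maps base coordinates to that subject's coordinates.
    """
    if n < 2:
        raise ValueError(f"cohort needs n >= 2 subjects (atlas averaging undefined), got {n}")
    base_spec = dict(base_spec or {})
    variation = dict(variation or {})
    rng = np.random.default_rng(seed)

    arch_radius = base_spec.get("arch_radius", 30.0)
    lumen_radius = base_spec.get("lumen_radius", 10.0)
    grid_spacing = base_spec.get("grid_spacing", 2.5)
    limb_length = base_spec.get("limb_length", 100.0)
    profile = base_spec.get("profile") or FlowProfileSpec()
    if grid_spacing <= 0:
        raise ValueError(f"grid_spacing must be > 0, got {grid_spacing}")
    if lumen_radius < 2 * grid_spacing:
        raise ValueError(
            f"lumen_radius must be >= 2 x grid_spacing: got lumen_radius={lumen_radius}, "
            f"grid_spacing={grid_spacing}"
        )
    geom = TubeGeometry(arch_radius, lumen_radius, limb_length)
    cl = geom.centerline()
    center = cl.points.mean(axis=0)

    pad = 6.0 + variation.get("max_translation", 0.0) + 0.35 * variation.get(
        "max_rotation", 0.0
    ) + variation.get("max_scale", 0.0) * (arch_radius + limb_length)
    origin, shape = _grid_for(geom, grid_spacing, pad=pad)
    pts = _voxel_centers(origin, shape, grid_spacing)

    subjects, affines = [], []
    for k in range(n):
        A = random_affine(rng, variation, center)
        Ainv = np.linalg.inv(A)
        base_pts = pts @ Ainv[:3, :3].T + Ainv[:3, 3]
        fr = geom.frame(base_pts)
        mask = (fr["r"] <= lumen_radius).reshape(shape)

        v_base = geom.analytic_velocity(base_pts, profile)
        L = A[:3, :3]
        s = np.linalg.det(L) ** (1.0 / 3.0)
        Rot = L / s
        v_subj = (v_base @ Rot.T).reshape(shape + (3,))
        data = v_subj[:, :, :, None, :] * profile.waveform[None, None, None, :, None]
        if profile.noise_sd > 0:
            sub_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
            data = data + sub_rng.normal(0.0, profile.noise_sd, size=data.shape) * mask[
                :, :, :, None, None
            ]

        venc = max(150.0, 1.5 * profile.v_peak * (1 + profile.swirl_fraction))
        vel = VelocityField4D(data, spacing=grid_spacing, origin=origin, venc=venc)
        seg = SegMask(mask, spacing=grid_spacing, origin=origin)
        cl_k = Centerline(
            cl.points @ A[:3, :3].T + A[:3, 3],
            cl.arclen * s,
            cl.tangent @ Rot.T,
        )
        subjects.append((vel, seg, cl_k))
        affines.append(A)
    return subjects, affines


# Default landmark arc positions on the phantom (deg along the arch / mm down
# the limb). The ascending-aorta window spans 30 deg of arch so that a single
# half-space split approximates the per-point inner/outer rule well.
PHI_STJ_DEG = 25.0
PHI_BCT_DEG = 55.0
PDAO_START_MM = 15.0
PDAO_END_MM = 55.0


def default_landmarks(
    geom: TubeGeometry,
    phi_stj_deg: float = PHI_STJ_DEG,
    phi_bct_deg: float = PHI_BCT_DEG,
    pdao_start_mm: float = PDAO_START_MM,
    pdao_end_mm: float = PDAO_END_MM,
) -> dict:
    """Region-dividing planes for the phantom, in world mm.

    Returns the five entries ``subdivide_regions`` expects: plane normals
    point distally (along flow); ``inner_outer_axis`` points from the
    mid-window arch point toward the torus center.
    """
    Ra = geom.arch_radius

    def arch_plane(phi_deg):
        phi = math.radians(phi_deg)
        point = np.array([-Ra * math.cos(phi), 0.0, Ra * math.sin(phi)])
        normal = np.array([math.sin(phi), 0.0, math.cos(phi)])
        return point, normal

    s_arch = geom.arch_length
    stj = arch_plane(phi_stj_deg)
    bct = arch_plane(phi_bct_deg)
    lsa = (geom.centerline_point(s_arch + pdao_start_mm), np.array([0.0, 0.0, -1.0]))
    pa = (geom.centerline_point(s_arch + pdao_end_mm), np.array([0.0, 0.0, -1.0]))

    phi_mid = math.radians(0.5 * (phi_stj_deg + phi_bct_deg))
    mid = np.array([-Ra * math.cos(phi_mid), 0.0, Ra * math.sin(phi_mid)])
    axis = -mid / np.linalg.norm(mid)  # toward the torus center
    return {
        "stj_plane": stj,
        "bct_plane": bct,
        "lsa_plane": lsa,
        "pa_plane": pa,
        "inner_outer_axis": axis,
    }
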