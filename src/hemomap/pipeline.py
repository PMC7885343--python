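"""End-to-end orchestration: subject analysis and atlas construction.

``analyze_subject`` / ``build_atlas`` operate on in-memory objects (the
library-facing API the tests and examples use); ``run_subject`` /
``run_atlas`` add file I/O, logging and provenance around them for the CLI.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .atlas import (
    AtlasMap,
    atlas_to_subject,
    average_cohort,
    build_shared_geometry,
    register_affine,
    resample_vertex_vectors,
    transform_mesh,
    transform_vectors,
)
from .deviation import DeviationMap, map_deviation, quantify_regional
from .fields import SegMask, VelocityField4D, VoxelVectorMap
from .geometry import (
    RegionLabels,
    WallMesh,
    compute_inward_normals_and_radius,
    extract_surface,
    smooth_laplacian,
    subdivide_regions,
)
from .helivort import (
    LNH_THRESHOLD_DEFAULT,
    compute_lnh,
    compute_vorticity,
    quantify_lnh_volume,
    quantify_vorticity,
)
from .preprocess import correct_background_phase, extract_peak_vectors, find_peak_systole
from .wss import DEFAULT_VISCOSITY_PA_S, WSSMap, compute_wss

__all__ = ["RunConfig", "SubjectReport", "analyze_subject", "build_atlas", "run_subject", "run_atlas"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Analysis settings; defaults are the method's published values."""

    venc: float = 150.0  # cm/s
    viscosity: float = DEFAULT_VISCOSITY_PA_S  # 3.2 cP
    theta_low: float = 60.0  # deg
    theta_high: float = 120.0  # deg
    lnh_threshold: float = LNH_THRESHOLD_DEFAULT  # |LNH| cut
    smooth_lambda: float = 0.5
    smooth_iterations: int = 10
    use_smoothed_mesh: bool = True
    background_correction: bool = True
    seed: int = 0
    paths: dict = dc_field(default_factory=dict)  # velocity/magnitude/mask/landmarks/atlas/output

    def __post_init__(self):
        if not (0 < self.theta_low < self.theta_high < 180):
            raise ValueError("deviation thresholds must satisfy 0 < low < high < 180")
        if self.viscosity <= 0:
            raise ValueError("viscosity must be positive")


@dataclass
class SubjectReport:
    """Everything the per-subject pipeline computes."""

    peak_frame: int
    peak_vectors: VoxelVectorMap
    mesh: WallMesh
    wss: WSSMap
    dev_velocity: DeviationMap
    dev_wss: Optional[DeviationMap]
    regions: RegionLabels
    regional: pd.DataFrame
    lnh_volume_cm3: dict
    mean_abs_vorticity: dict
    atlas_coverage: float
    provenance: dict


def _stage(name):
    log.info("stage: %s", name)
    return time.perf_counter()


def subject_surface(mask: SegMask, config: RunConfig) -> WallMesh:
    """Mesh the lumen: isosurface, optional Laplacian smoothing, normals,
    local radius."""
    mesh = extract_surface(mask.largest_component())
    if config.use_smoothed_mesh and config.smooth_iterations > 0:
        mesh = smooth_laplacian(mesh, config.smooth_iterations, config.smooth_lambda)
    return compute_inward_normals_and_radius(mesh, mask)


def subject_peak_map(
    vel: VelocityField4D, mask: SegMask, config: RunConfig
) -> tuple[VoxelVectorMap, int]:
    if config.background_correction:
        vel, _ = correct_background_phase(vel)
    frame = find_peak_systole(vel, mask)
    return extract_peak_vectors(vel, mask, frame), frame


def analyze_subject(
    vel: VelocityField4D,
    mask: SegMask,
    landmarks: dict,
    atlas: Optional[AtlasMap],
    config: Optional[RunConfig] = None,
) -> SubjectReport:
    """Full per-subject analysis: preprocess -> mesh -> WSS -> atlas
    comparison -> regional quantification -> LNH/vorticity."""
    config = config or RunConfig()
    t0 = _stage("preprocess")
    peak_map, frame = subject_peak_map(vel, mask, config)
    t1 = _stage("geometry")
    mesh = subject_surface(mask, config)
    t2 = _stage("wss")
    wss = compute_wss(peak_map, mesh, viscosity=config.viscosity)
    t3 = _stage("atlas mapping")
    if atlas is not None:
        u_vox, u_wss, coverage = atlas_to_subject(atlas, mask, mesh)
        dev_vel = map_deviation(peak_map, u_vox)
        dev_wss = map_deviation(wss.vectors, u_wss) if u_wss is not None else None
    else:
        u_vox = u_wss = None
        coverage = float("nan")
        nan_theta = np.full(mask.data.shape, np.nan)
        dev_vel = DeviationMap(nan_theta, np.full(mask.data.shape, 3, int), "voxel", mask.data)
        dev_wss = None
    t4 = _stage("regions + quantification")
    regions = subdivide_regions(mask, mesh, landmarks)
    regional = quantify_regional(dev_vel, dev_wss, regions, mask.spacing, mesh)
    t5 = _stage("helicity/vorticity")
    vort = compute_vorticity(peak_map)
    lnh = compute_lnh(peak_map, vort)
    lnh_vol = quantify_lnh_volume(lnh, regions, mask.spacing, config.lnh_threshold)
    vort_q = quantify_vorticity(vort, regions)
    log.info(
        "timings (s): preprocess %.2f, geometry %.2f, wss %.2f, atlas %.2f, regions %.2f",
        t1 - t0, t2 - t1, t3 - t2, t4 - t3, t5 - t4,
    )
    provenance = {
        "hemomap_version": __version__,
        "peak_frame": frame,
        "mask_volume_cm3": mask.volume_cm3(),
        "atlas_coverage": coverage,
        "settings": {
            "viscosity_pa_s": config.viscosity,
            "theta_low_deg": config.theta_low,
            "theta_high_deg": config.theta_high,
            "lnh_threshold": config.lnh_threshold,
            "smooth_lambda": config.smooth_lambda,
            "smooth_iterations": config.smooth_iterations,
            "seed": config.seed,
        },
    }
    return SubjectReport(
        peak_frame=frame,
        peak_vectors=peak_map,
        mesh=mesh,
        wss=wss,
        dev_velocity=dev_vel,
        dev_wss=dev_wss,
        regions=regions,
        regional=regional,
        lnh_volume_cm3=lnh_vol,
        mean_abs_vorticity=vort_q,
        atlas_coverage=coverage,
        provenance=provenance,
    )


def build_atlas(
    subjects: Sequence[tuple[VelocityField4D, SegMask]],
    config: Optional[RunConfig] = None,
) -> AtlasMap:
    """Cohort-averaged normal velocity and WSS atlas from >= 2 subjects."""
    if len(subjects) < 2:
        raise ValueError("atlas construction needs at least 2 subjects")
    config = config or RunConfig()
    spacings = np.array([s[1].spacing for s in subjects])
    if spacings.max() > 2.0 * spacings.min():
        raise ValueError("cohort voxel spacings differ by more than 2x; resample first")

    peak_maps, meshes, wss_maps = [], [], []
    for vel, mask in subjects:
        pm, _ = subject_peak_map(vel, mask, config)
        mesh = subject_surface(mask, config)
        peak_maps.append(pm)
        meshes.append(mesh)
        wss_maps.append(compute_wss(pm, mesh, viscosity=config.viscosity))

    masks = [s[1] for s in subjects]
    shared_mask, _ = build_shared_geometry(masks)
    shared_mesh = subject_surface(shared_mask, config)

    reg_maps, reg_wss = [], []
    for pm, mesh, wmap, mask in zip(peak_maps, meshes, wss_maps, masks):
        tx = register_affine(mask, shared_mask, "affine")
        reg_maps.append(transform_vectors(pm, tx, shared_mask))
        warped_mesh, warped_vecs = transform_mesh(mesh, wmap.vectors, tx)
        reg_wss.append(
            resample_vertex_vectors(
                warped_mesh.vertices, warped_vecs, shared_mesh.vertices,
                max_dist=float(max(shared_mask.spacing)),
            )
        )
    return average_cohort(reg_maps, shared_mask, registered_wss=reg_wss, shared_mesh=shared_mesh)


# ---------------------------------------------------------------------------
# File-level drivers (CLI backend)


def _load_subject(paths: dict):
    from .io import load_mask, load_velocity

    for key in ("velocity", "mask"):
        if key not in paths:
            raise FileNotFoundError(f"config is missing required input path: '{key}'")
    vel = load_velocity(paths["velocity"], venc=paths.get("venc", 150.0))
    mask = load_mask(paths["mask"])
    return vel, mask


def _landmarks_from(obj) -> dict:
    lm = dict(obj)
    out = {}
    for k in ("stj_plane", "bct_plane", "lsa_plane", "pa_plane"):
        p, n = lm[k]
        out[k] = (np.asarray(p, float), np.asarray(n, float))
    out["inner_outer_axis"] = np.asarray(lm["inner_outer_axis"], float)
    return out


def run_subject(config: RunConfig, atlas: Optional[AtlasMap]) -> SubjectReport:
    """Load a subject from config paths, analyze it, write all outputs."""
    from .io import save_json, save_nifti, write_vtk_polydata

    vel, mask = _load_subject(config.paths)
    landmarks = _landmarks_from(config.paths["landmarks"])
    report = analyze_subject(vel, mask, landmarks, atlas, config)

    outdir = Path(config.paths.get("output", "hemomap_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    save_nifti(np.nan_to_num(report.dev_velocity.theta, nan=-1.0), mask.spacing, mask.origin, outdir / "theta_velocity.nii.gz")
    save_nifti(report.dev_velocity.category.astype(np.int16), mask.spacing, mask.origin, outdir / "category_velocity.nii.gz")
    save_nifti(report.regions.voxel_label.astype(np.int16), mask.spacing, mask.origin, outdir / "regions.nii.gz")
    point_data = {"wss": report.wss.vectors, "wss_magnitude": report.wss.magnitudes()}
    if report.dev_wss is not None:
        point_data["theta_wss"] = report.dev_wss.theta
        point_data["category_wss"] = report.dev_wss.category.astype(float)
    write_vtk_polydata(outdir / "wall.vtk", report.mesh.vertices, report.mesh.faces, point_data)
    report.regional.to_csv(outdir / "regional_quantification.csv", index_label="region")
    summary = pd.DataFrame(
        {
            "lnh_volume_cm3": report.lnh_volume_cm3,
            "mean_abs_vorticity_1_s": report.mean_abs_vorticity,
        }
    )
    summary.to_csv(outdir / "helivort_summary.csv", index_label="region")
    save_json(report.provenance, outdir / "provenance.json")
    return report


def run_atlas(configs: Sequence[RunConfig]) -> AtlasMap:
    """Build and persist an atlas from per-subject configs."""
    from .io import save_json, save_mask, save_nifti, write_vtk_polydata

    if len(configs) < 2:
        raise ValueError("atlas construction needs at least 2 subjects")
    subjects = [_load_subject(c.paths) for c in configs]
    atlas = build_atlas(subjects, configs[0])
    outdir = Path(configs[0].paths.get("atlas_output", "atlas_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    save_mask(atlas.shared_mask, outdir / "shared_mask.nii.gz")
    save_nifti(atlas.mean_velocity.data, atlas.shared_mask.spacing, atlas.shared_mask.origin, outdir / "mean_velocity.nii.gz")
    save_nifti(atlas.n_contrib.astype(np.int16), atlas.shared_mask.spacing, atlas.shared_mask.origin, outdir / "n_contrib.nii.gz")
    if atlas.shared_mesh is not None and atlas.mean_wss is not None:
        write_vtk_polydata(outdir / "shared_wall.vtk", atlas.shared_mesh.vertices, atlas.shared_mesh.faces, {"mean_wss": atlas.mean_wss})
    save_json({"n_subjects": len(configs), "hemomap_version": __version__}, outdir / "manifest.json")
    return atlas
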