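"""Surface meshing, smoothing, normals/radius, regions, quantification."""

import math

import numpy as np
import pytest

from hemomap.fields import SegMask
from hemomap.geometry import (
    WallMesh,
    compute_inward_normals_and_radius,
    extract_surface,
    quantify_surface,
    quantify_volume,
    smooth_laplacian,
    subdivide_regions,
)
from hemomap.phantom import FlowProfileSpec, TubeGeometry, default_landmarks, make_tube_subject


class TestExtractSurface:
    def test_sphere_area_within_5pct(self, sphere_mesh):
        true = 4 * math.pi * 20.0**2
        assert sphere_mesh.total_area_mm2() == pytest.approx(true, rel=0.05)

    def test_cube_area_within_10pct(self):
        data = np.zeros((30, 30, 30), bool)
        data[5:25, 5:25, 5:25] = True
        mesh = extract_surface(SegMask(data, 1.0))
        assert mesh.total_area_mm2() == pytest.approx(2400.0, rel=0.10)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            extract_surface(SegMask(np.zeros((5, 5, 5), bool), 1.0))

    def test_watertight_and_area_partition(self, sphere_mesh):
        tm = sphere_mesh.to_trimesh()
        assert tm.is_watertight
        assert sphere_mesh.vertex_area.sum() == pytest.approx(tm.area, rel=1e-9)
        assert np.all(sphere_mesh.vertex_area > 0)


def _flat_grid_mesh(n=8):
    """Regular triangulated planar grid in the z=0 plane."""
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    verts = np.column_stack([ii.ravel() * 1.0, jj.ravel() * 1.0, np.zeros(n * n)])
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            faces += [[a, a + n, a + 1], [a + 1, a + n, a + n + 1]]
    return WallMesh(verts, np.array(faces))


class TestSmoothing:
    def test_zero_iterations_identity(self, sphere_mesh):
        out = smooth_laplacian(sphere_mesh, iterations=0, lam=0.5)
        assert np.array_equal(out.vertices, sphere_mesh.vertices)

    def test_sphere_volume_shrinks_mildly(self, sphere_mesh):
        before = sphere_mesh.enclosed_volume_mm3()
        after = smooth_laplacian(sphere_mesh, 10, 0.5).enclosed_volume_mm3()
        assert after < before
        assert (before - after) / before < 0.10

    def test_planar_interior_vertices_fixed(self):
        """A regular planar grid has symmetric 1-rings, so one smoothing
        step leaves interior vertices exactly in place; more steps keep
        every vertex in the plane."""
        mesh = _flat_grid_mesh()
        out = smooth_laplacian(mesh, 1, 0.5)
        interior = np.zeros(len(mesh.vertices), bool)
        idx = np.arange(64).reshape(8, 8)
        interior[idx[1:-1, 1:-1].ravel()] = True
        disp = np.linalg.norm(out.vertices - mesh.vertices, axis=1)
        assert disp[interior].max() < 1e-9
        many = smooth_laplacian(mesh, 10, 0.5)
        assert np.abs(many.vertices[:, 2]).max() < 1e-12

    def test_lambda_out_of_range_rejected(self, sphere_mesh):
        for lam in (0.0, 1.0, -0.5, 2.0):
            with pytest.raises(ValueError, match="lam"):
                smooth_laplacian(sphere_mesh, 1, lam)

    def test_connectivity_unchanged(self, sphere_mesh):
        out = smooth_laplacian(sphere_mesh, 3, 0.5)
        assert np.array_equal(out.faces, sphere_mesh.faces)


class TestNormalsAndRadius:
    def test_cylinder_mean_radius(self):
        shape = (26, 26, 40)
        g = np.indices(shape).astype(float)
        data = (g[0] - 12.5) ** 2 + (g[1] - 12.5) ** 2 <= 100.0
        mask = SegMask(data, 1.0)
        mesh = compute_inward_normals_and_radius(extract_surface(mask), mask)
        lateral = (mesh.vertices[:, 2] > 5) & (mesh.vertices[:, 2] < 34)
        assert np.nanmean(mesh.local_radius[lateral]) == pytest.approx(10.0, abs=1.0)

    def test_sphere_normals_point_at_center(self, sphere_mask):
        mesh = smooth_laplacian(extract_surface(sphere_mask), 10, 0.5)
        mesh = compute_inward_normals_and_radius(mesh, sphere_mask)
        to_center = -mesh.vertices / np.linalg.norm(mesh.vertices, axis=1, keepdims=True)
        ang = np.degrees(
            np.arccos(np.clip(np.einsum("ij,ij->i", mesh.inward_normal, to_center), -1, 1))
        )
        assert ang.mean() < 5.0
        assert np.percentile(ang, 99) < 10.0

    def test_flat_slab_radius_half_thickness(self):
        data = np.zeros((30, 30, 16), bool)
        data[:, :, 3:13] = True  # 10 mm slab at 1 mm spacing
        mask = SegMask(data, 1.0)
        mesh = compute_inward_normals_and_radius(extract_surface(mask), mask)
        faces = np.abs(np.abs(mesh.inward_normal[:, 2]) - 1.0) < 0.05
        central = (
            (mesh.vertices[:, 0] > 5) & (mesh.vertices[:, 0] < 25)
            & (mesh.vertices[:, 1] > 5) & (mesh.vertices[:, 1] < 25)
        )
        sel = faces & central
        assert sel.sum() > 50
        assert np.nanmean(mesh.local_radius[sel]) == pytest.approx(5.0, abs=1.0)

    def test_inward_probe_inside_mask(self, tube_single):
        _, mask, _ = tube_single
        mesh = compute_inward_normals_and_radius(extract_surface(mask), mask)
        eps = 0.25 * float(mask.spacing[0])
        probe = mesh.vertices + eps * mesh.inward_normal
        idx = np.rint((probe - mask.origin) / mask.spacing).astype(int)
        inside = mask.data[idx[:, 0], idx[:, 1], idx[:, 2]]
        assert inside.mean() >= 0.99

    def test_normals_unit_norm(self, tube_mesh):
        assert np.abs(np.linalg.norm(tube_mesh.inward_normal, axis=1) - 1.0).max() < 1e-6


class TestRegions:
    def test_inner_outer_split_matches_analytic_rule(self):
        # slim arch relative to the lumen keeps the single-plane split close
        # to the exact (torus-center distance) rule
        geom = TubeGeometry(40.0, 8.0, 100.0)
        profile = FlowProfileSpec(v_peak=100.0, waveform=[1.0])
        _, mask, _ = make_tube_subject(40.0, 8.0, 2.5, profile)
        mesh = compute_inward_normals_and_radius(extract_surface(mask), mask)
        lm = default_landmarks(geom, phi_stj_deg=32.0, phi_bct_deg=48.0)
        regs = subdivide_regions(mask, mesh, lm)
        pts = mask.world_points()
        lab = regs.voxel_label[mask.data]
        aao = (lab == 1) | (lab == 2)
        inner_true = np.hypot(pts[:, 0], pts[:, 2]) < 40.0
        agreement = ((lab == 1) == inner_true)[aao].mean()
        assert agreement >= 0.95

    def test_coincident_planes_rejected(self, tube_single, tube_mesh, tube_geom):
        _, mask, _ = tube_single
        lm = default_landmarks(tube_geom)
        lm["stj_plane"] = lm["bct_plane"]
        with pytest.raises(ValueError, match="stj_plane/bct_plane"):
            subdivide_regions(mask, tube_mesh, lm)

    def test_labels_partition_mask(self, tube_single, tube_mesh, tube_geom):
        _, mask, _ = tube_single
        regs = subdivide_regions(mask, tube_mesh, default_landmarks(tube_geom))
        total = sum(
            int((regs.voxel_label[mask.data] == code).sum()) for code in (0, 1, 2, 3)
        )
        assert total == mask.n_voxels
        inner = regs.voxel_region("innerAAo")
        outer = regs.voxel_region("outerAAo")
        assert not np.any(inner & outer)
        assert np.array_equal(regs.voxel_region("AAo"), inner | outer)


class TestQuantification:
    def test_volume_arithmetic(self):
        flags = np.zeros((10, 10, 10), bool)
        flags.ravel()[:64] = True
        assert quantify_volume(flags, 2.5) == pytest.approx(1.0)
        assert quantify_volume(np.zeros((5, 5, 5), bool), 2.5) == 0.0
        assert quantify_volume(np.ones(100, bool), 1.0) == pytest.approx(0.1)

    def test_surface_all_and_none(self, sphere_mesh):
        nv = sphere_mesh.n_vertices
        assert quantify_surface(np.ones(nv, bool), sphere_mesh) == pytest.approx(
            sphere_mesh.total_area_mm2() / 100.0
        )
        assert quantify_surface(np.zeros(nv, bool), sphere_mesh) == 0.0

    def test_hemisphere_surface(self, sphere_mesh):
        upper = sphere_mesh.vertices[:, 2] > 0
        area = quantify_surface(upper, sphere_mesh)
        assert area == pytest.approx(2 * math.pi * 20.0**2 / 100.0, rel=0.06)

    def test_regional_volume_partition_exact(self, tube_single, tube_mesh, tube_geom):
        _, mask, _ = tube_single
        regs = subdivide_regions(mask, tube_mesh, default_landmarks(tube_geom))
        parts = [
            quantify_volume(regs.voxel_region(r), mask.spacing)
            for r in ("innerAAo", "outerAAo", "pDAo", "other")
        ]
        assert sum(parts) == pytest.approx(mask.volume_cm3(), abs=1e-12)
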