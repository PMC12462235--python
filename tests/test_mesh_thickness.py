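"""Surface extraction, smoothing, decimation, inverse-normal thickness,
colour coding and mesh export."""

import numpy as np
import pytest
import trimesh

import cuticlemap as cm
from cuticlemap.mesh_thickness import PALETTES, ColorMap, MeshThicknessConfig


def _solid_sphere_mask(n=46, R=20.0):
    c = (n - 1) / 2.0
    z, y, x = np.indices((n, n, n), dtype=float)
    return cm.SegmentationMask(((z - c) ** 2 + (y - c) ** 2 + (x - c) ** 2) <= R * R)


def _slab_face_selector(mesh, mask_shape, normal=(1.0, 0.0, 0.0), frac=0.5, cos_min=0.98):
    """Vertices on the slab's flat faces, away from the rim."""
    v, n = mesh.vertices, mesh.normals
    nrm = np.asarray(normal)
    c = (np.array(mask_shape) - 1) / 2.0
    lateral = v - c
    lateral = lateral - np.outer(lateral @ nrm, nrm)
    half = min(mask_shape[1], mask_shape[2]) * frac / 2.0
    return (np.abs(n @ nrm) > cos_min) & (np.linalg.norm(lateral, axis=1) < half)


class TestExtractSurface:
    def test_solid_cube_mesh_is_closed_with_sphere_topology(self):
        mask = np.zeros((56, 56, 56), bool)
        mask[3:53, 3:53, 3:53] = True
        mesh = cm.extract_surface(cm.SegmentationMask(mask))
        tm = trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
        assert tm.is_watertight
        assert tm.euler_number == 2

    def test_sphere_area_close_to_analytic_after_slight_smoothing(self):
        # raw binary marching cubes is a staircase (~9% excess area); the
        # standard 2 smoothing passes bring it within 5% of 4*pi*R^2
        mesh = cm.smooth_mesh(cm.extract_surface(_solid_sphere_mask()), 2, 0.5)
        tm = trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
        analytic = 4 * np.pi * 20.0**2
        assert abs(tm.area - analytic) / analytic < 0.05

    def test_sphere_volume_close_to_analytic_unsmoothed(self):
        mesh = cm.extract_surface(_solid_sphere_mask())
        analytic = 4.0 / 3.0 * np.pi * 20.0**3
        assert abs(cm.enclosed_volume(mesh) - analytic) / analytic < 0.01

    def test_shell_splits_into_outer_and_inner_surface(self, small_shell):
        _, _, mask, _ = small_shell
        mesh = cm.extract_surface(mask)
        tm = trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
        assert len(tm.split(only_watertight=False)) == 2

    def test_normals_point_away_from_foreground(self):
        mesh = cm.extract_surface(_solid_sphere_mask())
        c = np.array([22.5, 22.5, 22.5])
        outward = np.einsum("ij,ij->i", mesh.normals, mesh.vertices - c)
        assert (outward > 0).mean() > 0.99

    def test_empty_and_full_masks_rejected(self):
        with pytest.raises(ValueError):
            cm.extract_surface(cm.SegmentationMask(np.zeros((8, 8, 8), bool)))
        with pytest.raises(ValueError):
            cm.extract_surface(cm.SegmentationMask(np.ones((8, 8, 8), bool)))


class TestSmoothing:
    def test_zero_iterations_is_identity(self):
        mesh = cm.extract_surface(_solid_sphere_mask())
        out = cm.smooth_mesh(mesh, 0)
        assert np.array_equal(out.vertices, mesh.vertices)
        assert np.array_equal(out.faces, mesh.faces)

    def test_taubin_preserves_enclosed_volume(self):
        mesh = cm.extract_surface(_solid_sphere_mask())
        v0 = cm.enclosed_volume(mesh)
        out = cm.smooth_mesh(mesh, 2, 0.5)
        assert abs(cm.enclosed_volume(out) - v0) / v0 < 0.02

    def test_flat_face_is_a_near_fixed_point(self, small_slab):
        _, _, mask, _ = small_slab
        mesh = cm.extract_surface(mask)
        sel = _slab_face_selector(mesh, mask.shape)
        out = cm.smooth_mesh(mesh, 2, 0.5)
        normal_motion = np.abs((out.vertices - mesh.vertices)[sel] @ np.array([1.0, 0, 0]))
        assert normal_motion.max() < 0.1

    def test_displacement_bounded_by_iterations_and_edge_length(self):
        mesh = cm.extract_surface(_solid_sphere_mask())
        tm = trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
        max_edge = tm.edges_unique_length.max()
        for iters in (1, 3):
            out = cm.smooth_mesh(mesh, iters, 0.5)
            disp = np.linalg.norm(out.vertices - mesh.vertices, axis=1)
            assert disp.max() <= iters * 0.5 * max_edge + 1e-9

    def test_vertex_count_and_topology_unchanged(self):
        mesh = cm.extract_surface(_solid_sphere_mask())
        out = cm.smooth_mesh(mesh, 5, 0.5)
        assert out.n_vertices == mesh.n_vertices
        assert np.array_equal(out.faces, mesh.faces)


class TestDecimation:
    def test_default_fraction_hits_70_percent_within_1pct(self):
        mesh = cm.extract_surface(_solid_sphere_mask())
        out = cm.decimate_mesh(mesh, 0.30)
        target = 0.70 * mesh.n_vertices
        assert abs(out.n_vertices - target) <= 0.01 * mesh.n_vertices

    def test_fraction_zero_is_identity(self):
        mesh = cm.extract_surface(_solid_sphere_mask())
        out = cm.decimate_mesh(mesh, 0.0)
        assert np.array_equal(out.vertices, mesh.vertices)

    def test_enclosed_volume_conserved_within_2pct(self):
        mesh = cm.extract_surface(_solid_sphere_mask())
        v0 = cm.enclosed_volume(mesh)
        out = cm.decimate_mesh(mesh, 0.30)
        assert abs(cm.enclosed_volume(out) - v0) / v0 < 0.02

    def test_result_stays_manifold_and_watertight(self):
        mesh = cm.extract_surface(_solid_sphere_mask())
        out = cm.decimate_mesh(mesh, 0.30)
        tm = trimesh.Trimesh(out.vertices, out.faces, process=False)
        assert tm.is_watertight
        assert tm.is_winding_consistent

    def test_invalid_fraction_rejected(self):
        mesh = cm.extract_surface(_solid_sphere_mask())
        with pytest.raises(ValueError):
            cm.decimate_mesh(mesh, 1.5)


class TestVertexThickness:
    def test_axis_aligned_slab_recovered_exactly(self, small_slab):
        _, _, mask, _ = small_slab
        mesh = cm.extract_surface(mask)
        th = cm.vertex_thickness(mesh, mask, MeshThicknessConfig())
        sel = _slab_face_selector(th, mask.shape)
        assert np.all(th.scalars[sel] == 5.0)

    def test_cap_saturation_on_thick_body(self):
        mask = _solid_sphere_mask(n=46, R=20.0)
        mesh = cm.extract_surface(mask)
        th = cm.vertex_thickness(mesh, mask, MeshThicknessConfig(rmax=12))
        assert th.scalars.max() == 12
        assert np.median(th.scalars) == 12

    def test_rotated_slab_within_one_voxel_of_continuous_oracle(self):
        spec = cm.PhantomSpec(
            kind="slab", grid_shape=(48, 48, 48), wall_thickness=10, rotation_deg=30
        )
        _, mask, _ = cm.make_phantom(spec)
        mesh = cm.extract_surface(mask)
        mesh = cm.smooth_mesh(mesh, 2, 0.5)
        mesh = cm.orient_normals(mesh, mask)
        th = cm.vertex_thickness(mesh, mask, MeshThicknessConfig())
        import math

        nrm = (math.cos(math.radians(30)), math.sin(math.radians(30)), 0.0)
        sel = _slab_face_selector(th, mask.shape, normal=nrm, frac=0.55)
        # continuous ray-slab intersection along the true normal is exactly t
        assert abs(np.median(th.scalars[sel]) - 10.0) <= 1.0

    def test_missing_normals_rejected(self, small_slab):
        _, _, mask, _ = small_slab
        mesh = cm.extract_surface(mask)
        broken = cm.SurfaceMesh(
            vertices=mesh.vertices, faces=mesh.faces, normals=mesh.normals
        )
        broken.normals = broken.normals[:-1]
        with pytest.raises(ValueError):
            cm.vertex_thickness(broken, mask, MeshThicknessConfig())


class TestColorize:
    def test_extremes_map_to_first_and_last_stops(self):
        rgba = cm.colorize(np.array([0.0, 10.0]), "blue-red")
        assert tuple(rgba[0][:3]) == (0, 0, 255)
        assert tuple(rgba[1][:3]) == (255, 0, 0)

    def test_monotone_scalars_get_monotone_palette_positions(self, rng):
        s = np.sort(rng.uniform(0, 100, size=50))
        rgba = cm.colorize(s, "blue-red").astype(int)
        # red minus blue channel is a monotone proxy for palette position
        proxy = rgba[:, 0] - rgba[:, 2]
        assert np.all(np.diff(proxy) >= 0)

    def test_constant_scalars_need_explicit_window(self):
        with pytest.raises(ValueError):
            cm.colorize(np.full(5, 3.0), "blue-red")
        rgba = cm.colorize(np.full(5, 3.0), "blue-red", lo=0.0, hi=10.0)
        assert len(np.unique(rgba, axis=0)) == 1

    def test_palette_stops_validated(self):
        with pytest.raises(ValueError):
            ColorMap(stops=[(0.0, (0, 0, 255)), (0.5, (0, 0, 0))])
        assert "blue-red" in PALETTES


class TestExport:
    def test_ply_roundtrip_preserves_vertices_and_colours(self, tmp_path):
        mask = _solid_sphere_mask(n=30, R=12.0)
        mesh = cm.extract_surface(mask)
        th = cm.vertex_thickness(mesh, mask, MeshThicknessConfig(rmax=30))
        th.colors = cm.colorize(th.scalars, "blue-red", lo=0, hi=30)
        cm.export_mesh(th, tmp_path / "m.ply")
        back = cm.read_mesh(tmp_path / "m.ply")
        assert back.n_vertices == th.n_vertices
        assert np.array_equal(back.colors, th.colors)

    def test_obj_has_geometry_normals_faces_and_scalar_sidecar(self, tmp_path):
        mask = _solid_sphere_mask(n=30, R=12.0)
        mesh = cm.extract_surface(mask)
        th = cm.vertex_thickness(mesh, mask, MeshThicknessConfig(rmax=30))
        cm.export_mesh(th, tmp_path / "m.obj")
        text = (tmp_path / "m.obj").read_text().splitlines()
        kinds = {line.split()[0] for line in text if line.strip()}
        assert kinds == {"v", "vn", "f"}
        assert sum(1 for l in text if l.startswith("v ")) == th.n_vertices
        side = (tmp_path / "m_thickness.csv").read_text().splitlines()
        assert side[0] == "vertex_id,thickness"
        assert len(side) == th.n_vertices + 1
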