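"""Point-cloud → volume-mesh pipeline: each stage against small oracles."""

import numpy as np
import pytest

from lapwsim.geometry import (
    PointCloud,
    clean_surface,
    downsample_pcd,
    extrude_surface,
    reconstruct_surface,
    refine_uniform,
    tetrahedralize,
)
from lapwsim.synthetic_data import SheetSpec, make_sheet_pcd


def grid_cloud(n=21, m=21, spacing=1.0):
    xs, ys = np.meshgrid(np.arange(n) * spacing, np.arange(m) * spacing, indexing="ij")
    return PointCloud(np.column_stack([xs.ravel(), ys.ravel(), np.zeros(xs.size)]))


class TestDownsample:
    def test_min_pairwise_distance_brute_force(self):
        out = downsample_pcd(grid_cloud(), 3.5)
        pts = out.points
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 3.5
        assert len(out) > 1

    def test_subset_of_input(self):
        cloud = grid_cloud(8, 8)
        out = downsample_pcd(cloud, 2.5)
        in_set = {tuple(p) for p in cloud.points}
        assert all(tuple(p) in in_set for p in out.points)

    def test_identity_when_spacing_below_min_distance(self):
        cloud = grid_cloud(5, 5, spacing=2.0)
        out = downsample_pcd(cloud, 1.0)
        assert len(out) == len(cloud)

    def test_single_point(self):
        out = downsample_pcd(PointCloud([[1.0, 2.0, 3.0]]), 10.0)
        assert np.allclose(out.points, [[1, 2, 3]])

    def test_idempotent(self):
        once = downsample_pcd(grid_cloud(), 3.5)
        twice = downsample_pcd(once, 3.5)
        assert np.array_equal(once.points, twice.points)

    def test_invalid_spacing(self):
        with pytest.raises(ValueError):
            downsample_pcd(grid_cloud(3, 3), 0.0)


class TestReconstruct:
    def test_three_points_one_triangle(self):
        mesh = reconstruct_surface(PointCloud([[0, 0, 0], [1, 0, 0], [0, 1, 0]]))
        assert len(mesh.triangles) == 1

    @pytest.mark.parametrize("n,m", [(5, 5), (4, 7)])
    def test_grid_triangle_count(self, n, m):
        mesh = reconstruct_surface(grid_cloud(n, m))
        assert len(mesh.triangles) == 2 * (n - 1) * (m - 1)

    def test_collinear_raises(self):
        pts = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError):
            reconstruct_surface(PointCloud(pts))

    def test_all_points_are_vertices_and_mesh_valid(self):
        cloud = grid_cloud(6, 6)
        mesh = reconstruct_surface(cloud)
        assert len(mesh.vertices) == len(cloud)
        mesh.validate()  # manifold + consistent winding + no degenerates

    def test_normals_oriented_up_for_flat_sheet(self):
        mesh = reconstruct_surface(grid_cloud(5, 5))
        assert np.all(mesh.vertex_normals[:, 2] > 0.99)


class TestClean:
    def test_smooth_sheet_identity(self):
        mesh = reconstruct_surface(grid_cloud(8, 8))
        cleaned, removed = clean_surface(mesh, 60.0)
        assert removed == 0
        assert len(cleaned.vertices) == len(mesh.vertices)

    def test_spike_vertex_removed(self):
        cloud = grid_cloud(7, 7).points.copy()
        center = 3 * 7 + 3
        cloud[center, 2] = 2.5  # spike: incident normals spread far past 60°
        mesh = reconstruct_surface(PointCloud(cloud))
        cleaned, removed = clean_surface(mesh, 60.0)
        assert removed == 1
        assert len(cleaned.vertices) == len(cloud) - 1

    def test_threshold_180_identity(self):
        cloud = grid_cloud(7, 7).points.copy()
        cloud[3 * 7 + 3, 2] = 2.5
        mesh = reconstruct_surface(PointCloud(cloud))
        _, removed = clean_surface(mesh, 180.0)
        assert removed == 0


class TestExtrude:
    def test_flat_sheet_shell_volume(self):
        mesh = reconstruct_surface(grid_cloud(11, 11))  # 10×10 mm planform
        shell = extrude_surface(mesh, 2.3)
        assert shell.volume() == pytest.approx(100.0 * 2.3, rel=1e-9)

    def test_mean_offset_equals_thickness(self):
        mesh = reconstruct_surface(grid_cloud(6, 6))
        shell = extrude_surface(mesh, 2.3)
        offsets = np.linalg.norm(shell.top_vertices - shell.base_vertices, axis=1)
        assert np.abs(offsets.mean() - 2.3) < 1e-9

    def test_zero_thickness_raises(self):
        mesh = reconstruct_surface(grid_cloud(4, 4))
        with pytest.raises(ValueError):
            extrude_surface(mesh, 0.0)

    def test_concave_cap_tighter_than_thickness_self_intersects(self):
        # spherical cap of radius 1.5 mm, extruded 2.3 mm toward its center
        r = 1.5
        u = np.linspace(-0.5, 0.5, 9)
        X, Y = np.meshgrid(u, u, indexing="ij")
        Z = -np.sqrt(r**2 - X**2 - Y**2)  # concave up; outward normal ~ +z
        cap = PointCloud(np.column_stack([X.ravel(), Y.ravel(), Z.ravel()]))
        mesh = reconstruct_surface(cap)
        with pytest.raises(ValueError, match="self-intersect"):
            extrude_surface(mesh, 2.3)


class TestTetrahedralize:
    def test_single_prism_three_tets_volume_exact(self):
        mesh = reconstruct_surface(PointCloud([[0, 0, 0], [1, 0, 0], [0, 1, 0]]))
        shell = extrude_surface(mesh, 2.0)
        vol_mesh = tetrahedralize(shell)
        assert vol_mesh.n_elements == 3
        assert vol_mesh.total_volume() == pytest.approx(0.5 * 2.0, rel=1e-9)

    def test_triangle_count_times_three(self):
        mesh = reconstruct_surface(grid_cloud(5, 5))
        vol_mesh = tetrahedralize(extrude_surface(mesh, 2.3))
        assert vol_mesh.n_elements == 3 * len(mesh.triangles)

    def test_all_tets_positively_oriented_and_volume_preserved(self):
        mesh = reconstruct_surface(grid_cloud(6, 4))
        shell = extrude_surface(mesh, 2.3)
        vol_mesh = tetrahedralize(shell)
        assert vol_mesh.signed_volumes().min() > 0
        assert vol_mesh.total_volume() == pytest.approx(shell.volume(), rel=1e-9)

    def test_conforming_no_hanging_faces(self):
        # every interior face must be shared by exactly 2 tets
        mesh = reconstruct_surface(grid_cloud(5, 5))
        vol_mesh = tetrahedralize(extrude_surface(mesh, 2.3))
        t = vol_mesh.tets
        faces = np.concatenate(
            [t[:, [0, 1, 2]], t[:, [0, 1, 3]], t[:, [0, 2, 3]], t[:, [1, 2, 3]]]
        )
        _, counts = np.unique(np.sort(faces, axis=1), axis=0, return_counts=True)
        assert counts.max() <= 2


class TestRefine:
    def test_level_zero_identity(self, small_slab):
        out = refine_uniform(small_slab, 0)
        assert out is small_slab

    def test_one_tet_becomes_eight_same_volume(self):
        from lapwsim.geometry import VolumeMesh

        tet = VolumeMesh(
            np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]]),
            np.array([[0, 1, 2, 3]]),
        )
        out = refine_uniform(tet, 1)
        assert out.n_elements == 8
        assert out.total_volume() == pytest.approx(tet.total_volume(), rel=1e-12)

    def test_three_tet_shell_two_levels(self):
        mesh = reconstruct_surface(PointCloud([[0, 0, 0], [1, 0, 0], [0, 1, 0]]))
        vol_mesh = tetrahedralize(extrude_surface(mesh, 2.0))
        out = refine_uniform(vol_mesh, 2)
        assert out.n_elements == 3 * 8**2
        assert out.total_volume() == pytest.approx(vol_mesh.total_volume(), rel=1e-9)

    def test_max_edge_shrinks_per_level(self, small_slab):
        out = refine_uniform(small_slab, 1)
        ratio = out.edge_lengths().max() / small_slab.edge_lengths().max()
        assert 0.49 <= ratio <= 0.75  # corner edges halve; octahedron diagonal ≤ 0.75

    def test_subdomain_inheritance(self, small_slab):
        from lapwsim.geometry import VolumeMesh

        sub = np.ones(small_slab.n_elements, dtype=np.int64)
        sub[::3] = 2
        tagged = VolumeMesh(
            small_slab.vertices,
            small_slab.tets,
            sub,
            vertex_depth=small_slab.vertex_depth,
            vertex_normal=small_slab.vertex_normal,
        )
        out = refine_uniform(tagged, 1)
        assert np.sum(out.element_subdomain == 2) == 8 * np.sum(sub == 2)


def test_full_pipeline_volume_matches_planform_area_times_thickness():
    cloud = make_sheet_pcd(SheetSpec(extent_x=10.0, extent_y=10.0, point_spacing=1.0, seed=0))
    mesh = reconstruct_surface(cloud)
    vol_mesh = refine_uniform(tetrahedralize(extrude_surface(mesh, 2.3)), 1)
    assert vol_mesh.total_volume() == pytest.approx(10.0 * 10.0 * 2.3, rel=1e-3)
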