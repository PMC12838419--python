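import numpy as np
import pytest
import trimesh

from corofuse.errors import EmptyCloudError, ParameterError
from corofuse.fusion import (BoxRegion, FusionConfig, LabeledPointCloud,
                             SphereRegion, TubeRegion, add_wall, fuse,
                             mesh_to_point_cloud, reconstruct_surface,
                             remove_overlapping_points, select_points_region)
from corofuse.geometry import Centerline, Plane, plane_mesh_section, polygon_area


def grid_cloud(n=10, label="CCTA", extent=10.0):
    g = np.linspace(0, extent, n)
    X, Y, Z = np.meshgrid(g, g, g, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    return LabeledPointCloud(pts, np.full(len(pts), label, object))


class TestMeshToPointCloud:
    def test_sampling_count_on_unit_triangle(self):
        tri = trimesh.Trimesh(vertices=[[0, 0, 0], [2, 0, 0], [0, 1, 0]],
                              faces=[[0, 1, 2]])   # area 1
        cloud = mesh_to_point_cloud(tri, density=100.0, seed=0)
        assert len(cloud) == 3 + 100

    def test_tiny_density_keeps_vertices_only(self):
        tri = trimesh.Trimesh(vertices=[[0, 0, 0], [1, 0, 0], [0, 1, 0]],
                              faces=[[0, 1, 2]])
        cloud = mesh_to_point_cloud(tri, density=1e-4)
        assert len(cloud) == 3

    def test_samples_lie_on_surface(self):
        cyl = trimesh.creation.cylinder(radius=1.0, height=4.0, sections=128)
        cloud = mesh_to_point_cloud(cyl, density=5.0, seed=1)
        from corofuse.proximity import points_to_mesh_distance
        assert np.max(points_to_mesh_distance(cyl, cloud.points)) < 1e-6

    def test_empty_mesh_rejected(self):
        with pytest.raises(ParameterError):
            mesh_to_point_cloud(trimesh.Trimesh(), density=1.0)


class TestRemoveOverlappingPoints:
    def test_empty_oct_is_noop(self):
        ccta = grid_cloud(5)
        out = remove_overlapping_points(
            ccta, LabeledPointCloud(np.empty((0, 3)), np.empty(0, object)))
        assert len(out) == len(ccta)

    def test_all_within_radius_removed(self):
        ccta = grid_cloud(4, extent=0.05)
        oct_c = LabeledPointCloud([[0.02, 0.02, 0.02]], ["OCT"])
        assert len(remove_overlapping_points(ccta, oct_c)) == 0

    def test_boundary_equality_kept(self):
        ccta = LabeledPointCloud([[0.35, 0, 0], [0.349, 0, 0]],
                                 ["CCTA", "CCTA"])
        oct_c = LabeledPointCloud([[0, 0, 0]], ["OCT"])
        out = remove_overlapping_points(ccta, oct_c)
        assert len(out) == 1
        np.testing.assert_allclose(out.points[0], [0.35, 0, 0])

    def test_matches_brute_force_filter(self, rng):
        ccta_pts = rng.uniform(0, 10, (1000, 3))
        oct_pts = rng.uniform(0, 10, (500, 3))
        ccta = LabeledPointCloud(ccta_pts, np.full(1000, "CCTA", object))
        oct_c = LabeledPointCloud(oct_pts, np.full(500, "OCT", object))
        out = remove_overlapping_points(ccta, oct_c)
        d = np.linalg.norm(ccta_pts[:, None, :] - oct_pts[None], axis=2)
        expected = ccta_pts[d.min(axis=1) >= 0.35]
        np.testing.assert_array_equal(out.points, expected)

    def test_monotone_in_radius(self, rng):
        ccta = LabeledPointCloud(rng.uniform(0, 5, (400, 3)),
                                 np.full(400, "CCTA", object))
        oct_c = LabeledPointCloud(rng.uniform(0, 5, (200, 3)),
                                  np.full(200, "OCT", object))
        kept = None
        for radius in (0.1, 0.35, 0.8, 1.5):
            out = remove_overlapping_points(
                ccta, oct_c, FusionConfig(overlap_radius_mm=radius))
            ids = {tuple(p) for p in out.points}
            if kept is not None:
                assert ids <= kept
            kept = ids


class TestRegionSelection:
    def test_sphere_removal_exact(self):
        cloud = grid_cloud(5, extent=2.0)
        region = SphereRegion([0, 0, 0], 1.0)
        out = select_points_region(cloud, region, keep=False)
        assert np.all(np.linalg.norm(out.points, axis=1) > 1.0)

    def test_tube_segment_matches_polyline_distance_oracle(self, rng):
        cl = Centerline([[0, 0, z] for z in np.linspace(0, 20, 41)])
        pts = rng.uniform(-3, 3, (500, 3)) + [0, 0, 10]
        cloud = LabeledPointCloud(pts, np.full(500, "CCTA", object))
        region = TubeRegion(cl, (10, 20), radius=2.0)
        out = select_points_region(cloud, region, keep=False)
        # brute-force point-to-segment oracle
        seg = cl.points[10:21]
        def dist(p):
            best = np.inf
            for a, b in zip(seg[:-1], seg[1:]):
                t = np.clip(np.dot(p - a, b - a) / np.dot(b - a, b - a), 0, 1)
                best = min(best, np.linalg.norm(p - (a + t * (b - a))))
            return best
        keep_mask = np.array([dist(p) > 2.0 for p in pts])
        np.testing.assert_array_equal(out.points, pts[keep_mask])

    def test_empty_region_keeps_cloud(self):
        cloud = grid_cloud(3)
        region = SphereRegion([100, 100, 100], 0.1)
        out = select_points_region(cloud, region, keep=False)
        assert len(out) == len(cloud)

    def test_removing_everything_raises(self):
        cloud = grid_cloud(3, extent=1.0)
        with pytest.raises(EmptyCloudError):
            select_points_region(cloud, SphereRegion([0.5, 0.5, 0.5], 10.0),
                                 keep=False)


class TestFuse:
    def test_concatenation_preserves_counts_and_coordinates(self, pipeline_results):
        res = pipeline_results["patient12-like"]
        fused, stack = res["fused"], res["stack"]
        counts = fused.label_counts()
        assert counts["OCT"] == sum(len(c.points) for c in stack.contours3d)
        oct_pts = stack.all_points()
        fused_set = {tuple(np.round(p, 9)) for p in fused.points}
        for p in oct_pts[::50]:
            assert tuple(np.round(p, 9)) in fused_set

    def test_no_ccta_point_near_oct_after_filter(self, pipeline_results):
        from scipy.spatial import cKDTree
        res = pipeline_results["patient7-like"]
        fused = res["fused"]
        mask = fused.labels.astype(str) == "OCT"
        d, _ = cKDTree(fused.points[mask]).query(fused.points[~mask])
        assert np.min(d) >= 0.35


class TestReconstructSurface:
    def _cylinder_cloud(self, r=1.5, L=20.0, n=6000, seed=0):
        rng = np.random.default_rng(seed)
        z = rng.uniform(0, L, n)
        th = rng.uniform(0, 2 * np.pi, n)
        pts = np.column_stack([r * np.cos(th), r * np.sin(th), z])
        return LabeledPointCloud(pts, np.full(n, "OCT", object))

    def test_cylinder_cloud_area(self):
        cloud = self._cylinder_cloud()
        cl = Centerline([[0, 0, z] for z in np.arange(0, 20.4, 0.4)])
        mesh = reconstruct_surface(cloud, cl)
        assert mesh.is_watertight
        lateral = 2 * np.pi * 1.5 * 20
        caps = 2 * np.pi * 1.5 ** 2
        assert mesh.area == pytest.approx(lateral + caps, rel=0.05)

    def test_mean_point_distance_below_tenth_mm(self):
        from corofuse.proximity import points_to_mesh_distance
        cloud = self._cylinder_cloud()
        cl = Centerline([[0, 0, z] for z in np.arange(0, 20.4, 0.4)])
        mesh = reconstruct_surface(cloud, cl)
        d = points_to_mesh_distance(mesh, cloud.points[::5])
        assert np.mean(d) < 0.1

    def test_too_few_points_rejected(self):
        cloud = LabeledPointCloud(np.random.default_rng(0).uniform(0, 1, (50, 3)),
                                  np.full(50, "OCT", object))
        with pytest.raises(ParameterError):
            reconstruct_surface(cloud)

    def test_section_radius_error_shrinks_with_density(self):
        """Equal-area radius converges to truth as sampling densifies."""
        cl = Centerline([[0, 0, z] for z in np.arange(0, 20.4, 0.4)])
        errs = []
        for n in (2000, 8000, 32000):
            mesh = reconstruct_surface(self._cylinder_cloud(n=n, seed=1), cl)
            secs = plane_mesh_section(mesh, Plane([0, 0, 10], [0, 0, 1]))
            r_eq = np.sqrt(polygon_area(secs[0]) / np.pi)
            errs.append(abs(r_eq - 1.5))
        assert errs[2] <= errs[0]
        assert errs[2] / 1.5 < 0.02

    def test_phantom_cross_sections_match_truth(self, pipeline_results):
        """Reconstructed fused surface reproduces the true area profile."""
        for res in pipeline_results.values():
            truth, profile = res["truth"], res["profile"]
            cal_spacing = 0.4
            fine_s = truth.centerline.cumulative_arclength
            for i in range(5, profile.centerline_indices[-1] - 5, 10):
                s = i * cal_spacing
                a_true = np.pi * truth.spec.radius_at(s) ** 2
                a_rec = profile.areas[i]
                if np.isfinite(a_rec):
                    assert abs(a_rec - a_true) / a_true < 0.1


class TestAddWall:
    def test_cylinder_outer_radius(self):
        cyl = trimesh.creation.cylinder(radius=1.5, height=20.0, sections=128)
        wall = add_wall(cyl, FusionConfig(wall_thickness_mm=1.0))
        assert wall.is_watertight
        secs = plane_mesh_section(wall, Plane([0, 0, 0], [0, 0, 1]))
        outer = max(secs, key=polygon_area)
        r_outer = np.sqrt(polygon_area(outer) / np.pi)
        assert r_outer == pytest.approx(2.5, rel=0.02)

    def test_sphere_outer_area(self):
        sph = trimesh.creation.icosphere(subdivisions=4, radius=5.0)
        wall = add_wall(sph, FusionConfig(wall_thickness_mm=1.0))
        outer_area = wall.area - sph.area
        assert outer_area == pytest.approx(4 * np.pi * 36, rel=0.02)

    def test_non_watertight_input_rejected(self):
        open_mesh = trimesh.Trimesh(vertices=[[0, 0, 0], [1, 0, 0], [0, 1, 0]],
                                    faces=[[0, 1, 2]])
        with pytest.raises(ParameterError):
            add_wall(open_mesh)

    def test_wall_volume_is_shell_volume(self):
        cyl = trimesh.creation.cylinder(radius=1.5, height=10.0, sections=64)
        wall = add_wall(cyl)
        assert wall.volume < np.pi * 2.5 ** 2 * 12    # less than the full outer solid
        assert wall.volume > 0
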