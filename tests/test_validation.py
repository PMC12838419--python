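import numpy as np
import pytest
import trimesh
from hypothesis import given, settings
from hypothesis import strategies as st

from corofuse.errors import (NoReferenceError, ParameterError, ProfileError)
from corofuse.geometry import Centerline, transport_frames
from corofuse.validation import (AreaProfile, ValidationConfig,
                                 area_difference_stats, lumen_area_profile,
                                 pct_area_stenosis, regression_slope_r2,
                                 side_branch_distance, stenosis_from_profile,
                                 vertex_distance_stats)


class TestPctAreaStenosis:
    def test_eighty_percent(self):
        assert pct_area_stenosis(10.0, 2.0) == 80.0

    def test_no_stenosis(self):
        assert pct_area_stenosis(7.0, 7.0) == 0.0

    def test_mla_above_rva_rejected(self):
        with pytest.raises(ParameterError):
            pct_area_stenosis(5.0, 6.0)

    def test_nonpositive_rva_rejected(self):
        with pytest.raises(ParameterError):
            pct_area_stenosis(0.0, 0.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(c=st.floats(1e-3, 1e3), mla=st.floats(0.1, 5.0))
    def test_scale_invariance(self, c, mla):
        rva = 6.0
        assert pct_area_stenosis(c * rva, c * mla) == pytest.approx(
            pct_area_stenosis(rva, mla), rel=1e-9)


class TestAreaProfile:
    def test_zscore_normalization_invariants(self):
        p = AreaProfile(np.arange(6), [7, 7, 7, 2, 6, 7])
        fin = np.isfinite(p.zscores)
        assert abs(np.mean(p.zscores[fin])) < 1e-9
        assert abs(np.std(p.zscores[fin]) - 1) < 1e-9

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(shift=st.floats(-10, 10), scale=st.floats(0.1, 10))
    def test_zscores_affine_invariant(self, shift, scale):
        a = np.array([3.0, 4.0, 6.0, 2.0, 5.0, 4.5])
        z1 = AreaProfile(np.arange(6), a).zscores
        z2 = AreaProfile(np.arange(6), scale * a + shift).zscores
        np.testing.assert_allclose(z1, z2, atol=1e-9)


class TestStenosisFromProfile:
    def test_documented_example(self):
        p = AreaProfile(np.arange(6), [7, 7, 7, 2, 6, 7])
        m = stenosis_from_profile(p)
        assert m.MLA == 2 and m.RVA == 7
        assert m.mla_index == 3
        assert m.pct_AS == pytest.approx(5 / 7 * 100, rel=1e-9)

    def test_monotone_increasing_has_no_reference(self):
        p = AreaProfile(np.arange(6), [1, 2, 3, 4, 5, 6])
        with pytest.raises(NoReferenceError):
            stenosis_from_profile(p)

    def test_constant_profile_zero_stenosis(self):
        p = AreaProfile(np.arange(6), [5.0] * 6)
        assert stenosis_from_profile(p).pct_AS == 0.0

    def test_too_few_points_rejected(self):
        p = AreaProfile(np.arange(4), [5, 4, 3, 5])
        with pytest.raises(ProfileError):
            stenosis_from_profile(p)


class TestLumenAreaProfile:
    def test_straight_cylinder_flat_profile(self):
        cyl = trimesh.creation.cylinder(radius=1.0, height=20.0, sections=128)
        cl = Centerline([[0, 0, z] for z in np.arange(-9, 9.5, 1.0)])
        p = lumen_area_profile(cyl, cl)
        np.testing.assert_allclose(p.areas, np.pi, rtol=2e-3)
        assert np.all(np.abs(p.zscores) < 3)

    def test_centerline_past_mesh_yields_missing_not_zero(self):
        cyl = trimesh.creation.cylinder(radius=1.0, height=10.0, sections=64)
        cl = Centerline([[0, 0, z] for z in np.arange(-4, 14, 1.0)])
        p = lumen_area_profile(cyl, cl)
        assert np.isnan(p.areas[-1])
        assert np.isfinite(p.areas[0])

    def test_phantom_throat_located(self, pipeline_results):
        for res in pipeline_results.values():
            truth, stenosis = res["truth"], res["stenosis"]
            throat_s = truth.spec.stenoses[0][0]
            expected_idx = throat_s / 0.4
            assert abs(stenosis.mla_index - expected_idx) <= 1


class TestVertexDistance:
    def _plane_patch(self, spacing=1.0, n=8):
        g = np.arange(n) * spacing
        X, Y = np.meshgrid(g, g)
        verts = np.column_stack([X.ravel(), Y.ravel(), np.zeros(n * n)])
        faces = []
        for i in range(n - 1):
            for j in range(n - 1):
                a = i * n + j
                faces.append([a, a + 1, a + n])
                faces.append([a + 1, a + n + 1, a + n])
        return trimesh.Trimesh(verts, faces, process=False)

    def test_identical_meshes_flagged_degenerate(self):
        m = self._plane_patch()
        stats = vertex_distance_stats(m, m)
        assert stats.degenerate
        assert np.isnan(stats.median)

    def test_translated_plane_median_exact(self):
        om = self._plane_patch()
        dm = om.copy()
        dm.apply_translation([0, 0, 0.20])
        stats = vertex_distance_stats(dm, om)
        assert stats.median == pytest.approx(0.20, abs=1e-6)

    def test_scaled_cylinder_radial_offset(self):
        om = trimesh.creation.cylinder(radius=1.5, height=10.0, sections=256)
        dm = om.copy()
        dm.apply_scale([(1.5 + 0.1) / 1.5, (1.5 + 0.1) / 1.5, 1.0])
        stats = vertex_distance_stats(dm, om)
        assert stats.median == pytest.approx(0.10, abs=0.01)

    def test_invariant_under_joint_rigid_transform(self):
        om = trimesh.creation.icosphere(subdivisions=3, radius=2.0)
        dm = om.copy()
        dm.apply_translation([0.1, 0, 0])
        s1 = vertex_distance_stats(dm, om)
        T = trimesh.transformations.rotation_matrix(0.7, [1, 1, 0], [1, 2, 3])
        om2, dm2 = om.copy(), dm.copy()
        om2.apply_transform(T)
        dm2.apply_transform(T)
        s2 = vertex_distance_stats(dm2, om2)
        assert s2.median == pytest.approx(s1.median, abs=1e-9)

    def test_raising_exclusion_never_lowers_median(self):
        om = self._plane_patch()
        rng = np.random.default_rng(0)
        dm = om.copy()
        dm.apply_translation([0, 0, 0.05])
        dm.vertices[:, 2] += rng.uniform(0, 0.2, len(dm.vertices))
        medians = []
        for thr in (0.0, 0.05, 0.1):
            s = vertex_distance_stats(dm, om, ValidationConfig(vd_exclusion_mm=thr))
            medians.append(s.median)
        assert medians[0] <= medians[1] <= medians[2]


class TestAreaDifference:
    def _profiles(self):
        a = np.array([5.0, 6.0, 4.0, 2.0, 4.5, 5.5, 6.0])
        om = AreaProfile(np.arange(7), a)
        return om, a

    def test_identical_profiles(self):
        om, a = self._profiles()
        dm = AreaProfile(np.arange(7), a.copy())
        out = area_difference_stats(om, dm)
        assert out["ad_median"] == 0.0
        assert out["zdiff_mean"] == 0.0

    def test_constant_offset(self):
        om, a = self._profiles()
        dm = AreaProfile(np.arange(7), a + 0.5)
        out = area_difference_stats(om, dm)
        assert out["ad_median"] == pytest.approx(0.5, abs=1e-12)
        assert out["zdiff_mean"] == pytest.approx(0.0, abs=1e-9)

    def test_pure_scale(self):
        om, a = self._profiles()
        dm = AreaProfile(np.arange(7), 1.2 * a)
        out = area_difference_stats(om, dm)
        assert out["zdiff_mean"] == pytest.approx(0.0, abs=1e-9)
        assert out["r_squared"] == pytest.approx(1.0, abs=1e-9)

    def test_too_few_shared_indices(self):
        om = AreaProfile(np.arange(7), np.arange(7) + 1.0)
        dm = AreaProfile(np.arange(7) + 5, np.arange(7) + 1.0)
        with pytest.raises(ProfileError):
            area_difference_stats(om, dm)


class TestRegression:
    def test_identity_line(self):
        x = np.arange(10, dtype=float)
        slope, intercept, r2 = regression_slope_r2(x, x)
        assert (slope, intercept, r2) == (1.0, 0.0, 1.0)

    def test_affine_line(self):
        x = np.arange(10, dtype=float)
        slope, intercept, r2 = regression_slope_r2(x, 2 * x + 1)
        assert slope == pytest.approx(2.0) and intercept == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self, rng):
        x = rng.uniform(0, 10, 10)
        y = 1.7 * x + rng.normal(0, 0.5, 10)
        slope, intercept, _ = regression_slope_r2(x, y)
        A = np.column_stack([x, np.ones(10)])
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        assert slope == pytest.approx(beta[0], abs=1e-12)
        assert intercept == pytest.approx(beta[1], abs=1e-12)

    def test_constant_x_rejected(self):
        with pytest.raises(ParameterError):
            regression_slope_r2([1, 1, 1], [1, 2, 3])


class TestSideBranchDistance:
    def _series(self, spacing=0.2, n=100):
        from conftest import circle_contour
        from corofuse.oct_processing import Calibration, PullbackSeries
        return PullbackSeries(
            contours=[circle_contour(n=16) for _ in range(n)],
            calibration=Calibration(frame_spacing_mm=spacing),
            frame_indices=list(range(n)))

    def test_frames_70_apart_at_02mm(self):
        assert side_branch_distance(self._series(), 10, 80) == 14

    def test_same_frame_rejected(self):
        with pytest.raises(ParameterError):
            side_branch_distance(self._series(), 5, 5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            side_branch_distance(self._series(n=20), 5, 99)

    def test_phantom_branch_separation(self, pipeline_results):
        for res in pipeline_results.values():
            truth, series = res["truth"], res["series"]
            p0, p1 = truth.branch_positions
            k0 = int(round(p0 / 0.4))
            k1 = int(round(p1 / 0.4))
            measured = side_branch_distance(series, k0, k1)
            assert abs(measured - (p1 - p0)) <= 1.0


class TestVDPerturbationMonotonicity:
    def test_vd_median_grows_with_injected_perturbation(self):
        """Simulated re-imaging error: VD median tracks the injected
        radial perturbation magnitude."""
        om = trimesh.creation.cylinder(radius=1.5, height=15.0, sections=128)
        medians = []
        for delta in (0.05, 0.1, 0.2, 0.4):
            dm = om.copy()
            dm.apply_scale([(1.5 + delta) / 1.5, (1.5 + delta) / 1.5, 1.0])
            s = vertex_distance_stats(dm, om)
            medians.append(s.median)
        assert all(a < b for a, b in zip(medians, medians[1:]))
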