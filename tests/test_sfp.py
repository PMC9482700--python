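"""Frame traces, boundary fitting, pose checks and coverage accounting."""

import numpy as np
import pytest

from sfproj import (
    AmbiguousBoundaryError,
    CoverageGrid,
    EulerSpec,
    Orientation,
    OrientationSet,
    RomSpec,
    UnanchoredStartError,
    ValidationError,
    arc_length,
    build_sfp,
    check_pose,
    check_pose_path,
    coverage_update,
    default_grid,
    fit_boundary,
    frame_trace,
    from_euler,
    generate_rom,
    geodesic_extent,
)
from conftest import random_orientations


class TestFrameTrace:
    def test_identity_gives_basis_vectors(self):
        tr = frame_trace(OrientationSet([Orientation.identity()]))
        np.testing.assert_array_equal(tr.clouds["X"][0], [1, 0, 0])
        np.testing.assert_array_equal(tr.clouds["Y"][0], [0, 1, 0])
        np.testing.assert_array_equal(tr.clouds["Z"][0], [0, 0, 1])

    def test_points_are_matrix_rows(self, rng):
        data = OrientationSet(random_orientations(rng, 10))
        tr = frame_trace(data)
        for i, o in enumerate(data):
            for j, ax in enumerate("XYZ"):
                np.testing.assert_allclose(tr.clouds[ax][i], o.m[j], atol=1e-12)

    def test_one_dof_arcs(self, one_dof_set):
        tr = frame_trace(one_dof_set)
        assert geodesic_extent(tr.clouds["X"]) == 0.0
        assert geodesic_extent(tr.clouds["Y"]) == pytest.approx(60.0, abs=1e-9)
        assert geodesic_extent(tr.clouds["Z"]) == pytest.approx(60.0, abs=1e-9)

    def test_invalid_member_reported_with_index(self, one_dof_set):
        bad = list(one_dof_set.items)
        bad[7] = Orientation.identity()
        bad[7].m = np.diag([1.0, 1.0, -1.0])  # bypass constructor validation
        with pytest.raises(ValidationError, match="7"):
            frame_trace(OrientationSet(bad))

    def test_per_index_orthogonality(self, two_dof_set):
        tr = frame_trace(two_dof_set)
        x, y, z = (tr.clouds[a] for a in "XYZ")
        assert np.abs(np.sum(x * y, axis=1)).max() < 1e-9
        assert np.abs(np.sum(y * z, axis=1)).max() < 1e-9


class TestFitBoundary:
    def test_single_point_degenerate_patch_loop(self):
        poly = fit_boundary(np.array([[0.0, 0.0, 1.0]]))
        assert len(poly) == 3  # one triangular patch's perimeter
        assert poly.contains([0.0, 0.0, 1.0])

    def test_all_points_contained(self, two_dof_set):
        tr = frame_trace(two_dof_set)
        for ax in "XYZ":
            poly = fit_boundary(tr.clouds[ax])
            assert poly.contains_many(tr.clouds[ax]).all()

    def test_octant_area_converges(self, rng):
        pts = rng.normal(size=(60000, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        pts = pts[(pts >= 0).all(axis=1)]
        errs = []
        for res in (1280, 5120):
            a = fit_boundary(pts, resolution=res).area()
            errs.append(abs(a - np.pi / 2) / (np.pi / 2))
        assert errs[1] < errs[0]  # first-order refinement
        assert errs[1] < 0.05

    def test_disconnected_cloud_auto_dilates_to_containment(self):
        a = np.array([[0.0, 0.0, 1.0]])
        b = np.array([[np.sin(0.5), 0.0, np.cos(0.5)]])  # ~29 deg away
        poly = fit_boundary(np.vstack([a, b]))
        assert poly.contains(a[0]) and poly.contains(b[0])
        assert poly.effective_dilation > 0

    def test_dilation_parameter_grows_area(self, two_dof_set):
        tr = frame_trace(two_dof_set)
        a0 = fit_boundary(tr.clouds["Z"], dilation=0)
        a1 = fit_boundary(tr.clouds["Z"], dilation=1)
        assert a0.effective_dilation == 0  # connected cloud, tight fit
        assert a1.area() > a0.area()

    def test_full_sphere_cloud_is_ambiguous(self, rng):
        pts = rng.normal(size=(5000, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        with pytest.raises(AmbiguousBoundaryError):
            fit_boundary(pts, resolution=20)

    def test_hole_is_absorbed_into_outer_polygon(self):
        # a closed ring of points: the outer perimeter must be selected and
        # the enclosed "hole" (the cap inside the ring) filled
        th = np.radians(40)
        phis = np.linspace(0, 2 * np.pi, 400)
        ring = np.c_[
            np.sin(th) * np.cos(phis), np.sin(th) * np.sin(phis),
            np.full_like(phis, np.cos(th)),
        ]
        poly = fit_boundary(ring)
        assert poly.contains([0.0, 0.0, 1.0])  # centre of the ring
        assert poly.area() > 2 * np.pi * (1 - np.cos(th))


class TestBuildSfp:
    def test_always_three_polygons(self, two_dof_set):
        sfp = build_sfp(two_dof_set)
        assert set(sfp.polygons) == {"X", "Y", "Z"}

    def test_one_dof_degenerate_rotation_axis_polygon(self, one_dof_set):
        sfp = build_sfp(one_dof_set)
        assert len(sfp.polygons["X"]) == 3  # single-patch loop
        # the other two are elongated: extent ~60 deg plus patch slop
        for ax in "YZ":
            v = sfp.polygons[ax].vertices
            assert geodesic_extent(v) > 55.0

    def test_containment_invariant(self, two_dof_set):
        sfp = build_sfp(two_dof_set)
        tr = frame_trace(two_dof_set)
        for ax in "XYZ":
            assert sfp.polygons[ax].contains_many(tr.clouds[ax]).all()

    def test_nested_sampling_monotonicity(self, two_dof_set):
        # the 5-degree grid is a strict subset of the 2.5-degree grid's poses
        sfp_full = build_sfp(two_dof_set)
        sub = generate_rom(RomSpec("two_dof", (30.0, 15.0, 0.0), "XYZ", grid_step=5.0))
        sfp_sub = build_sfp(sub)
        patch_sr = default_grid(3).areas.max()
        for ax in "XYZ":
            assert (
                sfp_sub.polygons[ax].area()
                <= sfp_full.polygons[ax].area() + patch_sr
            )

    def test_equivariance_under_global_rotation(self, rng):
        data = OrientationSet(random_orientations(rng, 30))
        g = random_orientations(rng, 1)[0]
        rotated = OrientationSet([o.compose(g) for o in data])
        tr, tr_rot = frame_trace(data), frame_trace(rotated)
        for ax in "XYZ":
            np.testing.assert_allclose(
                tr_rot.clouds[ax], tr.clouds[ax] @ g.rotation.T, atol=1e-9
            )


class TestCheckPose:
    def test_member_pose_all_inside(self, two_dof_set):
        sfp = build_sfp(two_dof_set)
        rep = check_pose(sfp, two_dof_set[17])
        assert rep.all_inside and set(rep.inside) == {"X", "Y", "Z"}

    def test_far_outside_pose_fails_some_axis(self, one_dof_set):
        sfp = build_sfp(one_dof_set)
        outside = from_euler(EulerSpec("XYZ", (0, 90, 0)))
        rep = check_pose(sfp, outside)
        assert not rep.all_inside

    def test_false_positive_construction_flagged_by_path_check(self):
        # two disjoint 1-DoF ranges about X; boundary fitting bridges the gap
        # (auto-dilation), so a gap pose passes the membership test even
        # though its rows never co-occur in one sampled pose -- the path
        # check exposes it
        angles = np.r_[np.arange(-10.0, 10.5, 1.0), np.arange(50.0, 70.5, 1.0)]
        data = OrientationSet(
            [from_euler(EulerSpec("XYZ", (a, 0, 0))) for a in angles]
        )
        sfp = build_sfp(data)
        gap_pose = from_euler(EulerSpec("XYZ", (30.0, 0, 0)))
        assert check_pose(sfp, gap_pose).all_inside
        start = data[0]
        res = check_pose_path(data, start, gap_pose, step_max=5.0)
        assert not res.viable


class TestCheckPosePath:
    def test_target_equals_start(self, one_dof_set):
        res = check_pose_path(one_dof_set, one_dof_set[0], one_dof_set[0])
        assert res.viable and len(res.path) == 1

    def test_dense_one_dof_in_range_viable(self, one_dof_set):
        start = from_euler(EulerSpec("XYZ", (0, 0, 0)))
        target = from_euler(EulerSpec("XYZ", (25, 0, 0)))
        res = check_pose_path(one_dof_set, start, target, step_max=5.0)
        assert res.viable
        # monotone path: angles increase along it
        angs = [o.angle_to(target) for o in res.path]
        assert all(b <= a + 1e-9 for a, b in zip(angs, angs[1:]))

    def test_out_of_range_not_viable(self, one_dof_set):
        start = from_euler(EulerSpec("XYZ", (0, 0, 0)))
        target = from_euler(EulerSpec("XYZ", (50, 0, 0)))
        assert not check_pose_path(one_dof_set, start, target, step_max=5.0).viable

    def test_disjoint_clusters_not_viable(self):
        a = [from_euler(EulerSpec("XYZ", (x, 0, 0))) for x in np.arange(-10.0, 11.0)]
        b = [from_euler(EulerSpec("XYZ", (x, 0, 0))) for x in np.arange(60.0, 81.0)]
        data = OrientationSet(a + b)
        assert not check_pose_path(data, a[0], b[5], step_max=5.0).viable

    def test_unanchored_start_raises(self, one_dof_set):
        far = from_euler(EulerSpec("XYZ", (120, 0, 0)))
        with pytest.raises(UnanchoredStartError):
            check_pose_path(one_dof_set, far, one_dof_set[0], step_max=5.0)


class TestCoverage:
    def setup_method(self):
        self.cov = CoverageGrid(default_grid(2))
        self.p = np.array([0.0, 0.0, 1.0])
        self.away = np.array([1.0, 0.0, 0.0])
        self.idx = self.cov.grid.locate(self.p)

    def test_single_dwell_counts_once(self):
        coverage_update(self.cov, np.array([self.p, self.p, self.p]))
        assert self.cov.counts[self.idx] == 1
        assert self.cov.intensity()[self.idx] == pytest.approx(1 / 3)

    def test_three_passes_saturate_not_fewer(self):
        for n_pass in (1, 2):
            coverage_update(self.cov, np.array([self.p, self.away]))
            assert self.cov.intensity()[self.idx] == pytest.approx(n_pass / 3)
            assert self.cov.intensity()[self.idx] < 1.0
        coverage_update(self.cov, np.array([self.p]))
        assert self.cov.intensity()[self.idx] == 1.0

    def test_saturation_is_a_ceiling(self):
        for _ in range(5):
            coverage_update(self.cov, np.array([self.p, self.away]))
        assert self.cov.counts[self.idx] == 5
        assert self.cov.intensity()[self.idx] == 1.0

    def test_empty_stream_is_noop(self):
        before = self.cov.counts.copy()
        coverage_update(self.cov, np.empty((0, 3)))
        np.testing.assert_array_equal(self.cov.counts, before)

    def test_fraction_visited(self, one_dof_set):
        tr = frame_trace(one_dof_set)
        coverage_update(self.cov, tr.clouds["Y"])
        assert 0 < self.cov.fraction_visited() < 0.2
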