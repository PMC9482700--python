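"""Homogeneous transform algebra, the marker-to-joint chain, landmark frame
fits, and exact orthogonalisation."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation as R

from sfproj import (
    FitError,
    LandmarkSet,
    Orientation,
    RigidTransform,
    ValidationError,
    fit_bone_frame,
    fit_plate_frame,
    invert,
    joint_orientation,
    orthogonalise,
)
from sfproj.transforms import _max_pairwise_dot, _ortho_step


def random_transform(rng, scale=50.0):
    return RigidTransform.from_rt(
        R.random(rng=rng).as_matrix(), rng.uniform(-scale, scale, 3)
    )


def skewed_frame(rng, skew_deg=2.0):
    """Right-handed orthonormal frame with each axis rotated by exactly
    ``skew_deg`` about a random perpendicular direction."""
    base = R.random(rng=rng).as_matrix().T
    out = []
    for a in base:
        t = rng.normal(size=3)
        t -= (t @ a) * a
        t /= np.linalg.norm(t)
        out.append(R.from_rotvec(np.radians(skew_deg) * np.cross(a, t)).as_matrix() @ a)
    out = np.array(out)
    if np.linalg.det(out) < 0:
        out[2] = -out[2]
    return out


class TestInvert:
    def test_identity(self):
        np.testing.assert_array_equal(
            invert(RigidTransform.identity()).matrix, np.eye(4)
        )

    def test_pure_rotation_inverse_is_transpose(self, rng):
        T = RigidTransform.from_rt(R.random(rng=rng).as_matrix())
        np.testing.assert_allclose(invert(T).matrix, T.matrix.T, atol=1e-15)

    def test_transpose_is_not_inverse_with_translation(self, rng):
        # the 4x4 transpose equals the inverse only at zero translation
        T = random_transform(rng)
        assert np.abs(invert(T).matrix - T.matrix.T).max() > 1.0

    def test_composition_with_inverse_is_identity(self, rng):
        for _ in range(20):
            T = random_transform(rng)
            np.testing.assert_allclose((T @ invert(T)).matrix, np.eye(4), atol=1e-12)

    def test_involution(self, rng):
        T = random_transform(rng)
        np.testing.assert_allclose(invert(invert(T)).matrix, T.matrix, atol=1e-12)

    def test_bad_bottom_row_rejected(self):
        m = np.eye(4)
        m[3, 0] = 0.1
        with pytest.raises(ValidationError):
            RigidTransform(m)


class TestJointOrientation:
    def test_all_identity(self):
        eye = RigidTransform.identity()
        o = joint_orientation(eye, eye, eye, eye, eye)
        np.testing.assert_allclose(o.m, np.eye(3), atol=1e-15)

    def test_ground_truth_round_trip(self, rng, rig_geometry):
        # inject a known joint pose through the forward model, recover it
        g = rig_geometry
        for _ in range(25):
            truth = Orientation.from_rotation(R.random(rng=rng).as_matrix())
            dACS_T_pACS = RigidTransform.from_rt(truth.m)
            markers_T_base = (
                invert(g.dACS_T_markers()) @ dACS_T_pACS @ g.pACS_T_base()
            )
            o = joint_orientation(
                markers_T_base, g.pACS_T_pPlate, g.pPlate_T_base,
                g.dACS_T_dPlate, g.dPlate_T_markers,
            )
            np.testing.assert_allclose(o.m, truth.m, atol=1e-9)

    def test_translation_invariance(self, rng, rig_geometry):
        g = rig_geometry
        markers_T_base = random_transform(rng)
        base = joint_orientation(
            markers_T_base, g.pACS_T_pPlate, g.pPlate_T_base,
            g.dACS_T_dPlate, g.dPlate_T_markers,
        )
        shifted = RigidTransform.from_rt(
            g.pPlate_T_base.rotation, g.pPlate_T_base.translation + [100, -50, 30]
        )
        moved = joint_orientation(
            markers_T_base, g.pACS_T_pPlate, shifted,
            g.dACS_T_dPlate, g.dPlate_T_markers,
        )
        np.testing.assert_allclose(moved.m, base.m, atol=1e-12)


def make_plate_landmarks(rotation, origin, rng, noise_sd=0.0):
    """Ten points spread evenly (5x2 grid) on each of the three faces meeting
    at the plate's reference corner, as a landmark protocol would place them."""
    uu, vv = np.meshgrid(np.linspace(-25, -2, 5), np.linspace(-25, -2, 2))
    grid_uv = np.c_[uu.ravel(), vv.ravel()]
    groups = {}
    for i, name in enumerate(("face_x", "face_y", "face_z")):
        j, k = (i + 1) % 3, (i + 2) % 3
        uv = grid_uv
        pts = (
            origin[None, :]
            + np.outer(uv[:, 0], rotation[:, j])
            + np.outer(uv[:, 1], rotation[:, k])
        )
        if noise_sd > 0:
            pts = pts + rng.normal(0, noise_sd, pts.shape)
        groups[name] = pts
    return LandmarkSet(groups)


class TestFitPlateFrame:
    def test_noiseless_recovery(self, rng):
        true_R = R.from_euler("XYZ", [20, -35, 50], degrees=True).as_matrix()
        origin = np.array([10.0, -5.0, 30.0])
        fit = fit_plate_frame(make_plate_landmarks(true_R, origin, rng))
        np.testing.assert_allclose(fit.transform.rotation, true_R, atol=1e-9)
        np.testing.assert_allclose(fit.transform.translation, origin, atol=1e-9)
        assert fit.max_axis_dot <= 1e-12

    def test_noisy_recovery_monte_carlo(self):
        # 0.05 mm isotropic placement noise, 10 points per face
        worst = 0.0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            true_R = R.random(rng=rng).as_matrix()
            origin = rng.uniform(-20, 20, 3)
            fit = fit_plate_frame(
                make_plate_landmarks(true_R, origin, rng, noise_sd=0.05)
            )
            for i in range(3):
                cosang = np.clip(fit.transform.rotation[:, i] @ true_R[:, i], -1, 1)
                worst = max(worst, np.degrees(np.arccos(cosang)))
        assert worst < 0.5

    def test_collinear_face_rejected(self):
        line = np.outer(np.linspace(0, 1, 5), [1.0, 0, 0])
        groups = {
            "face_x": line,
            "face_y": np.eye(3),
            "face_z": np.eye(3)[::-1],
        }
        with pytest.raises(FitError):
            fit_plate_frame(LandmarkSet(groups))

    def test_rigid_motion_equivariance(self, rng):
        true_R = R.from_euler("ZXY", [15, 40, -25], degrees=True).as_matrix()
        origin = np.array([3.0, 8.0, -2.0])
        lm = make_plate_landmarks(true_R, origin, np.random.default_rng(5))
        fit = fit_plate_frame(lm)
        G = random_transform(rng)
        moved = LandmarkSet({k: G.apply(v) for k, v in lm.groups.items()})
        fit2 = fit_plate_frame(moved)
        np.testing.assert_allclose(
            fit2.transform.matrix, (G @ fit.transform).matrix, atol=1e-9
        )


class TestFitBoneFrame:
    @staticmethod
    def cylinder_edges(axis_len=40.0, r_prox=5.0, r_dist=4.0, n=12):
        """Full edge rings of a synthetic cylindrical bone."""
        t = np.linspace(0, 2 * np.pi, n + 1)[:-1]
        prox = np.c_[r_prox * np.cos(t), r_prox * np.sin(t), np.zeros(n)]
        dist = np.c_[r_dist * np.cos(t), r_dist * np.sin(t), np.full(n, axis_len)]
        return prox, dist

    @staticmethod
    def edge_rows(axis_len=40.0, n=8):
        """Points placed along straight articular edges (ordered rows)."""
        s = np.linspace(-6.0, 6.0, n)
        prox = np.c_[s, 0.3 * s, np.zeros(n)]
        dist = np.c_[0.8 * s, -0.2 * s, np.full(n, axis_len)]
        return prox, dist

    def test_cylinder_long_axis(self):
        prox, dist = self.cylinder_edges()
        fit = fit_bone_frame(prox, dist)
        np.testing.assert_allclose(
            np.abs(fit.transform.rotation[:, 0]), [0, 0, 1], atol=1e-6
        )
        np.testing.assert_allclose(fit.transform.translation, [0, 0, 0], atol=1e-9)
        assert fit.max_axis_dot <= 1e-12

    def test_two_point_edges_interpolate(self):
        prox = np.array([[0.0, -3, 0], [0.0, 3, 0]])
        dist = np.array([[0.0, -2, 30], [0.0, 2, 30]])
        fit = fit_bone_frame(prox, dist)
        assert fit.max_point_residual == pytest.approx(0.0, abs=1e-12)

    def test_coincident_midpoints_rejected(self):
        pts = np.array([[0.0, -3, 0], [0.0, 3, 0]])
        with pytest.raises(FitError):
            fit_bone_frame(pts, pts.copy())

    def test_rigid_motion_equivariance(self, rng):
        prox, dist = self.edge_rows()
        fit = fit_bone_frame(prox, dist)
        G = random_transform(rng)
        fit2 = fit_bone_frame(G.apply(prox), G.apply(dist))
        np.testing.assert_allclose(
            fit2.transform.matrix, (G @ fit.transform).matrix, atol=1e-9
        )


class TestOrthogonalise:
    def test_idempotent_on_orthonormal_frame(self, rng):
        frame = R.random(rng=rng).as_matrix().T
        out = orthogonalise(frame.copy())
        np.testing.assert_allclose(out, frame, atol=1e-12)

    def test_two_degree_skews_converge(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            pert = skewed_frame(rng, 2.0)
            out = orthogonalise(pert)
            assert _max_pairwise_dot(out) <= 1e-12
            assert np.linalg.det(out) > 0
            moves = [
                np.degrees(np.arccos(np.clip(out[i] @ pert[i], -1, 1)))
                for i in range(3)
            ]
            assert max(moves) < 4.0  # bounded by twice the input skew

    def test_residual_monotone_over_steps(self, rng):
        a = skewed_frame(rng, 2.0)
        residuals = [_max_pairwise_dot(a)]
        for it in range(30):
            _ortho_step(a, it % 3)
            residuals.append(_max_pairwise_dot(a))
        assert all(b <= a + 1e-15 for a, b in zip(residuals, residuals[1:]))

    def test_left_handed_handling(self):
        lh = np.diag([1.0, 1.0, -1.0])
        out = orthogonalise(lh.copy())
        assert np.linalg.det(out) > 0
        with pytest.raises(FitError):
            orthogonalise(lh.copy(), fix_handedness=False)

    def test_unrecognisable_frame_rejected(self):
        bad = np.array([[1.0, 0, 0], [0.9, 0.44, 0], [0, 0, 1.0]])
        bad[1] /= np.linalg.norm(bad[1])
        with pytest.raises(FitError):
            orthogonalise(bad)
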