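"""Geometry: tip-from-pose, plane fitting, fistula frame and projections."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.transform import Rotation

from hdcmetrics.errors import (
    AmbiguousAxisError,
    DegenerateGeometryError,
    InvalidPoseError,
)
from hdcmetrics.geometry import (
    Plane,
    PoseSample,
    TipOffset,
    build_fistula_frame,
    cross_section_coords,
    fit_plane,
    project_to_axis,
    project_to_plane,
    tip_position,
)

IDENTITY_Q = np.array([1.0, 0.0, 0.0, 0.0])


def pose(p, q=IDENTITY_Q, t=0.0):
    return PoseSample(t=t, position=np.asarray(p, float), quaternion=np.asarray(q, float))


def quat_about_z(deg):
    q = Rotation.from_euler("z", deg, degrees=True).as_quat()
    return np.array([q[3], q[0], q[1], q[2]])


class TestTipPosition:
    @pytest.mark.parametrize(
        "p_sensor, q, d, expected",
        [
            ((0, 0, 0), IDENTITY_Q, (0, 0, 10), (0, 0, 10)),
            ((3, -2, 5), quat_about_z(137.0), (0, 0, 0), (3, -2, 5)),
            # 90 deg about +Z maps (10,0,0) -> (0,10,0); frozen from a hand
            # matrix-vector product R(90z) @ d + p
            ((1, 1, 1), quat_about_z(90.0), (10, 0, 0), (1, 11, 1)),
        ],
    )
    def test_examples(self, p_sensor, q, d, expected):
        tip = tip_position(pose(p_sensor, q), TipOffset(np.asarray(d, float)))
        np.testing.assert_allclose(tip, expected, atol=1e-9)

    def test_non_unit_quaternion_rejected(self):
        bad = pose((0, 0, 0), np.array([1.0, 0.1, 0.0, 0.0]))
        with pytest.raises(InvalidPoseError):
            tip_position(bad, TipOffset(np.zeros(3)))

    @given(
        d1=st.lists(st.floats(-50, 50), min_size=3, max_size=3),
        d2=st.lists(st.floats(-50, 50), min_size=3, max_size=3),
        angles=st.lists(st.floats(-180, 180), min_size=3, max_size=3),
    )
    def test_affine_in_offset(self, d1, d2, angles):
        """tip(d1 + d2) - tip(d1) equals R @ d2 for any pose."""
        rot = Rotation.from_euler("xyz", angles, degrees=True)
        q = rot.as_quat()
        sample = pose((5.0, -3.0, 2.0), np.array([q[3], q[0], q[1], q[2]]))
        d1, d2 = np.asarray(d1), np.asarray(d2)
        lhs = tip_position(sample, TipOffset(d1 + d2)) - tip_position(sample, TipOffset(d1))
        np.testing.assert_allclose(lhs, rot.as_matrix() @ d2, atol=1e-9)


def eigh_plane_oracle(points):
    """Independent total-least-squares plane via the 3x3 scatter eigenproblem."""
    pts = np.asarray(points, float)
    c = pts.mean(axis=0)
    cov = (pts - c).T @ (pts - c)
    w, v = np.linalg.eigh(cov)
    n = v[:, 0]
    return n, -float(n @ c)


class TestFitPlane:
    def test_coordinate_plane(self):
        plane = fit_plane([(0, 0, 0), (1, 0, 0), (0, 1, 0)])
        np.testing.assert_allclose(plane.coefficients(), [0, 0, 1, 0], atol=1e-12)

    def test_three_point_plane_matches_cross_product(self):
        pts = np.array([(1, 0, 0), (0, 1, 0), (0, 0, 1)], float)
        n = np.cross(pts[1] - pts[0], pts[2] - pts[0])
        n = n / np.linalg.norm(n)
        d = -n @ pts[0]
        plane = fit_plane(pts)
        np.testing.assert_allclose(plane.coefficients(), np.r_[n, d], atol=1e-12)

    def test_noisy_normal_within_one_degree(self):
        rng = np.random.default_rng(11)
        true_n = np.array([0.2, -0.3, 0.933])
        true_n /= np.linalg.norm(true_n)
        basis = np.linalg.svd(true_n[None, :])[2][1:]
        coords = rng.uniform(-40, 40, size=(50, 2))
        pts = coords @ basis + rng.normal(0, 0.1, size=(50, 3))
        plane = fit_plane(pts)
        angle = np.degrees(np.arccos(np.clip(abs(plane.normal @ true_n), 0, 1)))
        assert angle < 1.0

    def test_exact_coplanar_residual_zero(self):
        rng = np.random.default_rng(3)
        basis = np.array([[1.0, 0.0, 0.5], [0.0, 1.0, -0.25]])
        pts = rng.uniform(-10, 10, (20, 2)) @ basis + np.array([1.0, 2.0, 3.0])
        plane = fit_plane(pts)
        assert np.max(np.abs(plane.signed_distance(pts))) < 1e-10

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(5)
        pts = np.c_[rng.uniform(-10, 10, (12, 2)), rng.normal(0, 0.05, 12)]
        rot = Rotation.from_euler("xyz", [20, -35, 60], degrees=True)
        moved = pts @ rot.as_matrix().T + np.array([5.0, -2.0, 9.0])
        n0 = fit_plane(pts).normal
        n1 = fit_plane(moved).normal
        expected = rot.as_matrix() @ n0
        # equal up to the sign convention
        assert min(np.linalg.norm(n1 - expected), np.linalg.norm(n1 + expected)) < 1e-9

    def test_collinear_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            fit_plane([(0, 0, 0), (1, 1, 1), (2, 2, 2), (3, 3, 3)])

    def test_too_few_points_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            fit_plane([(0, 0, 0), (1, 0, 0)])

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            basis = rng.normal(size=(2, 3))
            pts = rng.uniform(-20, 20, (15, 2)) @ basis + rng.normal(size=3)
            pts += rng.normal(0, 0.01, pts.shape)
            plane = fit_plane(pts)
            n, d = eigh_plane_oracle(pts)
            if np.linalg.norm(plane.normal - n) > np.linalg.norm(plane.normal + n):
                n, d = -n, -d
            np.testing.assert_allclose(plane.normal, n, atol=1e-8)
            np.testing.assert_allclose(plane.d, d, atol=1e-8)


class TestFistulaFrame:
    def test_axis_aligned_rectangle(self, axis_frame):
        np.testing.assert_allclose(axis_frame.axis_direction, [1, 0, 0], atol=1e-12)
        np.testing.assert_allclose(axis_frame.u_lat, [0, 1, 0], atol=1e-12)
        np.testing.assert_allclose(axis_frame.v_vert, [0, 0, 1], atol=1e-12)
        np.testing.assert_allclose(axis_frame.axis_start, [-75, 0, 0], atol=1e-12)
        np.testing.assert_allclose(axis_frame.axis_end, [75, 0, 0], atol=1e-12)

    def test_rotated_rectangle_frame_follows(self):
        rot = Rotation.from_euler("z", 30, degrees=True).as_matrix()
        vertices = np.array(
            [[-75.0, -7.0, 0.0], [75.0, -7.0, 0.0], [75.0, 7.0, 0.0], [-75.0, 7.0, 0.0]]
        ) @ rot.T
        frame = build_fistula_frame(vertices, radius=7.0)
        np.testing.assert_allclose(frame.axis_direction, rot @ [1, 0, 0], atol=1e-9)
        np.testing.assert_allclose(frame.u_lat, rot @ [0, 1, 0], atol=1e-9)
        np.testing.assert_allclose(frame.v_vert, [0, 0, 1], atol=1e-9)

    def test_orthonormal_right_handed(self, axis_frame):
        basis = np.column_stack(
            [axis_frame.axis_direction, axis_frame.u_lat, axis_frame.v_vert]
        )
        np.testing.assert_allclose(basis.T @ basis, np.eye(3), atol=1e-9)
        assert np.linalg.det(basis) == pytest.approx(1.0, abs=1e-9)

    def test_square_is_ambiguous(self):
        square = [[-7, -7, 0], [7, -7, 0], [7, 7, 0], [-7, 7, 0]]
        with pytest.raises(AmbiguousAxisError):
            build_fistula_frame(square, radius=7.0)


class TestProjections:
    def test_plane_projection_examples(self, skin_plane):
        np.testing.assert_allclose(
            project_to_plane((3, 4, 5), skin_plane), (3, 4, 0), atol=1e-12
        )
        diag = Plane.from_coefficients(1, 1, 1, -1)
        np.testing.assert_allclose(
            project_to_plane((1, 1, 1), diag), (1 / 3, 1 / 3, 1 / 3), atol=1e-12
        )

    def test_plane_projection_idempotent(self, skin_plane):
        p = project_to_plane((7.0, -2.0, 13.0), skin_plane)
        np.testing.assert_allclose(project_to_plane(p, skin_plane), p, atol=1e-12)
        assert abs(skin_plane.signed_distance(p)) < 1e-9

    def test_axis_projection_examples(self, axis_frame):
        np.testing.assert_allclose(
            project_to_axis((12.0, 0.0, 0.0), axis_frame), (12, 0, 0), atol=1e-12
        )
        np.testing.assert_allclose(
            project_to_axis((0.0, 5.0, 0.0), axis_frame), (0, 0, 0), atol=1e-12
        )

    def test_projections_minimize_distance(self, axis_frame):
        """Projections beat a dense candidate scan (brute-force minimizer)."""
        rng = np.random.default_rng(9)
        plane = Plane.from_coefficients(0.3, -0.4, 0.866, 5.0)
        for _ in range(10):
            p = rng.uniform(-30, 30, 3)
            foot = project_to_plane(p, plane)
            # candidates: foot plus in-plane grid perturbations
            b1 = np.cross(plane.normal, [1, 0, 0])
            b1 /= np.linalg.norm(b1)
            b2 = np.cross(plane.normal, b1)
            for da in np.linspace(-1, 1, 21):
                for db in np.linspace(-1, 1, 21):
                    cand = foot + da * b1 + db * b2
                    assert np.linalg.norm(p - foot) <= np.linalg.norm(p - cand) + 1e-6

            ax = project_to_axis(p, axis_frame)
            ts = np.linspace(-200, 200, 4001)
            line = axis_frame.axis_start + ts[:, None] * axis_frame.axis_direction
            best = np.min(np.linalg.norm(line - p, axis=1))
            assert np.linalg.norm(p - ax) <= best + 1e-6

    def test_cross_section_examples(self, axis_frame):
        assert cross_section_coords((42.0, 3.0, -4.0), axis_frame) == pytest.approx((3, -4))
        assert cross_section_coords((10.0, 0.0, 0.0), axis_frame) == pytest.approx((0, 0))

    @given(
        p=st.lists(st.floats(-100, 100), min_size=3, max_size=3),
    )
    def test_cross_section_preserves_axis_distance(self, p, axis_frame):
        x, y = cross_section_coords(np.asarray(p), axis_frame)
        d = np.linalg.norm(np.asarray(p) - project_to_axis(np.asarray(p), axis_frame))
        assert np.hypot(x, y) == pytest.approx(d, abs=1e-9)
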