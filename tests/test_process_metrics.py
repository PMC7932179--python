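"""Process metrics: durations, path length, velocity, angles, accuracy."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from hdcmetrics.errors import UndefinedLateralAngleError
from hdcmetrics.geometry import SimGeometry, build_fistula_frame, fit_plane
from hdcmetrics.process_metrics import (
    angle_change_rate,
    average_insertion_angle,
    average_velocity,
    insertion_angle_series,
    lateral_angle,
    path_length,
    phase_time,
    start_point_accuracy,
)
from hdcmetrics.segmentation import segment
from hdcmetrics.synthetic import TrialConfig, generate_trial
from hdcmetrics.pipeline import analyze_trial

from conftest import make_straight_config


def trial_from_tips(times, tips, em, skin=None):
    return segment(np.asarray(times, float), np.asarray(tips, float), em, skin_plane=skin)


def uniform_times(n, rate=40.0, start=0.0):
    return start + np.arange(n) / rate


class TestTimeAndPath:
    def test_phase_times_from_event_times(self):
        times = uniform_times(401)
        tips = np.tile([0.0, 0.0, -1.0], (401, 1)) + np.linspace(0, 1, 401)[:, None]
        trial = trial_from_tips(times, tips, [1.0, 4.0, 5.0, 8.0])
        assert phase_time(trial, 1) == pytest.approx(3.0)
        assert phase_time(trial, 3) == pytest.approx(3.0)

    def test_straight_segment_any_subdivision(self):
        for n in (2, 5, 50):
            times = uniform_times(3 * n + 3)
            frac = np.linspace(0, 1, len(times))
            tips = np.outer(frac, [3.0, 4.0, 0.0])
            em = [times[0], times[n], times[2 * n], times[-1]]
            trial = trial_from_tips(times, tips, em)
            total = sum(
                path_length(trial, p) for p in (1, 3)
            ) + np.sum(np.linalg.norm(np.diff(trial.phase_tips(2), axis=0), axis=1))
            assert total == pytest.approx(5.0, rel=1e-12)

    def test_zigzag_path_length(self):
        tips = np.array(
            [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0], [0, 1, 0], [0, 1, 0], [0, 1, 0]],
            float,
        )
        times = uniform_times(7)
        em = [times[0], times[3], times[4], times[6]]
        trial = trial_from_tips(times, tips, em)
        assert path_length(trial, 1) == pytest.approx(3.0)
        assert path_length(trial, 3) == pytest.approx(0.0)

    def test_velocity_is_path_over_time(self):
        times = uniform_times(401)
        tips = np.outer(np.linspace(0, 10, 401), [1.0, 0.0, 0.0])
        trial = trial_from_tips(times, tips, [1.0, 4.0, 5.0, 8.0])
        for p in (1, 3):
            assert average_velocity(trial, p) == pytest.approx(
                path_length(trial, p) / phase_time(trial, p), abs=1e-12
            )


class TestInsertionAngle:
    def descent_trial(self, angle_deg, skin):
        """Straight descent from the origin at the given elevation angle."""
        times = uniform_times(161)
        a = np.radians(angle_deg)
        s = np.linspace(0, 20, 161)
        tips = np.column_stack([s * np.cos(a), np.zeros_like(s), -s * np.sin(a)])
        em = [times[0], times[60], times[100], times[160]]
        return trial_from_tips(times, tips, em, skin=skin)

    @pytest.mark.parametrize("angle", [45.0, 30.0, 60.0])
    def test_straight_descent_recovers_angle(self, angle, skin_plane):
        trial = self.descent_trial(angle, skin_plane)
        for p in (1, 3):
            assert average_insertion_angle(trial, p, skin_plane) == pytest.approx(
                angle, abs=1e-9
            )

    def test_in_plane_slide_is_zero(self, skin_plane):
        times = uniform_times(121)
        tips = np.column_stack(
            [np.linspace(1, 20, 121), np.linspace(0, 5, 121), np.zeros(121)]
        )
        trial = trial_from_tips(
            times, tips, [times[0], times[40], times[80], times[-1]], skin=skin_plane
        )
        assert average_insertion_angle(trial, 1, skin_plane) == pytest.approx(0.0)

    def test_mixed_path_matches_per_sample_oracle(self, skin_plane):
        rng = np.random.default_rng(4)
        times = uniform_times(161)
        tips = np.column_stack(
            [
                np.linspace(1, 30, 161),
                rng.normal(0, 1, 161),
                -np.abs(np.linspace(0.5, 12, 161)),
            ]
        )
        trial = trial_from_tips(
            times, tips, [times[0], times[60], times[100], times[-1]], skin=skin_plane
        )
        entry = trial.p_entry
        i, j = trial.phase_slice(1)
        expected = []
        for p in trial.tips[i : j + 1]:
            base = np.hypot(p[0] - entry[0], p[1] - entry[1])
            expected.append(np.degrees(np.arctan2(-p[2], base)))
        got = average_insertion_angle(trial, 1, skin_plane)
        assert got == pytest.approx(np.mean(expected), abs=1e-9)

    def test_sample_above_skin_is_negative(self, skin_plane):
        times = uniform_times(8)
        tips = np.column_stack(
            [np.linspace(0, 7, 8), np.zeros(8), np.array([0, -1, -2, -1, 0, 1, 1, 0.5])]
        )
        trial = trial_from_tips(
            times, tips, [times[0], times[3], times[5], times[-1]], skin=skin_plane
        )
        series = insertion_angle_series(trial, 3, skin_plane)
        assert np.all(series[:-1] < 0)  # tips above the plane


class TestAngleChangeRate:
    def test_constant_angle_rate_zero(self, skin_plane):
        trial = TestInsertionAngle().descent_trial(40.0, skin_plane)
        assert angle_change_rate(trial, 1, skin_plane) == pytest.approx(0.0, abs=1e-9)

    def test_telescoping_identity(self, skin_plane):
        """Direct summation equals (alpha_end - alpha_start) / (N dt) on
        uniformly sampled data."""
        rng = np.random.default_rng(8)
        for _ in range(50):
            n = rng.integers(30, 120)
            times = uniform_times(4 * n + 1)
            tips = np.column_stack(
                [
                    np.linspace(1, 25, len(times)),
                    rng.normal(0, 0.5, len(times)),
                    -np.abs(rng.uniform(0.5, 10, len(times))),
                ]
            )
            em = [times[0], times[n], times[2 * n], times[-1]]
            trial = trial_from_tips(times, tips, em, skin=skin_plane)
            for phase in (1, 3):
                series = insertion_angle_series(trial, phase, skin_plane)
                i, j = trial.phase_slice(phase)
                n_phase = j - i + 1
                dt = 1.0 / 40.0
                telescoped = (series[-1] - series[0]) / (n_phase * dt)
                assert angle_change_rate(trial, phase, skin_plane) == pytest.approx(
                    telescoped, abs=1e-9
                )

    def test_sign_negative_for_decreasing_angle(self, skin_plane):
        times = uniform_times(161)
        ang = np.radians(np.linspace(55, 35, 161))
        s = np.linspace(1, 20, 161)
        tips = np.column_stack([s * np.cos(ang), np.zeros(161), -s * np.sin(ang)])
        trial = trial_from_tips(
            times, tips, [times[0], times[60], times[100], times[-1]], skin=skin_plane
        )
        assert angle_change_rate(trial, 1, skin_plane) < 0


class TestStartAccuracyAndLateralAngle:
    def test_tip_over_axis_is_zero(self, axis_frame):
        times = uniform_times(10)
        tips = np.column_stack([np.linspace(0, 5, 10), np.zeros(10), np.full(10, 5.0)])
        trial = trial_from_tips(times, tips, [times[0], times[3], times[6], times[-1]])
        assert start_point_accuracy(trial, 1, axis_frame) == pytest.approx(0.0)

    def test_axis_aligned_offset(self, axis_frame):
        times = uniform_times(10)
        tips = np.tile([10.0, 3.0, 5.0], (10, 1)) + np.outer(
            np.linspace(0, 1, 10), [1.0, 0, 0]
        )
        trial = trial_from_tips(times, tips, [times[0], times[3], times[6], times[-1]])
        assert start_point_accuracy(trial, 1, axis_frame) == pytest.approx(3.0)

    def test_motion_parallel_to_axis_is_zero(self, axis_frame):
        times = uniform_times(10)
        tips = np.column_stack([np.linspace(0, 9, 10), np.full(10, 2.0), np.zeros(10)])
        trial = trial_from_tips(times, tips, [times[0], times[3], times[6], times[-1]])
        assert lateral_angle(trial, 1, axis_frame) == pytest.approx(0.0)

    def test_straight_toward_axis_is_plus_ninety(self, axis_frame):
        times = uniform_times(10)
        tips = np.column_stack(
            [np.full(10, 5.0), np.linspace(4.0, 1.0, 10), np.zeros(10)]
        )
        trial = trial_from_tips(times, tips, [times[0], times[3], times[6], times[-1]])
        assert lateral_angle(trial, 1, axis_frame) == pytest.approx(90.0)

    def test_motion_away_from_axis_is_negative(self, axis_frame):
        times = uniform_times(10)
        tips = np.column_stack(
            [np.linspace(0, 9, 10), np.linspace(1.0, 4.0, 10), np.zeros(10)]
        )
        trial = trial_from_tips(times, tips, [times[0], times[3], times[6], times[-1]])
        assert lateral_angle(trial, 1, axis_frame) < 0

    def test_zero_displacement_undefined(self, axis_frame):
        times = uniform_times(10)
        tips = np.tile([5.0, 3.0, 0.0], (10, 1))
        trial = trial_from_tips(times, tips, [times[0], times[3], times[6], times[-1]])
        with pytest.raises(UndefinedLateralAngleError):
            lateral_angle(trial, 1, axis_frame)


class TestComputeAll:
    def test_deterministic(self, noiseless_trial):
        t = noiseless_trial
        out1 = analyze_trial(
            t.times, t.sensor_positions, t.quaternions, t.annotation, t.geometry
        )[1]
        out2 = analyze_trial(
            t.times, t.sensor_positions, t.quaternions, t.annotation, t.geometry
        )[1]
        assert out1 == out2

    def test_consistency_v_times_t_equals_pl(self, noisy_trial):
        t = noisy_trial
        _, metrics, _ = analyze_trial(
            t.times, t.sensor_positions, t.quaternions, t.annotation, t.geometry
        )
        for phase in (1, 3):
            m = metrics[phase]
            assert m.v * m.t == pytest.approx(m.pl, abs=1e-9)

    def test_pl_at_least_chord(self, noisy_trial):
        t = noisy_trial
        seg, metrics, _ = analyze_trial(
            t.times, t.sensor_positions, t.quaternions, t.annotation, t.geometry
        )
        for phase in (1, 3):
            i, j = seg.phase_slice(phase)
            chord = np.linalg.norm(seg.tips[j] - seg.tips[i])
            assert metrics[phase].pl >= chord - 1e-12

    def test_rigid_rotation_invariance(self):
        """All metrics are unchanged when trajectory and geometry rotate
        together (angles to 1e-6 deg, lengths to 1e-9 mm)."""
        cfg = make_straight_config(35.0, beta_drift_deg=4.0)
        trial = generate_trial(cfg)
        base = analyze_trial(
            trial.times,
            trial.sensor_positions,
            trial.quaternions,
            trial.annotation,
            trial.geometry,
        )[1]

        rot = Rotation.from_euler("z", 40, degrees=True)
        Rm = rot.as_matrix()
        geo = trial.geometry
        skin2 = fit_plane(geo.skin_points @ Rm.T)
        frame2 = build_fistula_frame(geo.frame.vertices @ Rm.T, radius=geo.frame.radius)
        geo2 = SimGeometry(skin=skin2, frame=frame2, tip_offset=geo.tip_offset)
        q = trial.quaternions
        rot_all = rot * Rotation.from_quat(q[:, [1, 2, 3, 0]])
        q2 = rot_all.as_quat()[:, [3, 0, 1, 2]]
        moved = analyze_trial(
            trial.times,
            trial.sensor_positions @ Rm.T,
            q2,
            trial.annotation,
            geo2,
        )[1]
        for phase in (1, 3):
            a, b = base[phase], moved[phase]
            assert b.pl == pytest.approx(a.pl, abs=1e-9)
            assert b.t == a.t
            assert b.alpha == pytest.approx(a.alpha, abs=1e-6)
            assert b.alpha_dot == pytest.approx(a.alpha_dot, abs=1e-6)
            assert b.a == pytest.approx(a.a, abs=1e-9)
            assert b.beta == pytest.approx(a.beta, abs=1e-6)

    def test_time_shift_invariance(self):
        cfg = make_straight_config(35.0)
        trial = generate_trial(cfg)
        base = analyze_trial(
            trial.times,
            trial.sensor_positions,
            trial.quaternions,
            trial.annotation,
            trial.geometry,
        )[1]
        from hdcmetrics.segmentation import EventAnnotation

        ann2 = EventAnnotation(
            cam_times=trial.annotation.cam_times + 10.0,
            em_anchor_times=trial.annotation.em_anchor_times + 10.0,
        )
        shifted = analyze_trial(
            trial.times + 10.0,
            trial.sensor_positions,
            trial.quaternions,
            ann2,
            trial.geometry,
        )[1]
        for phase in (1, 3):
            assert shifted[phase].as_dict() == pytest.approx(base[phase].as_dict())
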