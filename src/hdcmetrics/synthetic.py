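"""Synthetic cannulation-trial generator.

Emulates the physical training simulator — a straight artificial fistula
(inner radius 7 mm, length 150 mm) under a flat artificial skin layer, a
needle-tip electromagnetic sensor sampled at 40 Hz, and two 15 fps cameras
whose clock lags the tracker by an unknown constant delay — so that every
analysis module can be exercised, with ground truth, without hardware.

A generated trial follows the four-event, three-phase task:

* approach (pre-roll, above the skin, discarded by trimming),
* Phase 1 [T0, T1]: straight descent from the skin entry point at the
  configured insertion angle with lateral drift, optional
  retract-and-reinsert cycles, optional overshoot past the bottom wall,
  ending at a flashback point inside the lumen,
* Phase 2 [T1, T2]: stationary tip while the needle rolls 180 degrees
  about its own axis,
* Phase 3 [T2, T3]: the needle levels out and advances toward a configured
  final cross-section position, optionally overshooting beyond the lumen
  wall (planted infiltration),
* run-out (post-roll, discarded by trimming).

Sensor poses are back-computed so that ``tip_position`` exactly reproduces
the (noisy) tip path; isotropic Gaussian noise is applied to the tip track.
Event times are placed on the common 40 Hz / 15 fps grid (multiples of
0.2 s), so camera annotations are exact frame instants offset by the
constant delay; ground truth stores the noiseless path and the true
metrics computed from it by generator-local closed-form/loop arithmetic
(independent of the analysis modules).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import InfeasibleScenarioError
from .geometry import SimGeometry, TipOffset, build_fistula_frame, fit_plane
from .segmentation import EventAnnotation

__all__ = [
    "TrialConfig",
    "GroundTruth",
    "SimulatedTrial",
    "Cohort",
    "default_geometry",
    "generate_trial",
    "generate_cohort",
    "generate_regression_cohort",
]

_GRID = 0.2  # s; common multiple of the 40 Hz and 15 fps sample periods


@dataclass(frozen=True)
class TrialConfig:
    """Scenario parameters of one synthetic trial (mm, s, degrees).

    Phase durations (not speeds) are the primary skill controls because the
    reference cohort statistics are reported as durations and path lengths;
    tip speed falls out as path length / duration.
    """

    seed: int = 0
    sample_rate_hz: float = 40.0
    camera_fps: float = 15.0
    # geometry
    fistula_radius_mm: float = 7.0
    fistula_length_mm: float = 150.0
    fistula_depth_mm: float = 10.0  # lumen axis below the skin surface
    tip_offset_mm: tuple = (0.0, 0.0, 18.0)
    # skill / scenario
    entry_lateral_mm: float = 3.0  # signed lateral entry offset from the axis
    entry_axial_mm: float = -20.0
    alpha1_deg: float = 55.0
    alpha3_deg: float = 35.0  # descent angle of the phase-3 dip (level_out only)
    beta_drift_deg: float = 3.0  # >0 drifts toward the axis, <0 away
    phase1_s: float = 4.4
    rotation_pause_s: float = 1.0
    phase3_s: float = 3.0
    n_retractions: int = 0
    retraction_depth_mm: float = 2.0
    flashback_offset_mm: float = 2.0  # flashback depth above the lumen axis
    phase1_overshoot_mm: float = 0.0  # past the bottom wall during Phase 1
    infiltration_depth_mm: float = 0.0  # past the lumen wall during Phase 3
    infiltration_side: int = -1  # -1 bottom, +1 top
    advance3_mm: float = 12.0  # axial advance during Phase 3
    final_offset_mm: tuple = (0.0, 0.0)  # final (lateral, vertical) from the axis
    level_out: bool = True  # False: Phase 3 continues straight along the Phase-1 line
    noise_sd_mm: float = 0.05
    camera_delay_s: float = 0.1949
    pre_roll_s: float = 0.6
    post_roll_s: float = 0.4

    def __post_init__(self):
        if self.sample_rate_hz <= 0 or self.camera_fps <= 0:
            raise ValueError("sampling rates must be positive")
        if self.noise_sd_mm < 0:
            raise ValueError("noise_sd_mm must be non-negative")
        if not (0.0 < self.alpha1_deg < 90.0 and 0.0 < self.alpha3_deg < 90.0):
            raise ValueError("insertion angles must lie in (0, 90) degrees")
        if self.infiltration_side not in (-1, 1):
            raise ValueError("infiltration_side must be -1 (bottom) or +1 (top)")


@dataclass(frozen=True)
class GroundTruth:
    """Everything the generator knows exactly about one trial."""

    em_event_times: np.ndarray  # T0..T3, tracker clock
    cam_event_times: np.ndarray
    t_delay: float
    times: np.ndarray  # full sample grid
    noiseless_tips: np.ndarray  # (N, 3) before noise
    entry_point: np.ndarray
    metrics: dict  # phase -> dict of the seven process metrics
    risk_p1: tuple
    risk_p3: tuple
    final_pos: tuple
    entered_fistula: bool
    infiltrated: dict  # phase -> bool
    infiltration_class: dict  # phase -> none|top|bottom
    success: bool


@dataclass(frozen=True)
class SimulatedTrial:
    """A generated pose stream plus annotation, geometry and ground truth."""

    times: np.ndarray
    sensor_positions: np.ndarray  # (N, 3)
    quaternions: np.ndarray  # (N, 4) scalar-first
    annotation: EventAnnotation
    ground_truth: GroundTruth
    geometry: SimGeometry
    config: TrialConfig

    def tip_trajectory(self) -> tuple[np.ndarray, np.ndarray]:
        """(times, tips) recovered from the emitted poses via P_sensor + R d."""
        rot = Rotation.from_quat(self.quaternions[:, [1, 2, 3, 0]])
        offsets = np.tile(self.geometry.tip_offset.d, (len(self.times), 1))
        return self.times, self.sensor_positions + rot.apply(offsets)


@dataclass(frozen=True)
class Cohort:
    """A set of generated trials sharing one simulator geometry."""

    trials: list  # of (subject_id, trial_id, SimulatedTrial)
    geometry: SimGeometry
    manifest: pd.DataFrame
    seed: int


def default_geometry(config: TrialConfig = TrialConfig()) -> SimGeometry:
    """Canonical calibrated geometry: skin plane z = 0, axis along +X.

    The fistula mid-plane rectangle is horizontal at the lumen-axis depth;
    skin calibration points span the working area of the skin surface.
    """
    z_axis = -config.fistula_depth_mm
    hl = config.fistula_length_mm / 2.0
    r = config.fistula_radius_mm
    vertices = np.array(
        [
            [-hl, -r, z_axis],
            [hl, -r, z_axis],
            [hl, r, z_axis],
            [-hl, r, z_axis],
        ]
    )
    frame = build_fistula_frame(vertices, radius=r, length=config.fistula_length_mm)
    skin_points = np.array(
        [[-60.0, -30.0, 0.0], [60.0, -30.0, 0.0], [60.0, 30.0, 0.0],
         [-60.0, 30.0, 0.0], [0.0, 0.0, 0.0]]
    )
    skin = fit_plane(skin_points)
    return SimGeometry(
        skin=skin,
        frame=frame,
        tip_offset=TipOffset(np.asarray(config.tip_offset_mm, dtype=float)),
        skin_points=skin_points,
    )


def _quantize_duration(t: float) -> float:
    """Snap a duration onto the common 40 Hz / 15 fps grid (>= one cell)."""
    return max(_GRID, round(t / _GRID) * _GRID)


def _arc_waypoint_path(waypoints: np.ndarray, fractions: np.ndarray) -> np.ndarray:
    """Constant-speed positions along a piecewise-linear waypoint path.

    ``fractions`` in [0, 1] are arc-length fractions of the total path.
    """
    seg = np.diff(waypoints, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    if total <= 0:
        return np.repeat(waypoints[:1], len(fractions), axis=0)
    s = np.clip(fractions, 0.0, 1.0) * total
    out = np.empty((len(s), waypoints.shape[1]))
    idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg_len) - 1)
    for k, (i, si) in enumerate(zip(idx, s)):
        if seg_len[i] == 0:
            out[k] = waypoints[i]
        else:
            frac = (si - cum[i]) / seg_len[i]
            out[k] = waypoints[i] + frac * seg[i]
    return out


def _shaft_rotation(direction: np.ndarray, roll: float) -> Rotation:
    """Orientation whose sensor +z axis points along ``direction``.

    ``roll`` rotates the sensor about its own z (the needle shaft), which is
    how the 180-degree bevel rotation of Phase 2 is realized.
    """
    w = direction / np.linalg.norm(direction)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(w @ ref) > 0.99:
        ref = np.array([1.0, 0.0, 0.0])
    u = np.cross(ref, w)
    u /= np.linalg.norm(u)
    v = np.cross(w, u)
    base = Rotation.from_matrix(np.column_stack([u, v, w]))
    return base * Rotation.from_euler("z", roll)


def _phase1_profile(
    cfg: TrialConfig, s_first: float, s_fb: float, s_entry: float
) -> np.ndarray:
    """1-D arc-position waypoints (distance along the insertion line).

    Retract-and-reinsert search cycles are placed strictly before the lumen
    entry distance ``s_entry`` — searching for the vessel happens before the
    needle first enters it, so the cycles do not themselves cross back out
    of the lumen.
    """
    ws = [0.0]
    n = max(0, int(cfg.n_retractions))
    rd = cfg.retraction_depth_mm
    s_search = max(0.0, s_entry - 0.5)
    for k in range(1, n + 1):
        fk = k / (n + 1) * s_search
        if fk - rd <= ws[-1]:
            continue
        ws.extend([fk, fk - rd])
    ws.append(s_first)
    if s_first > s_fb:  # overshoot past the bottom wall, then retract to flashback
        ws.append(s_fb)
    return np.asarray(ws)


def generate_trial(config: TrialConfig, rng: np.random.Generator | None = None) -> SimulatedTrial:
    """Generate one synthetic trial (pose stream, annotation, ground truth)."""
    cfg = config
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    geometry = default_geometry(cfg)
    z_axis = -cfg.fistula_depth_mm
    r = cfg.fistula_radius_mm

    alpha1 = math.radians(cfg.alpha1_deg)
    sin1, cos1 = math.sin(alpha1), math.cos(alpha1)
    y_e = cfg.entry_lateral_mm
    entry = np.array([cfg.entry_axial_mm, y_e, 0.0])

    # horizontal heading: +x rotated toward (beta > 0) or away from the axis
    side = 1.0 if y_e >= 0 else -1.0
    gamma = math.radians(-side * cfg.beta_drift_deg)
    h1 = np.array([math.cos(gamma), math.sin(gamma), 0.0])
    u1 = np.array([cos1 * h1[0], cos1 * h1[1], -sin1])

    z_fb = z_axis + cfg.flashback_offset_mm
    if z_fb >= 0 or z_fb <= z_axis - r:
        raise InfeasibleScenarioError("flashback depth outside the tissue/lumen")
    s_fb = -z_fb / sin1
    p_fb = entry + u1 * s_fb
    if math.hypot(p_fb[1], p_fb[2] - z_axis) >= r:
        raise InfeasibleScenarioError(
            "flashback point misses the lumen; reduce entry offset or drift"
        )
    if cfg.phase1_overshoot_mm > 0:
        s_first = (cfg.fistula_depth_mm + r + cfg.phase1_overshoot_mm) / sin1
    else:
        s_first = s_fb

    # distance along the insertion line at which the tip first enters the lumen
    a_cf, b_cf = cos1 * h1[1], sin1
    qa = a_cf * a_cf + b_cf * b_cf
    qb = 2.0 * (y_e * a_cf - cfg.fistula_depth_mm * b_cf)
    qc = y_e * y_e + cfg.fistula_depth_mm**2 - r * r
    disc = qb * qb - 4 * qa * qc
    if disc <= 0:
        raise InfeasibleScenarioError("insertion line never enters the lumen")
    s_entry = (-qb - math.sqrt(disc)) / (2 * qa)

    t1 = _quantize_duration(cfg.phase1_s)
    t2 = _quantize_duration(cfg.rotation_pause_s)
    t3 = _quantize_duration(cfg.phase3_s)
    pre = _quantize_duration(cfg.pre_roll_s)
    post = _quantize_duration(cfg.post_roll_s)
    T = np.array([pre, pre + t1, pre + t1 + t2, pre + t1 + t2 + t3])
    dt = 1.0 / cfg.sample_rate_hz
    n_samples = int(round((T[3] + post) / dt)) + 1
    times = np.arange(n_samples) * dt

    # --- noiseless tip path -------------------------------------------------
    tips = np.empty((n_samples, 3))
    dirs = np.empty((n_samples, 3))
    rolls = np.zeros(n_samples)

    profile1 = _phase1_profile(cfg, s_first, s_fb, s_entry)

    # phase 3 waypoints
    if cfg.level_out:
        w0 = p_fb
        x_adv = cfg.advance3_mm
        final = np.array(
            [p_fb[0] + x_adv, cfg.final_offset_mm[0], z_axis + cfg.final_offset_mm[1]]
        )
        if cfg.infiltration_depth_mm > 0:
            z_deep = z_axis + cfg.infiltration_side * (r + cfg.infiltration_depth_mm)
        else:
            # mild dip below the lumen axis while leveling out
            z_deep = z_axis - 0.3 * r
        alpha3 = math.radians(cfg.alpha3_deg)
        dx_dip = abs(p_fb[2] - z_deep) / math.tan(alpha3) if cfg.infiltration_side < 0 else 0.5 * x_adv
        dx_dip = min(max(dx_dip, 0.2 * x_adv), 0.8 * x_adv)
        frac = dx_dip / x_adv
        w1 = np.array(
            [p_fb[0] + dx_dip, p_fb[1] + frac * (final[1] - p_fb[1]), z_deep]
        )
        waypoints3 = np.array([w0, w1, final])
    else:
        final = p_fb + u1 * cfg.advance3_mm
        waypoints3 = np.array([p_fb, final])

    pre_speed = 8.0  # mm/s approach speed above the skin
    for i, t in enumerate(times):
        if t < T[0]:
            tips[i] = entry - u1 * pre_speed * (T[0] - t)
            dirs[i] = u1
        elif t <= T[1]:
            frac = (t - T[0]) / t1
            tips[i] = entry + u1 * _arc_waypoint_path(
                profile1[:, None], np.array([frac])
            )[0, 0]
            dirs[i] = u1
        elif t <= T[2]:
            tips[i] = p_fb
            dirs[i] = u1
            rolls[i] = math.pi * (t - T[1]) / t2
        elif t <= T[3]:
            frac = (t - T[2]) / t3
            tips[i] = _arc_waypoint_path(waypoints3, np.array([frac]))[0]
            seg = waypoints3[-1] - waypoints3[0] if not cfg.level_out else None
            if cfg.level_out:
                # direction of the current linear segment
                seg = (
                    waypoints3[1] - waypoints3[0]
                    if frac * _path_len(waypoints3) <= np.linalg.norm(waypoints3[1] - waypoints3[0])
                    else waypoints3[2] - waypoints3[1]
                )
            dirs[i] = seg / np.linalg.norm(seg)
            rolls[i] = math.pi
        else:
            tips[i] = tips[i - 1]
            dirs[i] = dirs[i - 1]
            rolls[i] = math.pi

    noisy_tips = tips + rng.normal(0.0, cfg.noise_sd_mm, size=tips.shape)

    # back-compute sensor poses: P_sensor = P_tip - R d
    d = np.asarray(cfg.tip_offset_mm, dtype=float)
    quats = np.empty((n_samples, 4))
    sensor = np.empty((n_samples, 3))
    for i in range(n_samples):
        rot = _shaft_rotation(dirs[i], rolls[i])
        q = rot.as_quat()  # (x, y, z, w)
        quats[i] = [q[3], q[0], q[1], q[2]]
        sensor[i] = noisy_tips[i] - rot.apply(d)

    cam_times = T + cfg.camera_delay_s
    annotation = EventAnnotation(cam_times=cam_times, em_anchor_times=T[:2].copy())

    event_idx = np.array([int(round(t / dt)) for t in T])
    gt_metrics = {
        1: _true_phase_metrics(times, tips, event_idx, 1, entry, z_axis),
        3: _true_phase_metrics(times, tips, event_idx, 3, entry, z_axis),
    }
    outcome = _true_outcomes(times, tips, event_idx, z_axis, r)

    ground_truth = GroundTruth(
        em_event_times=T,
        cam_event_times=cam_times,
        t_delay=cfg.camera_delay_s,
        times=times,
        noiseless_tips=tips,
        entry_point=entry,
        metrics=gt_metrics,
        **outcome,
    )
    return SimulatedTrial(
        times=times,
        sensor_positions=sensor,
        quaternions=quats,
        annotation=annotation,
        ground_truth=ground_truth,
        geometry=geometry,
        config=cfg,
    )


def _path_len(waypoints: np.ndarray) -> float:
    return float(np.sum(np.linalg.norm(np.diff(waypoints, axis=0), axis=1)))


def _true_phase_metrics(times, tips, event_idx, phase, entry, z_axis) -> dict:
    """Reference process metrics from the noiseless canonical-frame path.

    Plain-loop arithmetic in the canonical frame (skin z = 0, axis = x axis
    at z = z_axis): depth is -z, the fistula-plane projection of (x, y, z)
    is (x, y, z_axis) and its axis projection (x, 0, z_axis).
    """
    k0, k1 = (0, 1) if phase == 1 else (2, 3)
    i, j = event_idx[k0], event_idx[k1]
    seg_times = times[i : j + 1]
    seg = tips[i : j + 1]

    t = float(times[j] - times[i])
    pl = 0.0
    for k in range(len(seg) - 1):
        pl += float(np.linalg.norm(seg[k + 1] - seg[k]))

    angles, ang_times = [], []
    for k, p in enumerate(seg):
        base = math.hypot(p[0] - entry[0], p[1] - entry[1])
        h = abs(p[2])
        if base < 1e-9 and h < 1e-9:
            continue  # coincident with the entry point: undefined, skipped
        sign = 1.0 if p[2] <= 0 else -1.0
        angles.append(sign * math.degrees(math.atan2(h, base)))
        ang_times.append(seg_times[k])
    n_ang = len(angles)
    alpha = sum(angles) / n_ang
    rate = 0.0
    for k in range(n_ang - 1):
        rate += (angles[k + 1] - angles[k]) / (ang_times[k + 1] - ang_times[k])
    alpha_dot = rate / n_ang

    a_i = float(abs(tips[i][1]))
    dist_end = float(abs(tips[j][1]))
    denom = math.hypot(tips[j][0] - tips[i][0], tips[j][1] - tips[i][1])
    ratio = min(1.0, abs(a_i - dist_end) / denom) if denom > 0 else 0.0
    beta = math.degrees(math.asin(ratio))
    if dist_end > a_i:
        beta = -beta

    return {
        "t_s": float(t),
        "pl_mm": float(pl),
        "v_mm_s": float(pl / t),
        "alpha_deg": float(alpha),
        "alpha_dot_deg_s": float(alpha_dot),
        "a_mm": a_i,
        "beta_deg": float(beta),
        "n_samples": int(j - i + 1),
    }


def _true_outcomes(times, tips, event_idx, z_axis, r) -> dict:
    """Reference outcome quantities from the noiseless canonical-frame path."""
    i0, i1, i2, i3 = event_idx
    xy = np.column_stack([tips[i0 : i3 + 1, 1], tips[i0 : i3 + 1, 2] - z_axis])
    dist = np.hypot(xy[:, 0], xy[:, 1])

    p1 = slice(0, i1 - i0 + 1)
    p3 = slice(i2 - i0, i3 - i0 + 1)
    z_p1 = tips[i0 : i1 + 1, 2]
    k1 = int(np.argmin(z_p1))
    risk_p1 = (float(xy[p1][k1, 0]), float(xy[p1][k1, 1]))
    k3 = int(np.argmax(dist[p3]))
    risk_p3 = (float(xy[p3][k3, 0]), float(xy[p3][k3, 1]))
    final = (float(xy[-1, 0]), float(xy[-1, 1]))

    inside = dist <= r
    infiltrated = {1: False, 2: False, 3: False}
    classes = {1: "none", 2: "none", 3: "none"}
    entered = bool(np.any(inside))
    if entered:
        entry_k = int(np.argmax(inside))
        bounds = {1: (0, i1 - i0), 2: (i1 - i0, i2 - i0), 3: (i2 - i0, i3 - i0)}
        for phase, (a, b) in bounds.items():
            idxs = [
                k
                for k in range(a, b + 1)
                if k >= entry_k and dist[k] > r and _attribute(k, bounds) == phase
            ]
            if idxs:
                infiltrated[phase] = True
                worst = max(idxs, key=lambda k: dist[k])
                classes[phase] = "bottom" if xy[worst, 1] < 0 else "top"
    return {
        "risk_p1": risk_p1,
        "risk_p3": risk_p3,
        "final_pos": final,
        "entered_fistula": entered,
        "infiltrated": infiltrated,
        "infiltration_class": classes,
        "success": bool(math.hypot(*final) <= r),
    }


def _attribute(k, bounds) -> int:
    for phase in (1, 2, 3):
        a, b = bounds[phase]
        if a <= k <= b:
            return phase
    raise IndexError(k)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

#: population skill distributions (mean, sd) used for cohort draws; durations
#: and path-related quantities follow the reference cohort's reported spread
DEFAULT_SKILL = {
    "alpha1_deg": (54.45, 8.67),
    "phase1_s": (4.36, 3.18),
    "phase3_s": (3.02, 1.57),
    "rotation_pause_s": (1.0, 0.3),
    "beta_drift_deg": (-3.39, 6.56),
    "entry_lateral_mm": (3.02, 1.41),
    "advance3_mm": (12.0, 3.0),
    "camera_delay_s": (0.195, 0.05),
}

_CLIP = {
    "alpha1_deg": (25.0, 80.0),
    "phase1_s": (1.0, 12.0),
    "phase3_s": (1.0, 8.0),
    "rotation_pause_s": (0.4, 2.0),
    "beta_drift_deg": (-12.0, 12.0),
    "entry_lateral_mm": (0.0, 5.0),
    "advance3_mm": (6.0, 20.0),
    "camera_delay_s": (0.02, 0.45),
}

#: event-rate parameters mirroring the reference cohort's error pattern
#: (9/42 phase-1 infiltrations, 15/42 phase-3 with 6 bottom : 9 top,
#: 6/42 unsuccessful final positions)
DEFAULT_RATES = {
    "p_phase1_overshoot": 9 / 42,
    "p_phase3_infiltration": 15 / 42,
    "p_bottom_given_infiltration": 6 / 15,
    "p_unsuccessful_final": 6 / 42,
    "retraction_rate": 1.0,  # Poisson mean per trial
}


def _draw(rng, key, mean_shift=0.0, scale=1.0):
    mu, sd = DEFAULT_SKILL[key]
    lo, hi = _CLIP[key]
    return float(np.clip(rng.normal(mu + mean_shift, sd * scale), lo, hi))


def generate_cohort(
    n_subjects: int = 7,
    n_trials: int = 6,
    seed: int = 0,
    skill: dict | None = None,
    rates: dict | None = None,
    noise_sd_mm: float = 0.05,
) -> Cohort:
    """Generate a cohort of trials with per-subject latent skill.

    Each subject draws a latent skill offset for every parameter
    (between-subject spread 0.7 of the population SD); each trial jitters
    around the subject's level (within-subject spread 0.7 of the population
    SD).  Randomness is keyed by (seed, subject, trial) so any single trial
    is reproducible in isolation.
    """
    skill_table = dict(DEFAULT_SKILL)
    if skill:
        skill_table.update(skill)
    rate_table = dict(DEFAULT_RATES)
    if rates:
        rate_table.update(rates)

    trials = []
    rows = []
    geometry = default_geometry(TrialConfig())
    for s in range(n_subjects):
        subj_rng = np.random.default_rng([seed, s])
        offsets = {
            key: subj_rng.normal(0.0, 0.7 * sd) for key, (_, sd) in skill_table.items()
        }
        for k in range(n_trials):
            rng = np.random.default_rng([seed, s, k])
            params = {
                key: _draw(rng, key, mean_shift=offsets[key], scale=0.7)
                for key in skill_table
            }
            # subjects approach predominantly from one side of the fistula
            lateral_sign = 1.0 if rng.random() < 0.85 else -1.0
            params["entry_lateral_mm"] *= lateral_sign

            overshoot = 0.0
            if rng.random() < rate_table["p_phase1_overshoot"]:
                overshoot = float(np.clip(abs(rng.normal(1.5, 0.7)), 0.3, 4.0))
            infil_depth, infil_side = 0.0, -1
            if rng.random() < rate_table["p_phase3_infiltration"]:
                infil_depth = float(np.clip(abs(rng.normal(1.5, 0.7)), 0.3, 4.0))
                infil_side = (
                    -1 if rng.random() < rate_table["p_bottom_given_infiltration"] else 1
                )
            # an unsuccessful final necessarily lies outside the lumen, i.e. it
            # is itself a phase-3 infiltration sample; draw it only within
            # infiltration trials so the cohort error rates stay coherent
            p_unsucc = rate_table["p_unsuccessful_final"] / max(
                rate_table["p_phase3_infiltration"], 1e-12
            )
            if infil_depth > 0 and rng.random() < p_unsucc:
                ang = (np.pi / 2 if infil_side > 0 else -np.pi / 2) + rng.normal(0.0, 0.4)
                rad = 7.0 + 0.5 * infil_depth
                final_offset = (rad * np.cos(ang), rad * np.sin(ang))
            else:
                final_offset = (
                    float(np.clip(rng.normal(0.0, 1.5), -4.5, 4.5)),
                    float(np.clip(rng.normal(0.0, 1.5), -4.5, 4.5)),
                )
            n_retr = int(min(3, rng.poisson(rate_table["retraction_rate"])))

            cfg = TrialConfig(
                seed=seed,
                alpha1_deg=params["alpha1_deg"],
                phase1_s=params["phase1_s"],
                phase3_s=params["phase3_s"],
                rotation_pause_s=params["rotation_pause_s"],
                beta_drift_deg=params["beta_drift_deg"],
                entry_lateral_mm=params["entry_lateral_mm"],
                advance3_mm=params["advance3_mm"],
                camera_delay_s=params["camera_delay_s"],
                n_retractions=n_retr,
                phase1_overshoot_mm=overshoot,
                infiltration_depth_mm=infil_depth,
                infiltration_side=infil_side,
                final_offset_mm=final_offset,
                noise_sd_mm=noise_sd_mm,
            )
            trial = generate_trial(cfg, rng=rng)
            subject_id = f"S{s + 1:02d}"
            trial_id = f"{subject_id}_T{k + 1:02d}"
            trials.append((subject_id, trial_id, trial))
            rows.append(
                {
                    "subject_id": subject_id,
                    "trial_id": trial_id,
                    "camera_delay_s": cfg.camera_delay_s,
                    "alpha1_deg": cfg.alpha1_deg,
                    "infiltration_depth_mm": cfg.infiltration_depth_mm,
                    "phase1_overshoot_mm": cfg.phase1_overshoot_mm,
                    "n_retractions": cfg.n_retractions,
                }
            )
    manifest = pd.DataFrame(rows)
    return Cohort(trials=trials, geometry=geometry, manifest=manifest, seed=seed)


# ---------------------------------------------------------------------------
# direct regression-cohort generation (bypasses trajectory synthesis)
# ---------------------------------------------------------------------------

#: default predictor distributions (mean, sd) for the direct regression cohort
REGRESSION_PREDICTOR_DISTS = {
    "t_s": (4.36, 3.18),
    "pl_mm": (22.61, 6.28),
    "v_mm_s": (1.08, 0.71),
    "alpha_deg": (54.45, 8.67),
    "alpha_dot_deg_s": (-5.12, 8.07),
    "a_mm": (3.02, 1.41),
    "beta_deg": (-3.39, 6.56),
}


def generate_regression_cohort(
    true_coefficients,
    noise_sd: float,
    n: int = 42,
    seed: int = 0,
    phase: int = 1,
    predictor_dists: dict | None = None,
):
    """Draw process-metric rows and linear-model risk points directly.

    ``true_coefficients`` is a (2, 8) array — rows are the x and y
    responses, columns the intercept followed by the seven predictors —
    defining the planted linear relationship; Gaussian response noise with
    standard deviation ``noise_sd`` is added.  Returns
    (process_df, outcomes_df, coefficients).
    """
    coef = np.asarray(true_coefficients, dtype=float)
    if coef.shape != (2, 8):
        raise ValueError("true_coefficients must be shaped (2, 8): intercept + 7 predictors")
    dists = dict(REGRESSION_PREDICTOR_DISTS)
    if predictor_dists:
        dists.update(predictor_dists)
    rng = np.random.default_rng(seed)
    names = list(REGRESSION_PREDICTOR_DISTS)
    X = np.column_stack([rng.normal(*dists[name], size=n) for name in names])
    design = np.column_stack([np.ones(n), X])
    Y = design @ coef.T + rng.normal(0.0, noise_sd, size=(n, 2))

    trial_ids = [f"R_{i:03d}" for i in range(n)]
    process = pd.DataFrame(X, columns=names)
    process.insert(0, "trial_id", trial_ids)
    process.insert(1, "phase", phase)
    outcomes = pd.DataFrame(
        {
            "trial_id": trial_ids,
            f"x{phase}_mm": Y[:, 0],
            f"y{phase}_mm": Y[:, 1],
        }
    )
    return process, outcomes, coef
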