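"""Phase-specific process metrics of needle-insertion technique.

Seven metrics are computed for the insertion phase (Phase 1) and the
leveling-and-forwarding phase (Phase 3); the rotation phase contributes no
process metrics because the tip is nearly stationary there.

t      phase duration from the mapped event times, s
PL     path length: summed Euclidean tip displacement over the phase, mm
v      average velocity PL / t, mm/s
alpha  average insertion angle: mean over phase samples of
       arctan(|P_tip - P_tip'| / |P_tip' - P_entry|), where P_tip' is the
       orthogonal projection of the tip onto the skin plane and P_entry the
       projection of the tip at T0; positive below the skin plane, degrees
alpha_dot  average rate of change of the per-sample insertion angle, deg/s
a      start-point accuracy: distance between the phase-start tip projected
       onto the fistula plane and its projection onto the axial line, mm
beta   lateral angle between the in-plane tip displacement over the phase
       and the fistula's axial line; positive when the motion approaches
       the axis, degrees
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import DegeneratePhaseError, UndefinedLateralAngleError
from .geometry import (
    FistulaFrame,
    Plane,
    SimGeometry,
    project_to_axis,
    project_to_plane,
)
from .segmentation import SegmentedTrial

__all__ = [
    "ProcessMetrics",
    "phase_time",
    "path_length",
    "average_velocity",
    "insertion_angle_series",
    "average_insertion_angle",
    "angle_change_rate",
    "start_point_accuracy",
    "lateral_angle",
    "compute_all",
]

logger = logging.getLogger(__name__)

_EPS = 1e-9

#: event index pairs bounding each metric phase: phase -> (start event, end event)
_PHASE_EVENTS = {1: (0, 1), 3: (2, 3)}


@dataclass(frozen=True)
class ProcessMetrics:
    """Process-metric row for one (trial, phase)."""

    phase: int
    t: float  # s
    pl: float  # mm
    v: float  # mm/s
    alpha: float  # deg
    alpha_dot: float  # deg/s
    a: float  # mm
    beta: float  # deg
    n_samples: int

    def as_dict(self) -> dict:
        return {
            "phase": self.phase,
            "t_s": self.t,
            "pl_mm": self.pl,
            "v_mm_s": self.v,
            "alpha_deg": self.alpha,
            "alpha_dot_deg_s": self.alpha_dot,
            "a_mm": self.a,
            "beta_deg": self.beta,
            "n_samples": self.n_samples,
        }


def _check_phase(phase: int):
    if phase not in _PHASE_EVENTS:
        raise ValueError("process metrics are defined for phases 1 and 3 only")


def phase_time(trial: SegmentedTrial, phase: int) -> float:
    """Phase duration from the mapped event times (not the snapped samples)."""
    _check_phase(phase)
    k0, k1 = _PHASE_EVENTS[phase]
    return float(trial.em_times[k1] - trial.em_times[k0])


def path_length(trial: SegmentedTrial, phase: int) -> float:
    """Total tip distance traversed within the (closed) phase sample range."""
    _check_phase(phase)
    tips = trial.phase_tips(phase)
    return float(np.sum(np.linalg.norm(np.diff(tips, axis=0), axis=1)))


def average_velocity(trial: SegmentedTrial, phase: int) -> float:
    """Average speed PL / t of the needle tip over the phase."""
    t = phase_time(trial, phase)
    if t <= 0:
        raise DegeneratePhaseError(f"phase {phase} has non-positive duration")
    return path_length(trial, phase) / t


def insertion_angle_series(
    trial: SegmentedTrial, phase: int, skin: Plane
) -> np.ndarray:
    """Per-sample insertion angle (degrees) over the phase.

    For each tip sample, the angle is arctan of depth below the skin plane
    over horizontal (in-plane) distance of its skin projection from the
    entry point; the sign is positive below the plane.  A sample exactly
    over the entry point (zero horizontal distance) contributes +/-90 deg;
    a sample coincident with the entry point itself is undefined and
    returned as NaN (excluded from averages, N reduced accordingly).
    """
    _check_phase(phase)
    if trial.p_entry is None:
        raise DegeneratePhaseError("segmented trial carries no entry point (no skin plane)")
    tips = trial.phase_tips(phase)
    s = skin.signed_distance(tips)  # positive above the skin plane
    feet = tips - s[:, None] * skin.normal
    base = np.linalg.norm(feet - trial.p_entry, axis=1)
    h = np.abs(s)
    sign = np.where(s <= 0, 1.0, -1.0)
    with np.errstate(invalid="ignore"):
        ang = np.degrees(np.arctan2(h, base)) * sign
    ang = np.where((base < _EPS) & (h < _EPS), np.nan, ang)
    ang = np.where((base < _EPS) & (h >= _EPS), 90.0 * sign, ang)
    return ang


def average_insertion_angle(trial: SegmentedTrial, phase: int, skin: Plane) -> float:
    """Mean per-sample insertion angle over the phase, degrees."""
    ang = insertion_angle_series(trial, phase, skin)
    valid = np.isfinite(ang)
    if not np.any(valid):
        raise DegeneratePhaseError(
            f"phase {phase}: all samples coincide with the entry point"
        )
    return float(np.mean(ang[valid]))


def angle_change_rate(trial: SegmentedTrial, phase: int, skin: Plane) -> float:
    """Average rate of change of the insertion angle, degrees / s.

    (1/N) * sum over consecutive sample pairs of (alpha(t+dt) - alpha(t))/dt,
    with N the number of (defined) angle samples in the phase.  On uniformly
    sampled data this telescopes to (alpha_end - alpha_start) / (N * dt).
    """
    ang = insertion_angle_series(trial, phase, skin)
    times = trial.phase_times(phase)
    valid = np.isfinite(ang)
    ang, times = ang[valid], times[valid]
    n = ang.size
    if n < 2:
        raise DegeneratePhaseError(f"phase {phase}: fewer than 2 defined angle samples")
    dt = np.diff(times)
    if np.any(dt <= 0):
        raise DegeneratePhaseError("non-increasing timestamps within phase")
    return float(np.sum(np.diff(ang) / dt) / n)


def _projected_endpoints(trial: SegmentedTrial, phase: int, frame: FistulaFrame):
    k0, k1 = _PHASE_EVENTS[phase]
    i0 = trial.event_indices[k0]
    i1 = trial.event_indices[k1]
    tip_start, tip_end = trial.tips[i0], trial.tips[i1]
    return tip_start, tip_end


def start_point_accuracy(trial: SegmentedTrial, phase: int, frame: FistulaFrame) -> float:
    """Distance from the phase-start tip's fistula-plane projection to the axis (mm)."""
    _check_phase(phase)
    tip_start, _ = _projected_endpoints(trial, phase, frame)
    p_star = project_to_plane(tip_start, frame.plane)
    p_dstar = project_to_axis(tip_start, frame)
    return float(np.linalg.norm(p_star - p_dstar))


def lateral_angle(trial: SegmentedTrial, phase: int, frame: FistulaFrame) -> float:
    """In-plane angle (degrees) between phase tip displacement and the axis.

    arcsin(|a_i - dist_end| / in-plane displacement), where a_i is the
    start-point accuracy and dist_end the distance of the phase-end
    projected tip from the axial line.  Positive when the end point is
    closer to the axis than the start (motion toward the fistula), negative
    otherwise.  The arcsin argument can exceed 1 when motion leaves the
    fistula plane; it is clipped to 1 with a logged warning.
    """
    _check_phase(phase)
    tip_start, tip_end = _projected_endpoints(trial, phase, frame)
    p_star_s = project_to_plane(tip_start, frame.plane)
    p_star_e = project_to_plane(tip_end, frame.plane)
    a_i = float(np.linalg.norm(p_star_s - project_to_axis(tip_start, frame)))
    dist_end = float(np.linalg.norm(p_star_e - project_to_axis(tip_end, frame)))
    denom = float(np.linalg.norm(p_star_e - p_star_s))
    if denom < _EPS:
        raise UndefinedLateralAngleError(
            f"phase {phase}: zero in-plane displacement; lateral angle undefined"
        )
    ratio = abs(a_i - dist_end) / denom
    if ratio > 1.0:
        logger.warning(
            "lateral angle arcsin argument %.6f > 1 clipped (out-of-plane motion)", ratio
        )
        ratio = 1.0
    magnitude = float(np.degrees(np.arcsin(ratio)))
    sign = 1.0 if dist_end < a_i else (-1.0 if dist_end > a_i else 1.0)
    return sign * magnitude


def compute_all(trial: SegmentedTrial, geometry: SimGeometry) -> dict[int, ProcessMetrics]:
    """All seven process metrics for Phases 1 and 3."""
    out: dict[int, ProcessMetrics] = {}
    for phase in (1, 3):
        t = phase_time(trial, phase)
        pl = path_length(trial, phase)
        i, j = trial.phase_slice(phase)
        out[phase] = ProcessMetrics(
            phase=phase,
            t=t,
            pl=pl,
            v=average_velocity(trial, phase),
            alpha=average_insertion_angle(trial, phase, geometry.skin),
            alpha_dot=angle_change_rate(trial, phase, geometry.skin),
            a=start_point_accuracy(trial, phase, geometry.frame),
            beta=lateral_angle(trial, phase, geometry.frame),
            n_samples=j - i + 1,
        )
    return out
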