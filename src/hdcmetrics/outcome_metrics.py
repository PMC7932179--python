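"""Outcome metrics on the fistula cross-section.

All outcome metrics live in the 2D cross-sectional frame of the fistula
(origin on the lumen axis, x lateral, y vertical up); the lumen is the disc
of radius r.  Three points summarize each trial:

* phase-1 infiltration risk (x1, y1): the cross-section projection of the
  phase-1 tip sample with the lowest vertical (Z) position,
* phase-3 infiltration risk (x3, y3): the projected phase-3 sample farthest
  from the lumen axis,
* final position (xf, yf): the projected tip at T3; the cannulation is
  successful when it lies inside the lumen (boundary inclusive).

Infiltration is entry-gated: only samples *after* the tip first enters the
lumen (projected distance <= r) can flag infiltration, and a sample flags
the phase containing it when its projected distance exceeds r.  The flagged
phase is classified "bottom" or "top" by the sign of the vertical
coordinate at its maximal excursion (y == 0 classifies as top).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import FistulaFrame, cross_section_coords
from .segmentation import SegmentedTrial

__all__ = [
    "OutcomeMetrics",
    "risk_point_phase1",
    "risk_point_phase3",
    "final_position",
    "detect_infiltration",
    "compute_outcomes",
    "count_errors",
]


@dataclass(frozen=True)
class OutcomeMetrics:
    """Outcome-metric row for one trial."""

    risk_p1: tuple[float, float]
    risk_p3: tuple[float, float]
    final_pos: tuple[float, float]
    entered_fistula: bool
    entry_time: float | None
    infiltrated: dict = field(default_factory=dict)  # phase -> bool
    infiltration_class: dict = field(default_factory=dict)  # phase -> none|top|bottom
    success: bool = False

    def as_dict(self) -> dict:
        return {
            "x1_mm": self.risk_p1[0],
            "y1_mm": self.risk_p1[1],
            "x3_mm": self.risk_p3[0],
            "y3_mm": self.risk_p3[1],
            "xf_mm": self.final_pos[0],
            "yf_mm": self.final_pos[1],
            "entered": self.entered_fistula,
            "infil_p1": self.infiltrated.get(1, False),
            "infil_p2": self.infiltrated.get(2, False),
            "infil_p3": self.infiltrated.get(3, False),
            "class_p1": self.infiltration_class.get(1, "none"),
            "class_p2": self.infiltration_class.get(2, "none"),
            "class_p3": self.infiltration_class.get(3, "none"),
            "success": self.success,
        }


def _cross_section(points: np.ndarray, frame: FistulaFrame) -> np.ndarray:
    rel = points - frame.axis_start
    return np.column_stack([rel @ frame.u_lat, rel @ frame.v_vert])


def risk_point_phase1(trial: SegmentedTrial, frame: FistulaFrame) -> tuple[float, float]:
    """Cross-section projection of the phase-1 sample with minimal vertical position."""
    tips = trial.phase_tips(1)
    idx = int(np.argmin(tips[:, 2]))
    return cross_section_coords(tips[idx], frame)


def risk_point_phase3(trial: SegmentedTrial, frame: FistulaFrame) -> tuple[float, float]:
    """Projected phase-3 point with maximal radial distance from the axis."""
    xy = _cross_section(trial.phase_tips(3), frame)
    idx = int(np.argmax(np.hypot(xy[:, 0], xy[:, 1])))
    return float(xy[idx, 0]), float(xy[idx, 1])


def final_position(trial: SegmentedTrial, frame: FistulaFrame) -> tuple[float, float]:
    """Cross-section projection of the tip at (snapped) T3."""
    return cross_section_coords(trial.tips[trial.event_indices[3]], frame)


def _phase_of_sample(trial: SegmentedTrial, idx: int) -> int:
    """Attribute a sample to a phase; shared boundary samples go to the earlier phase."""
    for phase in (1, 2, 3):
        i, j = trial.phase_slice(phase)
        if i <= idx <= j:
            return phase
    raise IndexError(idx)


def detect_infiltration(trial: SegmentedTrial, frame: FistulaFrame):
    """Entry-gated infiltration flags and bottom/top classes per phase.

    Returns (entered, entry_time, infiltrated: dict, classes: dict).  A
    never-entered trial returns entered = False and all flags off.  Samples
    exactly on the lumen boundary (distance == r) count as inside.
    """
    xy = _cross_section(trial.tips, frame)
    dist = np.hypot(xy[:, 0], xy[:, 1])
    inside = dist <= frame.radius
    infiltrated = {1: False, 2: False, 3: False}
    classes = {1: "none", 2: "none", 3: "none"}
    if not np.any(inside):
        return False, None, infiltrated, classes
    entry_idx = int(np.argmax(inside))
    entry_time = float(trial.times[entry_idx])

    outside_after = (np.arange(dist.size) >= entry_idx) & (dist > frame.radius)
    # shared boundary samples are attributed to the earlier phase, for the
    # class exactly as for the flag
    attribution = np.array(
        [_phase_of_sample(trial, i) for i in range(dist.size)]
    )
    for phase in (1, 2, 3):
        cand = np.flatnonzero(outside_after & (attribution == phase))
        if cand.size == 0:
            continue
        infiltrated[phase] = True
        worst = cand[np.argmax(dist[cand])]
        classes[phase] = "bottom" if xy[worst, 1] < 0 else "top"
    return True, entry_time, infiltrated, classes


def compute_outcomes(trial: SegmentedTrial, frame: FistulaFrame) -> OutcomeMetrics:
    """All outcome metrics for one segmented trial."""
    entered, entry_time, infiltrated, classes = detect_infiltration(trial, frame)
    final = final_position(trial, frame)
    return OutcomeMetrics(
        risk_p1=risk_point_phase1(trial, frame),
        risk_p3=risk_point_phase3(trial, frame),
        final_pos=final,
        entered_fistula=entered,
        entry_time=entry_time,
        infiltrated=infiltrated,
        infiltration_class=classes,
        success=bool(np.hypot(*final) <= frame.radius),
    )


def count_errors(outcomes) -> dict:
    """Aggregate infiltration and final-position errors over a cohort.

    Returns per-phase bottom/top/total infiltration counts for Phases 1 and
    3 (the rotation phase is tallied separately under ``phase2_infiltrations``
    since it has no bottom/top table column), plus the number of
    unsuccessful final positions.
    """
    outcomes = list(outcomes)
    if not outcomes:
        raise ValueError("count_errors needs at least one trial outcome")
    counts = {
        phase: {"bottom": 0, "top": 0, "total": 0} for phase in (1, 3)
    }
    phase2 = 0
    unsuccessful = 0
    for om in outcomes:
        for phase in (1, 3):
            if om.infiltrated.get(phase, False):
                counts[phase][om.infiltration_class[phase]] += 1
                counts[phase]["total"] += 1
        if om.infiltrated.get(2, False):
            phase2 += 1
        if not om.success:
            unsuccessful += 1
    return {
        "phase1": counts[1],
        "phase3": counts[3],
        "phase2_infiltrations": phase2,
        "unsuccessful_finals": unsuccessful,
        "n_trials": len(outcomes),
    }
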