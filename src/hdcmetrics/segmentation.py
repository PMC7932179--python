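"""Event mapping and three-phase segmentation of cannulation trials.

A trial is bounded by four manually annotated events: (T0) needle tip
enters the skin, (T1) insertion pauses before the 180-degree rotation,
(T2) rotation completes, (T3) needle advancement completes.  Events are
annotated in the camera clock; a constant camera-to-tracker delay is
estimated from paired timestamps at the first two events and subtracted to
place all four events in the tracker timeline.  The trimmed tip trajectory
is then split into Phase 1 (insertion, [T0, T1]), Phase 2 (rotation,
[T1, T2]) and Phase 3 (leveling and forwarding, [T2, T3]).

Boundary samples belong to both adjacent phases (closed intervals); phase
*durations* use the mapped event times themselves, not the snapped sample
times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    ConfigurationError,
    DegenerateSegmentationError,
    OutOfRangeError,
)
from .geometry import Plane, project_to_plane

__all__ = [
    "EventAnnotation",
    "SegmentedTrial",
    "estimate_time_delay",
    "map_events",
    "segment",
]


@dataclass(frozen=True)
class EventAnnotation:
    """Per-trial event annotation.

    ``cam_times`` holds the four event timestamps ^C T0..^C T3 in the camera
    clock.  ``em_anchor_times`` optionally holds tracker-clock timestamps of
    events 0 and 1, used to estimate the constant camera-to-tracker delay.
    """

    cam_times: np.ndarray
    em_anchor_times: np.ndarray | None = None

    def __post_init__(self):
        cam = np.asarray(self.cam_times, dtype=float)
        if cam.shape != (4,) or not np.all(np.isfinite(cam)):
            raise ConfigurationError("cam_times must be four finite timestamps")
        if not np.all(np.diff(cam) > 0):
            raise ConfigurationError("cam_times must be strictly increasing")
        object.__setattr__(self, "cam_times", cam)
        if self.em_anchor_times is not None:
            em = np.asarray(self.em_anchor_times, dtype=float)
            if em.shape != (2,) or not np.all(np.isfinite(em)):
                raise ConfigurationError(
                    "em_anchor_times must hold two finite timestamps (events 0 and 1)"
                )
            object.__setattr__(self, "em_anchor_times", em)


@dataclass(frozen=True)
class SegmentedTrial:
    """Trimmed tip trajectory with mapped events and phase index ranges.

    ``times``/``tips`` cover the closed window [T0, T3] (snapped to
    samples).  ``phase_ranges[p]`` is the inclusive (start, stop) index pair
    of phase p; boundary samples are shared between adjacent phases.
    ``p_entry`` is the tip at T0 projected onto the skin plane (None when no
    skin plane was supplied).
    """

    times: np.ndarray
    tips: np.ndarray
    em_times: np.ndarray  # mapped T0..T3 (tracker clock)
    t_delay: float
    phase_ranges: dict
    event_indices: np.ndarray  # snapped indices of T0..T3 into times/tips
    p_entry: np.ndarray | None = None

    def phase_slice(self, phase: int) -> tuple[int, int]:
        """Inclusive index range (i, j) of a phase."""
        if phase not in self.phase_ranges:
            raise KeyError(f"no such phase: {phase}")
        return self.phase_ranges[phase]

    def phase_times(self, phase: int) -> np.ndarray:
        i, j = self.phase_slice(phase)
        return self.times[i : j + 1]

    def phase_tips(self, phase: int) -> np.ndarray:
        i, j = self.phase_slice(phase)
        return self.tips[i : j + 1]


def estimate_time_delay(annotation: EventAnnotation) -> float:
    """Constant camera-to-tracker delay, averaged over the first two events."""
    if annotation.em_anchor_times is None:
        raise ConfigurationError(
            "delay estimation needs tracker-clock anchors for events 0 and 1"
        )
    diffs = annotation.cam_times[:2] - annotation.em_anchor_times
    return float(np.mean(diffs))


def map_events(annotation: EventAnnotation, t_delay: float) -> np.ndarray:
    """Map the four camera-clock events into the tracker clock.

    ``^EM T_k = ^C T_k - t_delay``; the strict ordering of events is
    preserved because the delay is constant.
    """
    if not np.isfinite(t_delay):
        raise ConfigurationError("t_delay must be finite")
    return annotation.cam_times - t_delay


def _snap(times: np.ndarray, t: float) -> int:
    """Index of the sample nearest to t; ties break toward the earlier sample."""
    return int(np.argmin(np.abs(times - t)))


def segment(
    times,
    tips,
    em_times,
    skin_plane: Plane | None = None,
    t_delay: float = float("nan"),
) -> SegmentedTrial:
    """Trim a tip trajectory to [T0, T3] and split it into the three phases.

    Each mapped event time is snapped to the nearest sample; samples outside
    the trimmed window are discarded.  Raises :class:`OutOfRangeError` when
    an event lies outside the trajectory span and
    :class:`DegenerateSegmentationError` when a phase would contain fewer
    than two samples.
    """
    times = np.asarray(times, dtype=float)
    tips = np.asarray(tips, dtype=float)
    em = np.asarray(em_times, dtype=float)
    if em.shape != (4,):
        raise ConfigurationError("em_times must hold four event times")
    if not np.all(np.diff(em) > 0):
        raise ConfigurationError("event times must be strictly increasing (T0 < T1 < T2 < T3)")
    if times.ndim != 1 or tips.shape != (times.size, 3):
        raise ConfigurationError("trajectory must be (N,) times with (N, 3) tips")
    if times.size < 2:
        raise DegenerateSegmentationError("trajectory has fewer than 2 samples")
    if em[0] < times[0] or em[-1] > times[-1]:
        raise OutOfRangeError(
            f"events [{em[0]:.3f}, {em[-1]:.3f}] s outside trajectory span "
            f"[{times[0]:.3f}, {times[-1]:.3f}] s"
        )

    idx = np.array([_snap(times, t) for t in em])
    if np.any(np.diff(idx) < 1):
        raise DegenerateSegmentationError(
            "snapped event samples are not strictly increasing; a phase is empty"
        )

    i0, i3 = idx[0], idx[3]
    trimmed_times = times[i0 : i3 + 1]
    trimmed_tips = tips[i0 : i3 + 1]
    rel = idx - i0
    phase_ranges = {
        1: (int(rel[0]), int(rel[1])),
        2: (int(rel[1]), int(rel[2])),
        3: (int(rel[2]), int(rel[3])),
    }
    for p, (a, b) in phase_ranges.items():
        if b - a + 1 < 2:
            raise DegenerateSegmentationError(f"phase {p} has fewer than 2 samples")

    p_entry = None
    if skin_plane is not None:
        p_entry = project_to_plane(trimmed_tips[0], skin_plane)

    return SegmentedTrial(
        times=trimmed_times,
        tips=trimmed_tips,
        em_times=em,
        t_delay=float(t_delay),
        phase_ranges=phase_ranges,
        event_indices=rel,
        p_entry=p_entry,
    )
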