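"""File readers and writers for trajectories, events and geometry.

All files are plain text: trajectories and event annotations are CSV
(comma-separated, '.' decimal, mandatory header, UTF-8), geometry is JSON
or YAML.  Column names embed the unit (``x_mm``, ``time_s``) to prevent
silent unit drift.

Trajectory dialects
-------------------
quaternion:  time_s, x_mm, y_mm, z_mm, qw, qx, qy, qz
matrix:      time_s, x_mm, y_mm, z_mm, m00..m22 (row-major rotation matrix,
             re-orthonormalized on read; rejected if farther than 1e-6 from
             a rotation)

Geometry schema (exact keys; unknown keys rejected)
---------------------------------------------------
skin_points        list of [x, y, z] mm (>= 3)
fistula_vertices   4 x [x, y, z] mm
fistula_radius_mm  float
fistula_length_mm  float
tip_offset_mm      [x, y, z] mm (sensor frame)
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.spatial.transform import Rotation

from .errors import TrajectoryParseError
from .geometry import SimGeometry, TipOffset, build_fistula_frame, fit_plane
from .segmentation import EventAnnotation

__all__ = [
    "read_trajectory",
    "write_trajectory",
    "read_geometry",
    "write_geometry",
    "read_events",
    "write_events",
]

logger = logging.getLogger(__name__)

_QUAT_COLS = ["qw", "qx", "qy", "qz"]
_MAT_COLS = [f"m{i}{j}" for i in range(3) for j in range(3)]
_POS_COLS = ["time_s", "x_mm", "y_mm", "z_mm"]

GEOMETRY_KEYS = {
    "skin_points",
    "fistula_vertices",
    "fistula_radius_mm",
    "fistula_length_mm",
    "tip_offset_mm",
}


def read_trajectory(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read one trial's pose stream.

    Returns (times, positions, quaternions) with quaternions scalar-first;
    samples are time-sorted (a warning is logged if the file was shuffled).
    Raises :class:`TrajectoryParseError` naming the offending row for NaN
    fields or duplicate timestamps, and for malformed headers.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise TrajectoryParseError(f"{path}: cannot parse CSV: {exc}") from exc

    cols = list(df.columns)
    if cols[: len(_POS_COLS)] != _POS_COLS:
        raise TrajectoryParseError(
            f"{path}: header must start with {_POS_COLS}, got {cols[:4]}"
        )
    rest = cols[len(_POS_COLS):]
    if rest == _QUAT_COLS:
        dialect = "quaternion"
    elif rest == _MAT_COLS:
        dialect = "matrix"
    else:
        raise TrajectoryParseError(
            f"{path}: orientation columns must be {_QUAT_COLS} or {_MAT_COLS}"
        )

    bad = df.isna().any(axis=1)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise TrajectoryParseError(
            f"{path}: non-finite field at data row {row + 1}", row=row + 1
        )

    times = df["time_s"].to_numpy(dtype=float)
    if np.unique(times).size != times.size:
        dup = int(np.flatnonzero(np.diff(np.sort(times)) == 0)[0])
        raise TrajectoryParseError(f"{path}: duplicate timestamps (e.g. sorted row {dup + 1})")
    if not np.all(np.diff(times) > 0):
        logger.warning("%s: rows were not time-sorted; sorting", path)
        order = np.argsort(times, kind="stable")
        df = df.iloc[order].reset_index(drop=True)
        times = df["time_s"].to_numpy(dtype=float)

    positions = df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
    if dialect == "quaternion":
        quats = df[_QUAT_COLS].to_numpy(dtype=float)
        norms = np.linalg.norm(quats, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            row = int(np.flatnonzero(np.abs(norms - 1.0) > 1e-6)[0])
            raise TrajectoryParseError(
                f"{path}: non-unit quaternion at data row {row + 1}", row=row + 1
            )
    else:
        mats = df[_MAT_COLS].to_numpy(dtype=float).reshape(-1, 3, 3)
        # reject matrices farther than ~1e-6 from a rotation, re-orthonormalize the rest
        for i, m in enumerate(mats):
            if np.max(np.abs(m @ m.T - np.eye(3))) > 1e-5:
                raise TrajectoryParseError(
                    f"{path}: non-orthonormal rotation matrix at data row {i + 1}",
                    row=i + 1,
                )
        q = Rotation.from_matrix(mats).as_quat()  # scalar-last, re-orthonormalized
        quats = q[:, [3, 0, 1, 2]]
    return times, positions, quats


def write_trajectory(path, times, positions, quaternions) -> None:
    """Write a pose stream in the quaternion dialect (full precision)."""
    times = np.asarray(times, dtype=float)
    positions = np.asarray(positions, dtype=float)
    quaternions = np.asarray(quaternions, dtype=float)
    df = pd.DataFrame(
        {
            "time_s": times,
            "x_mm": positions[:, 0],
            "y_mm": positions[:, 1],
            "z_mm": positions[:, 2],
            "qw": quaternions[:, 0],
            "qx": quaternions[:, 1],
            "qy": quaternions[:, 2],
            "qz": quaternions[:, 3],
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")


def read_geometry(path) -> SimGeometry:
    """Read and validate a geometry calibration file (JSON or YAML)."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() in (".yaml", ".yml"):
        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    if not isinstance(raw, dict):
        raise TrajectoryParseError(f"{path}: geometry file must hold a mapping")
    unknown = set(raw) - GEOMETRY_KEYS
    if unknown:
        raise TrajectoryParseError(f"{path}: unknown geometry keys: {sorted(unknown)}")
    missing = GEOMETRY_KEYS - set(raw)
    if missing:
        raise TrajectoryParseError(f"{path}: missing geometry keys: {sorted(missing)}")

    skin_points = np.asarray(raw["skin_points"], dtype=float)
    vertices = np.asarray(raw["fistula_vertices"], dtype=float)
    if vertices.shape != (4, 3):
        raise TrajectoryParseError(f"{path}: fistula_vertices must be 4 x 3")
    skin = fit_plane(skin_points)
    frame = build_fistula_frame(
        vertices,
        radius=float(raw["fistula_radius_mm"]),
        length=float(raw["fistula_length_mm"]),
    )
    return SimGeometry(
        skin=skin,
        frame=frame,
        tip_offset=TipOffset(np.asarray(raw["tip_offset_mm"], dtype=float)),
        skin_points=skin_points,
    )


def write_geometry(path, geometry: SimGeometry) -> None:
    path = Path(path)
    payload = {
        "skin_points": np.asarray(geometry.skin_points).tolist(),
        "fistula_vertices": geometry.frame.vertices.tolist(),
        "fistula_radius_mm": geometry.frame.radius,
        "fistula_length_mm": geometry.frame.length,
        "tip_offset_mm": geometry.tip_offset.d.tolist(),
    }
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(payload), encoding="utf-8")
    else:
        path.write_text(json.dumps(payload, indent=2), encoding="utf-8")


def read_events(path) -> dict[str, EventAnnotation]:
    """Read the per-trial event annotation CSV.

    Columns: trial_id, cam_t0..cam_t3, optional em_anchor_t0, em_anchor_t1.
    """
    df = pd.read_csv(path)
    required = ["trial_id"] + [f"cam_t{k}" for k in range(4)]
    for col in required:
        if col not in df.columns:
            raise TrajectoryParseError(f"{path}: events file missing column {col!r}")
    has_anchors = {"em_anchor_t0", "em_anchor_t1"}.issubset(df.columns)
    out = {}
    for i, row in df.iterrows():
        cam = np.array([row[f"cam_t{k}"] for k in range(4)], dtype=float)
        anchors = None
        if has_anchors and np.isfinite(row["em_anchor_t0"]) and np.isfinite(row["em_anchor_t1"]):
            anchors = np.array([row["em_anchor_t0"], row["em_anchor_t1"]], dtype=float)
        out[str(row["trial_id"])] = EventAnnotation(cam_times=cam, em_anchor_times=anchors)
    return out


def write_events(path, annotations: dict) -> None:
    rows = []
    for trial_id in sorted(annotations):
        ann = annotations[trial_id]
        row = {"trial_id": trial_id}
        for k in range(4):
            row[f"cam_t{k}"] = ann.cam_times[k]
        if ann.em_anchor_times is not None:
            row["em_anchor_t0"] = ann.em_anchor_times[0]
            row["em_anchor_t1"] = ann.em_anchor_times[1]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")
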