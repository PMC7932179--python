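"""End-to-end analysis pipeline: files in, metric/outcome/statistics tables out.

``run_pipeline`` ties the modules together for a directory of trials:
read geometry + events, then per trial read the pose stream, compute tip
positions, estimate the camera-tracker delay, map and snap the four events,
segment into phases, and compute process and outcome metrics; finally run
the phase comparison and the per-phase risk-point regressions and write
everything as CSV/JSON plus a run manifest.  A failing trial is logged and
summarized without aborting the remaining trials.  Outputs are
deterministic: trials are processed in sorted trial-id order regardless of
file enumeration order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as hio
from . import __version__
from .errors import HdcMetricsError
from .geometry import tip_position, PoseSample
from .outcome_metrics import compute_outcomes, count_errors
from .process_metrics import compute_all
from .segmentation import estimate_time_delay, map_events, segment
from .stats import compare_phases, comparison_table, fit_outcome_regression, significance_table

__all__ = ["RunConfig", "PipelineResult", "analyze_trial", "run_pipeline", "write_cohort"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run."""

    geometry_path: Path
    trajectory_dir: Path
    events_path: Path
    output_dir: Path
    use_wilcoxon: bool = False
    holm: bool = False
    make_plots: bool = False
    log_level: str = "INFO"

    def validate(self) -> "RunConfig":
        for p in (self.geometry_path, self.trajectory_dir, self.events_path):
            if not Path(p).exists():
                raise FileNotFoundError(f"input path does not exist: {p}")
        return self


@dataclass
class PipelineResult:
    metrics: pd.DataFrame
    outcomes: pd.DataFrame
    comparison: pd.DataFrame
    regressions: dict  # phase -> RegressionModel
    significance: pd.DataFrame
    error_counts: dict
    failures: dict = field(default_factory=dict)  # trial_id -> message


def _tips_from_pose(times, positions, quats, offset):
    tips = np.empty_like(positions)
    for i in range(len(times)):
        sample = PoseSample(t=float(times[i]), position=positions[i], quaternion=quats[i])
        tips[i] = tip_position(sample, offset)
    return tips


def analyze_trial(times, positions, quats, annotation, geometry):
    """Segment one trial and compute its process and outcome metrics.

    Returns (segmented_trial, {phase: ProcessMetrics}, OutcomeMetrics).
    """
    tips = _tips_from_pose(times, positions, quats, geometry.tip_offset)
    t_delay = estimate_time_delay(annotation)
    em_times = map_events(annotation, t_delay)
    trial = segment(times, tips, em_times, skin_plane=geometry.skin, t_delay=t_delay)
    metrics = compute_all(trial, geometry)
    outcomes = compute_outcomes(trial, geometry.frame)
    return trial, metrics, outcomes


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full analysis over a trial directory and write result tables."""
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    geometry = hio.read_geometry(config.geometry_path)
    annotations = hio.read_events(config.events_path)
    if not annotations:
        raise HdcMetricsError(f"no trials annotated in {config.events_path}")

    traj_dir = Path(config.trajectory_dir)
    metric_rows, outcome_rows = [], []
    outcome_objs = []
    failures = {}
    for trial_id in sorted(annotations):
        traj_path = traj_dir / f"{trial_id}.csv"
        try:
            if not traj_path.exists():
                raise HdcMetricsError(f"missing trajectory file {traj_path.name}")
            times, positions, quats = hio.read_trajectory(traj_path)
            _, metrics, outcomes = analyze_trial(
                times, positions, quats, annotations[trial_id], geometry
            )
        except HdcMetricsError as exc:
            logger.error("trial %s failed: %s", trial_id, exc)
            failures[trial_id] = str(exc)
            continue
        subject_id = trial_id.split("_")[0]
        for phase in (1, 3):
            row = {"subject_id": subject_id, "trial_id": trial_id}
            row.update(metrics[phase].as_dict())
            metric_rows.append(row)
        orow = {"subject_id": subject_id, "trial_id": trial_id}
        orow.update(outcomes.as_dict())
        outcome_rows.append(orow)
        outcome_objs.append(outcomes)

    if not metric_rows:
        raise HdcMetricsError("no trial could be analyzed; see failures in the manifest")
    metrics_df = pd.DataFrame(metric_rows)
    outcomes_df = pd.DataFrame(outcome_rows)
    comparison_results = compare_phases(
        metrics_df, use_wilcoxon=config.use_wilcoxon, holm=config.holm
    )
    comparison_df = comparison_table(comparison_results)

    regressions = {}
    for phase in (1, 3):
        regressions[phase] = fit_outcome_regression(metrics_df, outcomes_df, phase)
    signif = significance_table([regressions[1], regressions[3]])
    errors = count_errors(outcome_objs)

    metrics_df.to_csv(out_dir / "process_metrics.csv", index=False, float_format="%.9g")
    outcomes_df.to_csv(out_dir / "outcome_metrics.csv", index=False, float_format="%.9g")
    comparison_df.to_csv(out_dir / "phase_comparison.csv", index=False, float_format="%.9g")
    signif.to_csv(out_dir / "regression_significance.csv", index=False, float_format="%.9g")
    reg_payload = {
        str(phase): {
            "coefficients": model.coefficients.tolist(),
            "p_values": model.p_values.tolist(),
            "r_squared_x_pct": model.r_squared_x,
            "r_squared_y_pct": model.r_squared_y,
            "n_obs": model.n_obs,
            "predictors": list(model.predictor_names),
        }
        for phase, model in regressions.items()
    }
    (out_dir / "regression_models.json").write_text(
        json.dumps(reg_payload, indent=2, sort_keys=True), encoding="utf-8"
    )
    manifest = {
        "package_version": __version__,
        "inputs": {
            "geometry": str(config.geometry_path),
            "trajectories": str(config.trajectory_dir),
            "events": str(config.events_path),
        },
        "flags": {"use_wilcoxon": config.use_wilcoxon, "holm": config.holm},
        "n_trials_analyzed": int(len(outcome_rows)),
        "failures": failures,
        "error_counts": errors,
    }
    (out_dir / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
    )

    if config.make_plots:
        from .plots import plot_cross_section, plot_z_profile  # lazy: needs matplotlib

        plot_cross_section(outcomes_df, geometry.frame.radius, out_dir / "cross_section.png")

    return PipelineResult(
        metrics=metrics_df,
        outcomes=outcomes_df,
        comparison=comparison_df,
        regressions=regressions,
        significance=signif,
        error_counts=errors,
        failures=failures,
    )


def write_cohort(cohort, out_dir) -> Path:
    """Write a synthetic cohort in the exact formats the pipeline reads.

    Emits one trajectory CSV per trial, an events CSV, the geometry JSON, a
    ground-truth JSON sidecar per trial and a cohort manifest CSV; returns
    the output directory.
    """
    out_dir = Path(out_dir)
    traj_dir = out_dir / "trajectories"
    gt_dir = out_dir / "ground_truth"
    traj_dir.mkdir(parents=True, exist_ok=True)
    gt_dir.mkdir(parents=True, exist_ok=True)

    annotations = {}
    for _, trial_id, trial in cohort.trials:
        hio.write_trajectory(
            traj_dir / f"{trial_id}.csv",
            trial.times,
            trial.sensor_positions,
            trial.quaternions,
        )
        annotations[trial_id] = trial.annotation
        gt = trial.ground_truth
        payload = {
            "em_event_times": gt.em_event_times.tolist(),
            "cam_event_times": gt.cam_event_times.tolist(),
            "t_delay": gt.t_delay,
            "metrics": gt.metrics,
            "risk_p1": list(gt.risk_p1),
            "risk_p3": list(gt.risk_p3),
            "final_pos": list(gt.final_pos),
            "entered_fistula": gt.entered_fistula,
            "infiltrated": {str(k): v for k, v in gt.infiltrated.items()},
            "infiltration_class": {str(k): v for k, v in gt.infiltration_class.items()},
            "success": gt.success,
        }
        (gt_dir / f"{trial_id}.json").write_text(
            json.dumps(payload, indent=2, sort_keys=True), encoding="utf-8"
        )
    hio.write_events(out_dir / "events.csv", annotations)
    hio.write_geometry(out_dir / "geometry.json", cohort.geometry)
    cohort.manifest.to_csv(out_dir / "cohort_manifest.csv", index=False, float_format="%.9g")
    return out_dir
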