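"""Phase comparisons and the process-to-outcome regression.

Two analyses relate the metric tables produced upstream:

* :func:`compare_phases` — for each process metric, a normality-gated
  two-sample comparison between Phase 1 and Phase 3: Shapiro-Wilk on the
  paired per-trial differences at alpha = 0.05; a paired t-test when
  normality is not rejected, otherwise a Mann-Whitney U test on the two
  phase samples (an unpaired test applied to paired data — kept for
  fidelity to the original analysis; a Wilcoxon signed-rank alternative is
  available behind ``use_wilcoxon``).

* :func:`fit_outcome_regression` — a bivariate-response multiple linear
  regression of the phase's infiltration-risk point (x, y) on the seven
  process metrics.  Each predictor carries a 2-vector coefficient (effect
  on x, effect on y); the fit is two independent ordinary-least-squares
  regressions sharing one design matrix, which yields identical point
  estimates to a stacked formulation.  R^2 is reported in percent per
  response, and per-coefficient two-sided p-values come from the usual
  t statistics.

No multiple-testing correction is applied by default (seven metrics at the
0.05 level); a Holm correction is available behind ``holm``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import CollinearityError, PairingError

__all__ = [
    "PREDICTORS",
    "ComparisonResult",
    "RegressionModel",
    "compare_phases",
    "comparison_table",
    "fit_outcome_regression",
    "significance_table",
]

#: canonical predictor order: duration, path length, velocity, insertion
#: angle, angle change rate, start-point accuracy, lateral angle
PREDICTORS = ("t_s", "pl_mm", "v_mm_s", "alpha_deg", "alpha_dot_deg_s", "a_mm", "beta_deg")

_SHORT = {
    "t_s": "t",
    "pl_mm": "PL",
    "v_mm_s": "v",
    "alpha_deg": "alpha",
    "alpha_dot_deg_s": "alpha_dot",
    "a_mm": "a",
    "beta_deg": "beta",
}

ALPHA = 0.05


@dataclass(frozen=True)
class ComparisonResult:
    metric_name: str
    mean_p1: float
    sd_p1: float
    mean_p3: float
    sd_p3: float
    test_used: str  # "paired-t" | "mann-whitney" | "wilcoxon"
    p_value: float
    normality_p: float

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


@dataclass(frozen=True)
class RegressionModel:
    """Fitted bivariate-response regression for one phase.

    ``coefficients`` is a (2, 8) array: rows are the x and y responses,
    columns the intercept followed by the seven predictors in
    :data:`PREDICTORS` order.  ``p_values`` is shaped likewise.
    """

    phase: int
    coefficients: np.ndarray
    p_values: np.ndarray
    r_squared_x: float  # percent
    r_squared_y: float  # percent
    n_obs: int
    predictor_names: tuple = PREDICTORS
    results_x: object = field(default=None, repr=False, compare=False)
    results_y: object = field(default=None, repr=False, compare=False)

    @property
    def intercept(self) -> np.ndarray:
        return self.coefficients[:, 0]


def _paired(table: pd.DataFrame):
    """Split a long metrics table into phase-1/phase-3 blocks paired by trial."""
    required = {"trial_id", "phase"}
    if not required.issubset(table.columns):
        raise PairingError("metrics table needs 'trial_id' and 'phase' columns")
    p1 = table[table["phase"] == 1].set_index("trial_id").sort_index()
    p3 = table[table["phase"] == 3].set_index("trial_id").sort_index()
    if p1.index.has_duplicates or p3.index.has_duplicates:
        raise PairingError("duplicate (trial, phase) rows")
    if not p1.index.equals(p3.index):
        missing = set(p1.index).symmetric_difference(p3.index)
        raise PairingError(f"unpaired trials between phases: {sorted(missing)}")
    if len(p1) < 3:
        raise PairingError("need at least 3 paired trials")
    return p1, p3


def compare_phases(
    table: pd.DataFrame,
    metrics=PREDICTORS,
    use_wilcoxon: bool = False,
    holm: bool = False,
) -> list[ComparisonResult]:
    """Normality-gated Phase 1 vs Phase 3 comparison for each metric.

    Parameters
    ----------
    table : DataFrame
        Long-format process-metric table with ``trial_id``, ``phase`` and
        one column per metric.
    use_wilcoxon : bool
        Replace the Mann-Whitney U fallback by a Wilcoxon signed-rank test
        on the paired differences.
    holm : bool
        Apply a Holm step-down correction across the tested metrics.
    """
    p1, p3 = _paired(table)
    results = []
    for name in metrics:
        x1 = p1[name].to_numpy(dtype=float)
        x3 = p3[name].to_numpy(dtype=float)
        diffs = x1 - x3
        if np.allclose(diffs, diffs[0]):
            # constant differences: Shapiro is undefined; treat as normal
            norm_p = 1.0
        else:
            norm_p = float(sps.shapiro(diffs).pvalue)
        if norm_p >= ALPHA:
            test_used = "paired-t"
            if np.allclose(diffs, 0):
                p = 1.0
            else:
                p = float(sps.ttest_rel(x1, x3).pvalue)
        elif use_wilcoxon:
            test_used = "wilcoxon"
            p = float(sps.wilcoxon(x1, x3).pvalue)
        else:
            test_used = "mann-whitney"
            p = float(sps.mannwhitneyu(x1, x3, alternative="two-sided").pvalue)
        results.append(
            ComparisonResult(
                metric_name=name,
                mean_p1=float(np.mean(x1)),
                sd_p1=float(np.std(x1, ddof=1)),
                mean_p3=float(np.mean(x3)),
                sd_p3=float(np.std(x3, ddof=1)),
                test_used=test_used,
                p_value=p,
                normality_p=norm_p,
            )
        )
    if holm:
        results = _holm_adjust(results)
    return results


def _holm_adjust(results):
    order = np.argsort([r.p_value for r in results])
    m = len(results)
    adjusted = [None] * m
    running = 0.0
    for rank, idx in enumerate(order):
        r = results[idx]
        p_adj = min(1.0, (m - rank) * r.p_value)
        running = max(running, p_adj)
        adjusted[idx] = ComparisonResult(
            metric_name=r.metric_name,
            mean_p1=r.mean_p1,
            sd_p1=r.sd_p1,
            mean_p3=r.mean_p3,
            sd_p3=r.sd_p3,
            test_used=r.test_used,
            p_value=running,
            normality_p=r.normality_p,
        )
    return adjusted


def comparison_table(results) -> pd.DataFrame:
    """Shape a list of comparison results into a mean +/- SD / p-value table."""
    rows = []
    for r in results:
        rows.append(
            {
                "metric": _SHORT.get(r.metric_name, r.metric_name),
                "mean_p1": r.mean_p1,
                "sd_p1": r.sd_p1,
                "mean_p3": r.mean_p3,
                "sd_p3": r.sd_p3,
                "test": r.test_used,
                "p_value": r.p_value,
                "significant": "*" if r.significant else "",
            }
        )
    return pd.DataFrame(rows)


def _check_rank(design: np.ndarray, names):
    """Raise CollinearityError naming columns lying in the span of earlier ones."""
    n, k = design.shape
    if np.linalg.matrix_rank(design) == k:
        return
    offending = []
    for j in range(1, k):
        prev = design[:, :j]
        col = design[:, j]
        resid = col - prev @ np.linalg.lstsq(prev, col, rcond=None)[0]
        scale = np.linalg.norm(col) or 1.0
        if np.linalg.norm(resid) < 1e-8 * scale:
            offending.append(names[j])
    raise CollinearityError(
        f"rank-deficient design; collinear columns: {offending}", columns=offending
    )


def fit_outcome_regression(
    process: pd.DataFrame,
    outcomes: pd.DataFrame,
    phase: int,
) -> RegressionModel:
    """Fit the bivariate risk-point regression for one phase.

    ``process`` is the long metrics table (filtered internally to ``phase``),
    ``outcomes`` the per-trial outcome table carrying the risk-point columns
    ``x{phase}_mm`` / ``y{phase}_mm``.  Rows are matched on ``trial_id``.
    """
    if phase not in (1, 3):
        raise ValueError("regression is defined for phases 1 and 3")
    proc = process[process["phase"] == phase].set_index("trial_id").sort_index()
    outc = outcomes.set_index("trial_id").sort_index()
    common = proc.index.intersection(outc.index)
    if len(common) < 10:
        raise PairingError(
            f"need >= 10 complete rows for the regression, got {len(common)}"
        )
    proc, outc = proc.loc[common], outc.loc[common]

    X = proc[list(PREDICTORS)].to_numpy(dtype=float)
    design = sm.add_constant(X, has_constant="add")
    names = ("const",) + PREDICTORS
    _check_rank(design, names)
    y_x = outc[f"x{phase}_mm"].to_numpy(dtype=float)
    y_y = outc[f"y{phase}_mm"].to_numpy(dtype=float)

    fit_x = sm.OLS(y_x, design).fit()
    fit_y = sm.OLS(y_y, design).fit()
    return RegressionModel(
        phase=phase,
        coefficients=np.vstack([fit_x.params, fit_y.params]),
        p_values=np.vstack([fit_x.pvalues, fit_y.pvalues]),
        r_squared_x=float(100.0 * fit_x.rsquared),
        r_squared_y=float(100.0 * fit_y.rsquared),
        n_obs=int(len(common)),
        results_x=fit_x,
        results_y=fit_y,
    )


def _format_p(p: float) -> str:
    if p < 0.001:
        return "<0.001*"
    return f"{p:.3f}" + ("*" if p < ALPHA else "")


def significance_table(models) -> pd.DataFrame:
    """Per-predictor p-value table across phases and responses.

    One row per (phase, response) with the seven predictor p-values
    (stars at p < 0.05) and the response R^2 in percent.  Accepts a single
    fitted model or an iterable of them.
    """
    if isinstance(models, RegressionModel):
        models = [models]
    rows = []
    for model in models:
        for resp_idx, resp in enumerate(("x", "y")):
            row = {"phase": model.phase, "response": resp}
            for j, name in enumerate(model.predictor_names):
                row[_SHORT.get(name, name)] = _format_p(float(model.p_values[resp_idx, j + 1]))
            row["r_squared_pct"] = (
                model.r_squared_x if resp == "x" else model.r_squared_y
            )
            rows.append(row)
    return pd.DataFrame(rows)
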