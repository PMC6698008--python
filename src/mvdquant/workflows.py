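"""End-to-end cohort workflows composing the statistics layer.

These glue functions mirror the study's analysis flow: dichotomize each
continuous marker per stage at its Youden-optimal cutoff, compare
disease-free survival between the high and low groups (Kaplan-Meier /
log-rank / univariate Cox), and build the 5-year multivariate model by
backward-stepwise Cox elimination.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import (
    ConvergenceError,
    CutoffResult,
    SurvivalFit,
    StepwiseCoxResult,
    cox_backward_stepwise,
    dichotomize_by_stage,
    km_logrank,
)

__all__ = [
    "add_marker_groups",
    "marker_survival_by_stage",
    "stepwise_by_stage",
    "DEFAULT_STEPWISE_CANDIDATES",
]

#: covariates entered into the multivariate backward-stepwise model
DEFAULT_STEPWISE_CANDIDATES = [
    "mvd_high",
    "tsp_high",
    "hif1a_high",
    "vegfa_high",
    "right_sided",
    "diameter_mm",
    "grade_poor",
    "ulceration",
    "angioinvasion",
]


def add_marker_groups(
    cohort: pd.DataFrame,
    markers: tuple[str, ...] = ("mvd_percent", "tsp_percent", "hif1a_score", "vegfa_score"),
    outcome: str = "dfs_event",
) -> tuple[pd.DataFrame, dict[str, dict[str, CutoffResult]]]:
    """Append per-stage high/low indicator columns for each marker.

    Each marker gets a ``<prefix>_high`` column (1 = strictly above the
    stage-specific Youden cutoff); rows with a missing marker value keep
    a missing indicator.  Returns the augmented table and the cutoffs,
    keyed marker -> stage.
    """
    out = cohort.copy()
    cutoffs: dict[str, dict[str, CutoffResult]] = {}
    for marker in markers:
        prefix = marker.split("_")[0]
        col = f"{prefix}_high"
        complete = out[out[marker].notna()]
        ind, cuts = dichotomize_by_stage(complete, marker=marker, outcome=outcome)
        out[col] = np.nan
        out.loc[complete.index, col] = ind
        cutoffs[marker] = cuts
    return out, cutoffs


def marker_survival_by_stage(
    cohort: pd.DataFrame,
    marker: str = "mvd_percent",
    outcome: str = "dfs_event",
    time_col: str = "dfs_months",
) -> dict[str, dict]:
    """Per-stage dichotomization and high-vs-low survival comparison.

    Returns, per stage, the Youden cutoff and the two-group survival fit
    (Kaplan-Meier curves, log-rank p, Cox hazard ratio for high vs low).
    Rows missing the marker are dropped (listwise deletion).
    """
    results: dict[str, dict] = {}
    for stage, sub in cohort.groupby("stage", sort=True):
        sub = sub[sub[marker].notna()]
        ind, cuts = dichotomize_by_stage(sub, marker=marker, outcome=outcome)
        fit: SurvivalFit | None
        try:
            fit = km_logrank(sub[time_col], sub[outcome], ind.to_numpy())
        except (ConvergenceError, ValueError):
            fit = None
        results[str(stage)] = {"cutoff": cuts[str(stage)], "fit": fit, "n": len(sub)}
    return results


def stepwise_by_stage(
    cohort: pd.DataFrame,
    stage: str,
    candidates: list[str] | None = None,
    p_out: float = 0.1,
    horizon_months: float = 60.0,
    outcome: str = "dfs_event",
    time_col: str = "dfs_months",
) -> StepwiseCoxResult:
    """Backward-stepwise multivariate Cox for one stage's 5-year DFS.

    Marker indicator columns are created if absent; ``grade`` is entered
    as a poor-vs-rest indicator.  Listwise deletion over the candidate
    set is applied before fitting.
    """
    candidates = list(candidates or DEFAULT_STEPWISE_CANDIDATES)
    sub = cohort[cohort["stage"] == stage].copy()
    if "grade_poor" in candidates and "grade_poor" not in sub.columns:
        sub["grade_poor"] = (sub["grade"] == "poor").astype(int)
    missing_inds = [c for c in candidates if c.endswith("_high") and c not in sub.columns]
    if missing_inds:
        sub, _ = add_marker_groups(sub, outcome=outcome)
    candidates = [c for c in candidates if c in sub.columns]
    design = sub[[time_col, outcome, *candidates]].dropna()
    # constant columns cannot enter a Cox model; drop them up front
    keep = [c for c in candidates if design[c].nunique() > 1]
    return cox_backward_stepwise(
        design[time_col],
        design[outcome],
        design[keep].astype(float),
        p_out=p_out,
        horizon_months=horizon_months,
    )
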