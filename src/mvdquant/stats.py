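"""Cohort statistics: dichotomization, baseline tests, and survival models.

Implements the statistical layer of the MVD study design:

* ROC-based dichotomization of continuous markers at the Youden-optimal
  cutoff (highest sensitivity + specificity), per disease stage;
* ordinal tissue-microarray core-score aggregation;
* baseline-table comparisons (Pearson chi-square without continuity
  correction, pooled-variance t-test, Mann-Whitney U, Lilliefors-corrected
  Kolmogorov-Smirnov normality);
* Kaplan-Meier curves with log-rank tests;
* Cox proportional-hazards fits (Breslow ties by default, Efron by
  flag) and backward-stepwise elimination at a Wald p-out threshold;
* Spearman rank correlation.

Conventions follow common clinical-statistics practice: two-sided tests
throughout, 95% Wald confidence intervals on hazard ratios, listwise
deletion of missing marker values within each analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats as sps
from statsmodels.duration.hazard_regression import PHReg
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "ConvergenceError",
    "CutoffResult",
    "ContingencyResult",
    "CorrelationResult",
    "SurvivalFit",
    "CoxFit",
    "StepwiseCoxResult",
    "dichotomize_roc",
    "dichotomize_by_stage",
    "aggregate_tma_scores",
    "pearson_chi2",
    "ttest_ind",
    "mann_whitney",
    "ks_normality",
    "km_logrank",
    "cox_fit",
    "cox_backward_stepwise",
    "spearman",
    "baseline_table",
]


class ConvergenceError(RuntimeError):
    """Cox partial-likelihood maximization failed or is monotone."""


@dataclass
class CutoffResult:
    """Youden-optimal dichotomization cutoff for a continuous marker."""

    cutoff: float
    sensitivity: float
    specificity: float
    youden_j: float
    direction: str  # "high_positive": values > cutoff predict the event

    def to_dict(self) -> dict:
        return {
            "cutoff": self.cutoff,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "youden_j": self.youden_j,
            "direction": self.direction,
        }


@dataclass
class ContingencyResult:
    chi2: float
    df: int
    p: float


@dataclass
class CorrelationResult:
    rho: float
    p: float
    n: int


@dataclass
class SurvivalFit:
    """Two-group survival comparison: KM curves, log-rank, Cox HR."""

    hr: float
    ci_low: float
    ci_high: float
    logrank_p: float
    wald_p: float
    n: int
    n_events: int
    km_curves: dict = field(default_factory=dict)  # group -> DataFrame(time, survival)


@dataclass
class CoxFit:
    """Cox proportional-hazards fit summary (one row per covariate)."""

    summary: pd.DataFrame  # columns: covariate, coef, se, hr, ci_low, ci_high, p
    n: int
    n_events: int
    ties: str

    def coef(self, name: str) -> float:
        return float(self.summary.set_index("covariate").loc[name, "coef"])

    def hr(self, name: str) -> float:
        return float(self.summary.set_index("covariate").loc[name, "hr"])

    def p(self, name: str) -> float:
        return float(self.summary.set_index("covariate").loc[name, "p"])


@dataclass
class StepwiseCoxResult:
    retained: pd.DataFrame  # columns: covariate, coef, se, hr, ci_low, ci_high, p
    removal_trace: list  # ordered (covariate, p_at_removal)
    final_fit: CoxFit | None


# ---------------------------------------------------------------------------
# dichotomization
# ---------------------------------------------------------------------------


def dichotomize_roc(
    values: Sequence[float], outcome: Sequence[int]
) -> CutoffResult:
    """Youden-optimal cutoff over all midpoints between distinct values.

    Every midpoint between consecutive sorted distinct marker values is
    evaluated in both directions ("high" group = strictly greater than
    the cutoff, or its mirror); the cutoff maximizing
    J = sensitivity + specificity - 1 is returned, ties broken toward
    the smallest cutoff and toward the high-positive direction.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(outcome, dtype=int)
    if v.shape != y.shape or v.ndim != 1:
        raise ValueError("values and outcome must be equal-length 1-d sequences")
    ok = ~np.isnan(v)
    v, y = v[ok], y[ok]
    if np.unique(v).size < 2:
        raise ValueError("need at least 2 distinct marker values")
    if np.unique(y).size < 2:
        raise ValueError("both outcome classes must be present")
    distinct = np.unique(v)
    cutoffs = (distinct[:-1] + distinct[1:]) / 2.0
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    # sens/spec for the high-positive direction at each cutoff
    pred_high = v[None, :] > cutoffs[:, None]
    tp = (pred_high & (y == 1)).sum(axis=1)
    tn = (~pred_high & (y == 0)).sum(axis=1)
    sens = tp / n_pos
    spec = tn / n_neg
    j_high = sens + spec - 1.0

    best_i, best_dir, best_j = 0, "high_positive", -np.inf
    for i, c in enumerate(cutoffs):
        for direction, j in (("high_positive", j_high[i]), ("low_positive", -j_high[i])):
            if j > best_j + 1e-12:
                best_i, best_dir, best_j = i, direction, j
    if best_dir == "high_positive":
        se, sp = float(sens[best_i]), float(spec[best_i])
    else:
        se, sp = 1.0 - float(sens[best_i]), 1.0 - float(spec[best_i])
    return CutoffResult(
        cutoff=float(cutoffs[best_i]),
        sensitivity=se,
        specificity=sp,
        youden_j=float(best_j),
        direction=best_dir,
    )


def dichotomize_by_stage(
    cohort: pd.DataFrame,
    marker: str = "mvd_percent",
    outcome: str = "dfs_event",
    stage_col: str = "stage",
) -> tuple[pd.Series, dict[str, CutoffResult]]:
    """Stage-specific Youden cutoffs; returns the high/low indicator.

    The "high" group is marker strictly greater than the stage's cutoff,
    regardless of the direction in which the marker predicts the event.
    """
    indicator = pd.Series(np.zeros(len(cohort), dtype=int), index=cohort.index,
                          name=f"{marker}_high")
    cutoffs: dict[str, CutoffResult] = {}
    for stage, sub in cohort.groupby(stage_col, sort=True):
        res = dichotomize_roc(sub[marker].to_numpy(), sub[outcome].to_numpy())
        cutoffs[str(stage)] = res
        indicator.loc[sub.index] = (sub[marker] > res.cutoff).astype(int)
    return indicator, cutoffs


def aggregate_tma_scores(core_scores: Iterable) -> float:
    """Mean of up to six non-missing ordinal (0-3) core intensities.

    Missing cores (None/NaN, damaged or absent) are skipped; an
    all-missing patient yields NaN.
    """
    vals = []
    for s in core_scores:
        if s is None or (isinstance(s, float) and np.isnan(s)):
            continue
        f = float(s)
        if not 0.0 <= f <= 3.0:
            raise ValueError(f"core score {s!r} outside the ordinal range 0-3")
        vals.append(f)
    if len(vals) > 6:
        raise ValueError("at most 6 cores per patient")
    return float(np.mean(vals)) if vals else float("nan")


# ---------------------------------------------------------------------------
# baseline tests
# ---------------------------------------------------------------------------


def pearson_chi2(table: Sequence[Sequence[int]]) -> ContingencyResult:
    """Pearson chi-square on an r x k count table, no continuity correction."""
    t = np.asarray(table)
    if t.ndim != 2 or np.any(t < 0) or not np.issubdtype(t.dtype, np.number):
        raise ValueError("table must be a 2-d array of non-negative counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("degenerate margins: all-zero row or column")
    chi2, p, df, _ = sps.chi2_contingency(t, correction=False)
    return ContingencyResult(chi2=float(chi2), df=int(df), p=float(p))


def ttest_ind(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pooled-variance two-sided independent-samples t-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 observations per sample")
    if np.var(x) == 0 and np.var(y) == 0:
        raise ValueError("zero variance in both samples")
    t, p = sps.ttest_ind(x, y, equal_var=True)
    return float(t), float(p)


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (exact for small untied samples,
    otherwise normal approximation with tie correction)."""
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 observations per sample")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def ks_normality(x: Sequence[float]) -> tuple[float, float]:
    """Kolmogorov-Smirnov normality test with the Lilliefors correction
    (mean and variance estimated from the sample)."""
    x = np.asarray(x, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 observations")
    d, p = lilliefors(x, dist="norm")
    return float(d), float(p)


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation with midrank ties, two-sided t-approx p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("constant input")
    rho, p = sps.spearmanr(x, y)
    return CorrelationResult(rho=float(rho), p=float(p), n=int(len(x)))


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------


def _as_survival_arrays(times, events):
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.shape != e.shape or t.ndim != 1:
        raise ValueError("times and events must be equal-length 1-d sequences")
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    return t, e


def cox_fit(
    times: Sequence[float],
    events: Sequence[int],
    covariates: pd.DataFrame | np.ndarray,
    names: Sequence[str] | None = None,
    ties: str = "breslow",
) -> CoxFit:
    """Cox proportional-hazards fit by partial-likelihood maximization.

    HR = exp(coef); 95% CI = exp(coef +- 1.96 * SE); two-sided Wald p.
    Ties handled by Breslow's approximation by default (Efron by flag).

    Raises :class:`ConvergenceError` on non-convergence or a monotone
    likelihood (perfect separation).
    """
    t, e = _as_survival_arrays(times, events)
    if isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        X = covariates.to_numpy(dtype=float)
    else:
        X = np.asarray(covariates, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = list(names) if names is not None else [f"x{i}" for i in range(X.shape[1])]
    if ties not in ("breslow", "efron"):
        raise ValueError("ties must be 'breslow' or 'efron'")
    if e.sum() < 1:
        raise ValueError("need at least 1 event")
    if np.any(np.ptp(X, axis=0) == 0):
        const = [names[i] for i in np.nonzero(np.ptp(X, axis=0) == 0)[0]]
        raise ValueError(f"constant covariates: {const}")

    model = PHReg(t, X, status=e, ties=ties)
    try:
        with warnings.catch_warnings():
            # separation shows up as an optimizer warning; it is re-diagnosed
            # below and raised as ConvergenceError
            warnings.simplefilter("ignore")
            res = model.fit(disp=False)
    except Exception as exc:  # noqa: BLE001 — surfaced as a domain error
        raise ConvergenceError(f"Cox fit failed: {exc}") from exc
    coef = np.asarray(res.params, dtype=float)
    se = np.asarray(res.bse, dtype=float)
    if not (np.all(np.isfinite(coef)) and np.all(np.isfinite(se))):
        raise ConvergenceError("Cox fit did not converge (non-finite estimates)")
    if np.any(np.abs(coef) > 20) or np.any(se > 100):
        raise ConvergenceError(
            "monotone partial likelihood (perfect separation suspected)"
        )
    z = coef / se
    p = 2.0 * sps.norm.sf(np.abs(z))
    summary = pd.DataFrame(
        {
            "covariate": names,
            "coef": coef,
            "se": se,
            "hr": np.exp(coef),
            "ci_low": np.exp(coef - 1.96 * se),
            "ci_high": np.exp(coef + 1.96 * se),
            "p": p,
        }
    )
    return CoxFit(summary=summary, n=len(t), n_events=int(e.sum()), ties=ties)


def km_logrank(
    times: Sequence[float],
    events: Sequence[int],
    group: Sequence,
    ties: str = "breslow",
) -> SurvivalFit:
    """Two-group Kaplan-Meier curves, log-rank test, and Cox HR.

    The hazard ratio contrasts the second group (sorted order) against
    the first; at tied times, events precede censorings in the risk set.
    """
    t, e = _as_survival_arrays(times, events)
    g = np.asarray(group)
    levels = np.unique(g)
    if levels.size != 2:
        raise ValueError(f"need exactly 2 non-empty groups, got {levels.size}")
    curves = {}
    for lv in levels:
        sel = g == lv
        kmf = KaplanMeierFitter()
        kmf.fit(t[sel], e[sel])
        sf = kmf.survival_function_
        curves[lv] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
    sel1 = g == levels[1]
    lr = logrank_test(t[sel1], t[~sel1], e[sel1], e[~sel1])
    fit = cox_fit(t, e, sel1.astype(float)[:, None], names=["group"], ties=ties)
    row = fit.summary.iloc[0]
    return SurvivalFit(
        hr=float(row["hr"]),
        ci_low=float(row["ci_low"]),
        ci_high=float(row["ci_high"]),
        logrank_p=float(lr.p_value),
        wald_p=float(row["p"]),
        n=len(t),
        n_events=int(e.sum()),
        km_curves=curves,
    )


def cox_backward_stepwise(
    times: Sequence[float],
    events: Sequence[int],
    candidates: pd.DataFrame,
    p_out: float = 0.1,
    horizon_months: float | None = 60.0,
    ties: str = "breslow",
) -> StepwiseCoxResult:
    """Backward elimination: drop the worst Wald p > p_out, refit, repeat.

    Subjects with follow-up beyond ``horizon_months`` are
    administratively censored at the horizon before fitting (5-year
    disease-free survival for the default 60).  One variable is removed
    per step, with no re-entry; an empty final model is a valid result.
    """
    if candidates.shape[1] == 0:
        raise ValueError("candidate set must be non-empty")
    t, e = _as_survival_arrays(times, events)
    if horizon_months is not None:
        over = t > horizon_months
        t = np.where(over, horizon_months, t)
        e = np.where(over, 0, e)
    current = list(candidates.columns)
    trace: list[tuple[str, float]] = []
    fit: CoxFit | None = None
    while current:
        try:
            fit = cox_fit(t, e, candidates[current], ties=ties)
        except (ConvergenceError, ValueError) as exc:
            # drop-one retry: remove the first candidate whose exclusion
            # makes the model estimable
            retried = False
            for drop in current:
                rest = [c for c in current if c != drop]
                if not rest:
                    continue
                try:
                    fit = cox_fit(t, e, candidates[rest], ties=ties)
                except (ConvergenceError, ValueError):
                    continue
                trace.append((drop, float("nan")))
                current = rest
                retried = True
                break
            if not retried:
                raise ConvergenceError(
                    f"stepwise Cox failed and no drop-one retry succeeded: {exc}"
                ) from exc
            continue
        worst = fit.summary.loc[fit.summary["p"].idxmax()]
        if worst["p"] > p_out:
            trace.append((str(worst["covariate"]), float(worst["p"])))
            current.remove(worst["covariate"])
            fit = None
        else:
            break
    if current and fit is None:
        fit = cox_fit(t, e, candidates[current], ties=ties)
    if current:
        retained = fit.summary[["covariate", "coef", "se", "hr", "ci_low", "ci_high", "p"]]
    else:
        retained = pd.DataFrame(
            columns=["covariate", "coef", "se", "hr", "ci_low", "ci_high", "p"]
        )
        fit = None
    return StepwiseCoxResult(retained=retained.reset_index(drop=True),
                             removal_trace=trace, final_fit=fit)


# ---------------------------------------------------------------------------
# baseline table
# ---------------------------------------------------------------------------


def baseline_table(
    cohort: pd.DataFrame,
    group_by: str,
    variables: Sequence[str] | None = None,
    continuous: Sequence[str] = ("age", "diameter_mm", "mvd_percent", "tsp_percent"),
) -> pd.DataFrame:
    """Two-group comparison table: counts (%) or mean (sd) with p-values.

    Categorical variables are tested with the uncorrected Pearson
    chi-square on the full level-by-group table; continuous variables
    with the pooled-variance t-test.  The grouping variable must be
    binary within the supplied cohort (stratify upstream if needed).
    """
    groups = sorted(cohort[group_by].dropna().unique().tolist())
    if len(groups) != 2:
        raise ValueError(f"{group_by!r} must be binary, got levels {groups}")
    if variables is None:
        variables = [c for c in cohort.columns
                     if c not in (group_by, "patient_id", "dfs_months")]
    rows = []
    g1 = cohort[cohort[group_by] == groups[0]]
    g2 = cohort[cohort[group_by] == groups[1]]
    for var in variables:
        if var in continuous:
            x = g1[var].dropna().to_numpy(dtype=float)
            y = g2[var].dropna().to_numpy(dtype=float)
            _, p = ttest_ind(x, y)
            rows.append(
                {
                    "variable": var,
                    "level": "mean (sd)",
                    str(groups[0]): f"{x.mean():.1f} ({x.std(ddof=1):.1f})",
                    str(groups[1]): f"{y.mean():.1f} ({y.std(ddof=1):.1f})",
                    "p": p,
                }
            )
        else:
            tab = pd.crosstab(cohort[var], cohort[group_by])
            tab = tab.loc[(tab.sum(axis=1) > 0), :]
            p = pearson_chi2(tab.to_numpy()).p if tab.shape[0] > 1 else np.nan
            for j, (level, row) in enumerate(tab.iterrows()):
                n1 = int(row.get(groups[0], 0))
                n2 = int(row.get(groups[1], 0))
                rows.append(
                    {
                        "variable": var,
                        "level": str(level),
                        str(groups[0]): f"{n1} ({100 * n1 / max(len(g1), 1):.1f})",
                        str(groups[1]): f"{n2} ({100 * n2 / max(len(g2), 1):.1f})",
                        "p": p if j == 0 else np.nan,
                    }
                )
    return pd.DataFrame(rows)
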