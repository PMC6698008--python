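"""Statistics layer: dichotomization, baseline tests, survival models."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps
from scipy.optimize import minimize_scalar

from mvdquant.stats import (
    ConvergenceError,
    aggregate_tma_scores,
    baseline_table,
    cox_backward_stepwise,
    cox_fit,
    dichotomize_roc,
    km_logrank,
    ks_normality,
    mann_whitney,
    pearson_chi2,
    spearman,
    ttest_ind,
)

# ---------------------------------------------------------------------------
# ROC dichotomization
# ---------------------------------------------------------------------------


def _youden_oracle(values, outcome):
    """Exhaustive scan over every midpoint and both directions."""
    values = np.asarray(values, float)
    outcome = np.asarray(outcome, int)
    distinct = np.unique(values)
    best = (-np.inf, None, None)
    for c in (distinct[:-1] + distinct[1:]) / 2.0:
        for direction in ("high_positive", "low_positive"):
            if direction == "high_positive":
                pred = values > c
            else:
                pred = values <= c
            sens = np.mean(pred[outcome == 1])
            spec = np.mean(~pred[outcome == 0])
            j = sens + spec - 1.0
            if j > best[0] + 1e-12:
                best = (j, float(c), direction)
    return best


def test_perfect_separation_yields_unit_youden():
    res = dichotomize_roc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1])
    assert res.youden_j == pytest.approx(1.0)
    assert 3 < res.cutoff < 10
    assert res.direction == "high_positive"


def test_uninformative_marker_gives_zero_j_at_smallest_midpoint():
    res = dichotomize_roc([1, 1, 2, 2], [0, 1, 0, 1])
    assert res.youden_j == pytest.approx(0.0)
    assert res.cutoff == pytest.approx(1.5)
    assert res.direction == "high_positive"


def test_single_outcome_class_rejected():
    with pytest.raises(ValueError, match="both outcome classes"):
        dichotomize_roc([1, 2, 3], [1, 1, 1])


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_youden_cutoff_matches_exhaustive_oracle(seed):
    rng = np.random.default_rng(seed)
    n = 50
    values = np.round(rng.normal(10, 3, n), 1)  # rounding induces ties
    outcome = rng.integers(0, 2, n)
    if len(np.unique(values)) < 2 or len(np.unique(outcome)) < 2:
        return
    res = dichotomize_roc(values, outcome)
    j, cutoff, direction = _youden_oracle(values, outcome)
    assert res.youden_j == pytest.approx(j)
    assert res.cutoff == pytest.approx(cutoff)
    assert res.direction == direction
    assert res.youden_j == pytest.approx(res.sensitivity + res.specificity - 1.0)


# ---------------------------------------------------------------------------
# TMA score aggregation
# ---------------------------------------------------------------------------


def test_tma_aggregation_mean_and_missing_rules():
    assert aggregate_tma_scores([2, 2, 2, 2, 2, 2]) == 2.0
    assert np.isnan(aggregate_tma_scores([None, np.nan, None]))
    assert aggregate_tma_scores([0, 1, 3, None, None, np.nan]) == pytest.approx(4 / 3)
    with pytest.raises(ValueError, match="0-3"):
        aggregate_tma_scores([4])
    with pytest.raises(ValueError, match="at most 6"):
        aggregate_tma_scores([1] * 7)


# ---------------------------------------------------------------------------
# contingency and two-sample tests
# ---------------------------------------------------------------------------


def test_chi2_reproduces_printed_cohort_pvalues():
    # high vs low marker group counts: recurrence and ulceration rows
    assert round(pearson_chi2([[11, 4], [14, 25]]).p, 3) == 0.013
    assert round(pearson_chi2([[10, 5], [35, 4]]).p, 3) == 0.042


def test_chi2_independence_and_degenerate_margins():
    res = pearson_chi2([[10, 10], [10, 10]])
    assert res.chi2 == 0.0 and res.p == 1.0 and res.df == 1
    with pytest.raises(ValueError, match="margins"):
        pearson_chi2([[0, 0], [5, 5]])


def test_chi2_close_to_exact_permutation_midp(rng):
    """Asymptotic p vs the margin-conditioned permutation null (mid-p)."""
    for _ in range(5):
        x = rng.integers(0, 2, 80)
        y = rng.integers(0, 2, 80)
        tab = np.array([[np.sum((x == i) & (y == j)) for j in (0, 1)] for i in (0, 1)])
        if (tab.sum(0) == 0).any() or (tab.sum(1) == 0).any():
            continue
        res = pearson_chi2(tab)
        n, r1, c1 = tab.sum(), tab.sum(1)[0], tab.sum(0)[0]
        ks = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
        probs = sps.hypergeom.pmf(ks, n, r1, c1)
        stats_k = []
        for k in ks:
            t = np.array([[k, r1 - k], [c1 - k, n - r1 - c1 + k]])
            e = np.outer(t.sum(1), t.sum(0)) / n
            stats_k.append(((t - e) ** 2 / e).sum())
        stats_k = np.array(stats_k)
        p_mid = probs[stats_k > res.chi2 + 1e-9].sum() + 0.5 * probs[
            np.isclose(stats_k, res.chi2)
        ].sum()
        assert abs(res.p - p_mid) <= 0.05


def test_identical_samples_symmetry():
    t, p = ttest_ind([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert t == 0.0 and p == 1.0
    u, _ = mann_whitney([1, 2, 3], [1, 2, 3])
    assert u == 3 * 3 / 2


def test_mann_whitney_exact_small_sample():
    u, p = mann_whitney([1, 2, 3], [4, 5, 6])
    assert u == 0.0
    assert p == pytest.approx(0.1)


def test_ttest_zero_variance_rejected():
    with pytest.raises(ValueError, match="variance"):
        ttest_ind([2.0, 2.0, 2.0], [2.0, 2.0])


def test_ttest_null_pvalues_are_uniform(rng):
    """Under H0 the two-sided p-value is U(0,1) across replicates."""
    pvals = [
        ttest_ind(rng.normal(size=1000), rng.normal(size=1000))[1] for _ in range(500)
    ]
    d, p = sps.kstest(pvals, "uniform")
    assert p > 0.01


def test_lilliefors_normality_direction(rng):
    d_norm, p_norm = ks_normality(rng.normal(size=200))
    d_unif, p_unif = ks_normality(rng.uniform(size=200))
    assert p_norm > 0.05
    assert p_unif < 0.01


def test_spearman_monotone_and_midrank_tie_oracle(rng):
    x = np.arange(10.0)
    up = spearman(x, np.exp(x))
    down = spearman(x, -(x**3))
    assert up.rho == pytest.approx(1.0) and down.rho == pytest.approx(-1.0)
    xt = rng.integers(0, 4, 10).astype(float)  # heavy ties
    yt = rng.integers(0, 4, 10).astype(float)
    if len(np.unique(xt)) > 1 and len(np.unique(yt)) > 1:
        res = spearman(xt, yt)
        oracle = np.corrcoef(sps.rankdata(xt), sps.rankdata(yt))[0, 1]
        assert res.rho == pytest.approx(oracle)
    with pytest.raises(ValueError, match="constant"):
        spearman([1, 1, 1], [1, 2, 3])


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank
# ---------------------------------------------------------------------------


def _logrank_oracle(times, events, group):
    """Hand risk-set computation: chi2 = (sum O-E)^2 / sum V."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    group = np.asarray(group, int)
    o_minus_e, var = 0.0, 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t  # events precede censorings at tied times
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (group == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = o_minus_e**2 / var
    return chi2, sps.chi2.sf(chi2, 1)


def test_identical_groups_logrank_is_null():
    times = [3.0, 5.0, 8.0, 12.0]
    events = [1, 0, 1, 0]
    fit = km_logrank(times * 2, events * 2, [0] * 4 + [1] * 4)
    assert fit.logrank_p == pytest.approx(1.0)
    assert fit.hr == pytest.approx(1.0, abs=1e-6)


def test_logrank_matches_hand_risk_set_oracle():
    times = [2.0, 4.0, 4.0, 7.0, 9.0, 11.0]
    events = [1, 1, 0, 1, 0, 1]
    group = [0, 1, 0, 1, 0, 1]
    chi2, p = _logrank_oracle(times, events, group)
    fit = km_logrank(times, events, group)
    assert fit.logrank_p == pytest.approx(p, rel=1e-6)


def test_logrank_asymptotic_p_matches_permutation_null(rng):
    n = 60
    times = rng.exponential(50, n)
    events = (rng.random(n) < 0.7).astype(int)
    group = rng.integers(0, 2, n)
    if group.sum() in (0, n):
        group[:5] = 1 - group[0]
    obs_chi2, p_asym = _logrank_oracle(times, events, group)
    perm_stats = np.empty(2000)
    g = group.copy()
    for i in range(2000):
        rng.shuffle(g)
        perm_stats[i], _ = _logrank_oracle(times, events, g)
    p_perm = np.mean(perm_stats >= obs_chi2)
    mc_se = np.sqrt(max(p_perm * (1 - p_perm), 1e-4) / 2000)
    assert abs(p_asym - p_perm) <= max(3 * mc_se, 0.03)


def test_km_curves_are_monotone_step_functions():
    rng = np.random.default_rng(1)
    times = rng.exponential(30, 80)
    events = (rng.random(80) < 0.6).astype(int)
    group = rng.integers(0, 2, 80)
    fit = km_logrank(times, events, group)
    for curve in fit.km_curves.values():
        surv = curve["survival"].to_numpy()
        assert surv[0] == pytest.approx(1.0)
        assert (np.diff(surv) <= 1e-12).all()


def test_km_logrank_needs_two_groups():
    with pytest.raises(ValueError, match="2"):
        km_logrank([1.0, 2.0], [1, 1], [0, 0])


# ---------------------------------------------------------------------------
# Cox regression
# ---------------------------------------------------------------------------


def test_single_event_partial_likelihood_matches_closed_form():
    # one event among three subjects: L(b) = exp(b*x1) / sum_j exp(b*xj)
    times = [1.0, 2.0, 3.0]
    events = [1, 0, 0]
    x = np.array([1.0, 0.0, 2.0])

    def nll(b):
        return -(b * x[0] - np.log(np.exp(b * x).sum()))

    oracle = minimize_scalar(nll, bounds=(-10, 10), method="bounded").x
    fit = cox_fit(times, events, x[:, None], names=["x"])
    assert fit.coef("x") == pytest.approx(oracle, abs=1e-4)


def test_cox_requires_events_and_variation():
    with pytest.raises(ValueError, match="event"):
        cox_fit([1.0, 2.0], [0, 0], np.array([[1.0], [0.0]]))
    with pytest.raises(ValueError, match="constant"):
        cox_fit([1.0, 2.0, 3.0], [1, 1, 0], np.array([[1.0], [1.0], [1.0]]))


def test_cox_perfect_separation_raises_explicitly():
    times = [1.0, 2.0, 3.0, 4.0, 10.0, 11.0, 12.0, 13.0]
    events = [1, 1, 1, 1, 0, 0, 0, 0]
    x = np.array([1.0] * 4 + [0.0] * 4)
    with pytest.raises(ConvergenceError):
        cox_fit(times, events, x[:, None])


def test_breslow_and_efron_agree_without_ties(rng):
    times = rng.exponential(20, 100) + rng.uniform(0, 1e-3, 100)  # no ties
    events = (rng.random(100) < 0.7).astype(int)
    x = rng.normal(size=(100, 1))
    b = cox_fit(times, events, x, ties="breslow")
    e = cox_fit(times, events, x, ties="efron")
    assert b.summary["coef"].iloc[0] == pytest.approx(e.summary["coef"].iloc[0], abs=1e-6)


# ---------------------------------------------------------------------------
# backward stepwise
# ---------------------------------------------------------------------------


def _sim_survival(n, beta_strong, rng):
    strong = rng.integers(0, 2, n).astype(float)
    noise = rng.integers(0, 2, n).astype(float)
    t = rng.exponential(1.0 / (0.02 * np.exp(beta_strong * strong)))
    c = rng.exponential(80, n)
    return pd.DataFrame(
        {
            "time": np.minimum(t, c),
            "event": (t <= c).astype(int),
            "strong": strong,
            "noise": noise,
        }
    )


def test_stepwise_keeps_strong_effect_and_drops_noise():
    df = _sim_survival(1000, np.log(2.5), np.random.default_rng(2024))
    res = cox_backward_stepwise(
        df["time"], df["event"], df[["strong", "noise"]], p_out=0.1,
        horizon_months=None,
    )
    assert "strong" in list(res.retained["covariate"])
    removed = [name for name, _ in res.removal_trace]
    assert "noise" in removed
    assert (res.retained["p"] <= 0.1).all()


def test_stepwise_single_strong_covariate_retained():
    df = _sim_survival(500, np.log(3), np.random.default_rng(7))
    res = cox_backward_stepwise(df["time"], df["event"], df[["strong"]],
                                horizon_months=None)
    assert list(res.retained["covariate"]) == ["strong"]


def test_stepwise_empty_model_is_valid_return():
    df = _sim_survival(300, 0.0, np.random.default_rng(99))
    res = cox_backward_stepwise(df["time"], df["event"], df[["strong", "noise"]],
                                horizon_months=None)
    # candidates are partitioned between retained and the removal trace
    removed = {name for name, _ in res.removal_trace}
    assert removed | set(res.retained["covariate"]) == {"strong", "noise"}


def test_stepwise_horizon_censors_late_follow_up():
    # events beyond the 60-month horizon must not drive the fit
    times = [10.0, 20.0, 30.0, 40.0, 70.0, 90.0]
    events = [1, 1, 0, 1, 1, 1]
    x = pd.DataFrame({"x": [1.0, 0.0, 1.0, 0.0, 1.0, 0.0]})
    res = cox_backward_stepwise(times, events, x, p_out=1.1, horizon_months=60.0)
    t_trunc = np.minimum(times, 60.0)
    e_trunc = np.where(np.asarray(times) > 60.0, 0, events)
    direct = cox_fit(t_trunc, e_trunc, x)
    assert res.retained["coef"].iloc[0] == pytest.approx(direct.coef("x"))


# ---------------------------------------------------------------------------
# baseline table
# ---------------------------------------------------------------------------


def _cohort_from_counts(n_low, n_high, rec_low, rec_high, ulc_low, ulc_high):
    """Rebuild patient rows from grouped counts."""
    rows = []
    for group, n, rec, ulc in (
        (0, n_low, rec_low, ulc_low),
        (1, n_high, rec_high, ulc_high),
    ):
        for i in range(n):
            rows.append(
                {"mvd_group": group, "recurrence": int(i < rec), "ulceration": int(i < ulc)}
            )
    return pd.DataFrame(rows)


def test_baseline_table_reproduces_printed_stage3_pvalues():
    # low: 11/15 recurrences, 10/15 ulceration; high: 14/39 and 35/39
    cohort = _cohort_from_counts(15, 39, 11, 14, 10, 35)
    table = baseline_table(cohort, "mvd_group", variables=["recurrence", "ulceration"])
    p_rec = table.loc[table["variable"] == "recurrence", "p"].dropna().iloc[0]
    p_ulc = table.loc[table["variable"] == "ulceration", "p"].dropna().iloc[0]
    assert round(p_rec, 3) == 0.013
    assert round(p_ulc, 3) == 0.042


def test_baseline_table_identical_groups_give_unit_pvalues():
    cohort = _cohort_from_counts(20, 20, 8, 8, 12, 12)
    table = baseline_table(cohort, "mvd_group", variables=["recurrence", "ulceration"])
    assert (table["p"].dropna() == 1.0).all()


def test_baseline_table_continuous_row_uses_t_test(rng):
    df = pd.DataFrame(
        {
            "g": np.repeat([0, 1], 50),
            "age": np.r_[rng.normal(70, 10, 50), rng.normal(66, 10, 50)],
        }
    )
    table = baseline_table(df, "g", variables=["age"], continuous=("age",))
    _, p = ttest_ind(df.loc[df.g == 0, "age"], df.loc[df.g == 1, "age"])
    assert table["p"].iloc[0] == pytest.approx(p)
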