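"""Survival analysis of the simulated cohorts.

Reproduces the statistical flow on the cohorts from
``04_simulate_cohorts.py``: per-stage Youden dichotomization of MVD,
Kaplan-Meier / log-rank / univariate Cox for high vs low MVD, the
baseline comparison table, and the backward-stepwise multivariate Cox
model for 5-year disease-free survival.  Writes survival JSON, KM curve
coordinates, baseline tables and the stepwise trace under ``results/``.
"""

from pathlib import Path

import pandas as pd

from mvdquant.io import read_cohort, write_json
from mvdquant.stats import baseline_table
from mvdquant.workflows import add_marker_groups, marker_survival_by_stage, stepwise_by_stage

OUT = Path(__file__).resolve().parents[1] / "results"


def analyse(name: str) -> None:
    cohort = read_cohort(OUT / name / "cohort.csv")
    print(f"\n=== {name} ({len(cohort)} patients) ===")

    res = marker_survival_by_stage(cohort, marker="mvd_percent")
    payload, curve_rows = {}, []
    for stage, r in sorted(res.items()):
        fit = r["fit"]
        payload[stage] = {
            "n": r["n"],
            "cutoff_percent": r["cutoff"].cutoff,
            "youden_j": r["cutoff"].youden_j,
            "hr_high_vs_low": None if fit is None else fit.hr,
            "ci_95": None if fit is None else [fit.ci_low, fit.ci_high],
            "logrank_p": None if fit is None else fit.logrank_p,
        }
        if fit is not None:
            print(f"stage {stage}: cutoff {r['cutoff'].cutoff:.2f}%, "
                  f"HR {fit.hr:.2f} [{fit.ci_low:.2f}, {fit.ci_high:.2f}], "
                  f"log-rank p = {fit.logrank_p:.4f}")
            for level, curve in fit.km_curves.items():
                for _, row in curve.iterrows():
                    curve_rows.append({"stage": stage, "mvd_high": int(level),
                                       "time": row["time"], "survival": row["survival"]})
    write_json(payload, OUT / name / "survival_mvd.json")
    pd.DataFrame(curve_rows).to_csv(OUT / name / "km_curves.csv", index=False)

    with_groups, _ = add_marker_groups(cohort)
    for stage, sub in with_groups.groupby("stage"):
        sub = sub[sub["mvd_high"].notna()]
        if sub["mvd_high"].nunique() == 2:
            table = baseline_table(sub.drop(columns=["stage"]), "mvd_high")
            table.to_csv(OUT / name / f"baseline_stage_{stage}.csv", index=False)

    for stage in ("II", "III"):
        sw = stepwise_by_stage(cohort, stage)
        write_json(
            {
                "retained": sw.retained.to_dict(orient="records"),
                "removal_trace": [{"covariate": c, "p_at_removal": p}
                                  for c, p in sw.removal_trace],
            },
            OUT / name / f"stepwise_stage_{stage}.json",
        )
        kept = ", ".join(
            f"{r.covariate} (HR {r.hr:.2f}, p {r.p:.3f})"
            for r in sw.retained.itertuples()
        ) or "(empty model)"
        print(f"stage {stage} stepwise retained: {kept}")


def main() -> None:
    for name in ("cohort", "cohort_large"):
        analyse(name)


if __name__ == "__main__":
    main()
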