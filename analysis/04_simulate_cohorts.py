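"""Simulate the study-style two-stage cohort with opposite MVD effects.

Draws a cohort of 53 stage II + 54 stage III patients — the size of the
published series — with a harmful high-MVD effect in stage II
(log HR = +1) and a protective one in 5FU-treated stage III
(log HR = -1), ~30% censoring, and writes ``results/cohort/cohort.csv``
plus the generator truth.  A second, larger cohort (200/stage) is
written for the better-powered survival analysis in step 05.
"""

from pathlib import Path

from mvdquant import CohortSpec, generate_cohort
from mvdquant.io import write_cohort, write_json

OUT = Path(__file__).resolve().parents[1] / "results"

EFFECTS = {"mvd_high:II": 1.0, "mvd_high:III": -1.0}


def main() -> None:
    for name, n2, n3, seed in (("cohort", 53, 54, 1), ("cohort_large", 200, 200, 2)):
        spec = CohortSpec(n_stage2=n2, n_stage3=n3, true_log_hrs=dict(EFFECTS),
                          censor_rate=0.3, seed=seed)
        cohort, truth = generate_cohort(spec)
        outdir = OUT / name
        outdir.mkdir(parents=True, exist_ok=True)
        write_cohort(cohort, outdir / "cohort.csv")
        write_json(
            {"cohort_log_hrs": truth.cohort_log_hrs, "censor_rate": truth.censor_rate,
             "mvd_true_cutoffs": truth.mvd_true_cutoffs},
            outdir / "truth.json",
        )
        events = cohort.groupby("stage")["dfs_event"].agg(["sum", "count"])
        print(f"{name}: {len(cohort)} patients; events by stage:")
        print(events.to_string())


if __name__ == "__main__":
    main()
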