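"""How often does the pipeline recover opposite stage-specific effects?

Repeats the full chain — simulate a 200+200 cohort with a harmful
high-MVD effect in stage II and a protective one in stage III, then
Youden-dichotomize per stage and fit the high-vs-low Cox model — over 50
seeds, and tabulates how often both effect directions are recovered.
Writes ``results/stage_effect_replication.csv``.
"""

from pathlib import Path

import pandas as pd

from mvdquant import CohortSpec, generate_cohort
from mvdquant.workflows import marker_survival_by_stage

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    rows = []
    for seed in range(50):
        spec = CohortSpec(n_stage2=200, n_stage3=200,
                          true_log_hrs={"mvd_high:II": 1.0, "mvd_high:III": -1.0},
                          censor_rate=0.3, seed=seed)
        cohort, _ = generate_cohort(spec)
        res = marker_survival_by_stage(cohort, marker="mvd_percent")
        f2, f3 = res["II"]["fit"], res["III"]["fit"]
        rows.append(
            {
                "seed": seed,
                "hr_stage2": None if f2 is None else f2.hr,
                "hr_stage3": None if f3 is None else f3.hr,
                "both_signs_recovered": int(
                    f2 is not None and f3 is not None and f2.hr > 1 and f3.hr < 1
                ),
            }
        )
    table = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "stage_effect_replication.csv", index=False)
    rate = 100 * table.both_signs_recovered.mean()
    print(f"both effect directions recovered in {rate:.0f}% of 50 seeds "
          f"(harmful high-MVD in stage II, protective in stage III)")


if __name__ == "__main__":
    main()
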