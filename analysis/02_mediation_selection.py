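#!/usr/bin/env python
"""Fit the two-mediator path models and select the purely-direct sub-scores.

For each group pair, every sub-score is regressed on diagnosis with age and
education as parallel mediators (1000 bootstrap resamples for the indirect
effects, per-test alpha 0.004). Sub-scores whose group difference is purely
direct — significant direct effect, no significant indirect effect — are the
candidates for the composite total scores. Writes results/mediation_*.csv.
"""

from pathlib import Path

from cogscore import read_cohort_csv
from cogscore.battery import default_battery
from cogscore.cohort import PAIRS
from cogscore.mediation import mediation_frame, mediation_table, select_subtasks

SEED = 11
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = read_cohort_csv(OUT / "cohort.csv")
    outcomes = [s.id for s in default_battery() if s.id in cohort.frame.columns]
    for pair in PAIRS:
        table = mediation_table(cohort, pair, outcomes, n_boot=1000, seed=SEED,
                                alpha=0.004)
        tag = "-".join(pair)
        path = OUT / f"mediation_{tag}.csv"
        mediation_frame(table).to_csv(path, index=False)
        sel = select_subtasks(table)
        print(f"{tag}: {len(sel.selected)} purely-direct sub-scores "
              f"-> {sel.selected or sel.warning}")
        print(f"  wrote {path}")


if __name__ == "__main__":
    main()
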