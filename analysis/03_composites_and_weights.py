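#!/usr/bin/env python
"""Normalize the selected sub-scores and compute the eight composite totals.

Selected sub-scores are oriented (higher = better), min–max normalized over
the pooled pair, and combined into the eight candidate total scores with
their σ-after-normalization and per-variable AUC weights. Writes
results/weights_*.csv and results/composites_*.csv.
"""

from pathlib import Path

from cogscore import read_cohort_csv
from cogscore.battery import default_battery
from cogscore.cohort import PAIRS
from cogscore.composite import compute_composites, normalize_selected, weight_frame
from cogscore.mediation import mediation_table, select_subtasks

SEED = 11
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = read_cohort_csv(OUT / "cohort.csv")
    outcomes = [s.id for s in default_battery() if s.id in cohort.frame.columns]
    for pair in PAIRS:
        tag = "-".join(pair)
        table = mediation_table(cohort, pair, outcomes, n_boot=1000, seed=SEED,
                                alpha=0.004)
        sel = select_subtasks(table)
        if not sel.selected:
            print(f"{tag}: {sel.warning}; no composites")
            continue
        norm = normalize_selected(cohort, pair, sel.selected)
        wf = weight_frame(norm)
        wf.to_csv(OUT / f"weights_{tag}.csv", index=False)
        composites = compute_composites(norm)
        composites.frame.to_csv(OUT / f"composites_{tag}.csv", index=False)
        print(f"{tag}: weights (σ after min–max, AUC) per selected sub-score")
        print(wf.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
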