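#!/usr/bin/env python
"""Classify each pair with the eight composite totals and pick the best.

Runs the full per-pair pipeline (mediation → selection → composites → ROC)
and writes the bundled report: cutoff, AUC, sensitivity, specificity, 95% CI,
p and quality band per formula, with the Youden-best row flagged. Writes
results/report_*.json, results/classification_*.csv and companions.
"""

from pathlib import Path

from cogscore import RunConfig, read_cohort_csv, run_all, write_report
from cogscore.pipeline import classification_frame

SEED = 11
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = read_cohort_csv(OUT / "cohort.csv")
    reports, errors = run_all(cohort, RunConfig(seed=SEED))
    for pair, rep in reports.items():
        tag = "-".join(pair)
        write_report(rep, OUT)
        if not rep.best_formula:
            print(f"{tag}: {rep.selection.warning}")
            continue
        best = rep.roc[rep.best_formula]
        print(f"{tag}: best formula {rep.best_formula} "
              f"(cutoff {best.cutoff:.4f}, AUC {best.auc:.3f}, "
              f"sens {best.sensitivity:.1%}, spec {best.specificity:.1%}, "
              f"{best.quality.value})")
        print(classification_frame(rep)
              .drop(columns=["alias"]).round(4).to_string(index=False))
    for pair, msg in errors.items():
        print(f"{'-'.join(pair)} failed: {msg}")


if __name__ == "__main__":
    main()
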