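"""End-to-end pairwise discrimination analysis.

For each diagnostic group pair the stages run in a fixed order: mediation
table → purely-direct subtask selection → orientation + min–max
normalization with σ/AUC weights → the eight composite totals → one ROC row
(AUC, CI, p, Youden cutoff, sensitivity, specificity, quality band) per
formula → best-formula choice. Everything is deterministic given the run
seed; the weights used by the composites are exactly the ones reported.

The best formula maximizes the Youden index, ties broken by higher AUC and
then by the canonical formula order (plain sum first) — the full eight-row
table is always emitted so users can apply their own criterion.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .battery import default_battery
from .cohort import PAIRS, Cohort, CohortError, worse_group
from .composite import (
    FORMULA_ALIASES,
    FORMULA_NAMES,
    CompositeScoreTable,
    DegenerateColumnError,
    NormalizedMatrix,
    compute_composites,
    normalize_selected,
    weight_frame,
)
from .mediation import (
    MediationTable,
    SelectionResult,
    mediation_frame,
    mediation_table,
    select_subtasks,
)
from .roc import Direction, ROCResult, analyze_score

log = logging.getLogger("cogscore.pipeline")


@dataclass(frozen=True)
class RunConfig:
    """Per-run analysis settings; together with the cohort these fix every
    number in the report."""

    seed: int = 0
    n_boot_mediation: int = 1000
    n_boot_auc: int = 2000
    #: per-test level for both the direct and indirect screens; the
    #: conventional Bonferroni value for a 13-outcome family
    alpha: float = 0.004
    outcomes: tuple[str, ...] | None = None
    stratified_bootstrap: bool = False
    sd_ddof: int = 1


@dataclass
class PairwiseReport:
    pair: tuple[str, str]
    positive_group: str
    mediation: MediationTable
    selection: SelectionResult
    normalized: NormalizedMatrix | None
    composites: CompositeScoreTable | None
    roc: dict[str, ROCResult]
    best_formula: str | None
    best_trace: list[dict]
    config: RunConfig
    warnings: list[str] = field(default_factory=list)


def pick_best_formula(rows: dict[str, ROCResult]) -> tuple[str, list[dict]]:
    """Maximize Youden J; ties broken by AUC, then canonical formula order."""
    if set(rows) != set(FORMULA_NAMES):
        raise ValueError("expected exactly the eight formula rows")
    best: str | None = None
    trace: list[dict] = []
    for name in FORMULA_NAMES:
        row = rows[name]
        key = (round(row.youden_j, 12), round(row.auc, 12))
        if best is None:
            best, best_key = name, key
            outcome = "initial"
        elif key > best_key:
            best, best_key = name, key
            outcome = "new_best"
        else:
            outcome = "kept"
        trace.append(
            {"formula": name, "youden_j": row.youden_j, "auc": row.auc,
             "decision": outcome}
        )
    assert best is not None
    return best, trace


def run_pair(cohort: Cohort, pair: tuple[str, str], config: RunConfig) -> PairwiseReport:
    """Run the full analysis for one group pair."""
    for g in pair:
        if g not in set(cohort.frame["group"]):
            raise CohortError(f"group {g} absent from cohort")
    warnings: list[str] = []
    outcomes = (
        list(config.outcomes)
        if config.outcomes is not None
        else [s.id for s in default_battery() if s.id in cohort.frame.columns]
    )
    ss = np.random.SeedSequence(config.seed)
    seed_mediation, seed_roc = (
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2)
    )

    log.info("pair=%s stage=mediation outcomes=%d", "-".join(pair), len(outcomes))
    table = mediation_table(
        cohort, pair, outcomes,
        n_boot=config.n_boot_mediation, seed=seed_mediation,
        alpha=config.alpha, stratified=config.stratified_bootstrap,
    )
    for outcome, msg in table.errors.items():
        warnings.append(f"mediation[{outcome}]: {msg}")
    selection = select_subtasks(table)
    positive = worse_group(pair)
    if selection.warning:
        warnings.append(selection.warning)
        log.warning("pair=%s stage=selection %s", "-".join(pair), selection.warning)
        return PairwiseReport(
            pair=pair, positive_group=positive, mediation=table,
            selection=selection, normalized=None, composites=None,
            roc={}, best_formula=None, best_trace=[], config=config,
            warnings=warnings,
        )

    log.info("pair=%s stage=normalize selected=%s", "-".join(pair), selection.selected)
    norm = normalize_selected(
        cohort, pair, selection.selected, sd_ddof=config.sd_ddof
    )
    for sid in norm.dropped:
        warnings.append(f"normalize[{sid}]: degenerate column dropped")
    if cohort.clipped:
        warnings.append(f"generation clipped values: {cohort.clipped}")
    composites = compute_composites(norm)

    labels = (composites.frame["group"] == positive).astype(int).to_numpy()
    roc_rows: dict[str, ROCResult] = {}
    roc_seeds = np.random.SeedSequence(seed_roc).spawn(len(FORMULA_NAMES))
    for name, child in zip(FORMULA_NAMES, roc_seeds):
        roc_rows[name] = analyze_score(
            composites.frame[name].to_numpy(float),
            labels,
            score_name=name,
            pair=pair,
            direction=Direction.POSITIVE_LOW,  # composites are higher-better
            n_boot=config.n_boot_auc,
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
    best, trace = pick_best_formula(roc_rows)
    log.info("pair=%s stage=best formula=%s J=%.3f", "-".join(pair), best,
             roc_rows[best].youden_j)
    return PairwiseReport(
        pair=pair, positive_group=positive, mediation=table,
        selection=selection, normalized=norm, composites=composites,
        roc=roc_rows, best_formula=best, best_trace=trace, config=config,
        warnings=warnings,
    )


def run_all(cohort: Cohort, config: RunConfig):
    """Reports for (SCD,HC), (SCD,MCI), (HC,MCI) with independent per-pair
    weights and cutoffs; per-pair errors are collected, not raised."""
    reports: dict[tuple[str, str], PairwiseReport] = {}
    errors: dict[tuple[str, str], str] = {}
    for pair in PAIRS:
        try:
            reports[pair] = run_pair(cohort, pair, config)
        except CohortError as exc:
            errors[pair] = str(exc)
            log.warning("pair=%s skipped: %s", "-".join(pair), exc)
    return reports, errors


def classification_frame(report: PairwiseReport) -> pd.DataFrame:
    """Eight-formula classification table: cutoff, AUC, sensitivity,
    specificity, CI, p, quality, best-row flag."""
    rows = []
    for name in FORMULA_NAMES:
        if name not in report.roc:
            continue
        r = report.roc[name]
        rows.append(
            {
                "formula": name,
                "alias": FORMULA_ALIASES[name],
                "cutoff": r.cutoff,
                "auc": r.auc,
                "sensitivity": r.sensitivity,
                "specificity": r.specificity,
                "youden_j": r.youden_j,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p_value": r.p_value,
                "quality": r.quality.value,
                "best": name == report.best_formula,
            }
        )
    return pd.DataFrame(rows)


def report_to_dict(report: PairwiseReport) -> dict:
    """JSON-serializable report bundle; metadata suffices to re-run
    bit-identically."""
    d = {
        "pair": list(report.pair),
        "positive_group": report.positive_group,
        "metadata": {
            "seed": report.config.seed,
            "n_boot_mediation": report.config.n_boot_mediation,
            "n_boot_auc": report.config.n_boot_auc,
            "alpha": report.config.alpha,
            "stratified_bootstrap": report.config.stratified_bootstrap,
            "sd_ddof": report.config.sd_ddof,
            "software_version": __version__,
        },
        "selection": {
            "selected": report.selection.selected,
            "warning": report.selection.warning,
            "rule": "direct effect significant and neither indirect "
                    "effect significant, at the same per-test alpha",
        },
        "mediation": mediation_frame(report.mediation).to_dict(orient="records"),
        "warnings": report.warnings,
        "best_formula": report.best_formula,
        "best_trace": report.best_trace,
    }
    if report.normalized is not None:
        d["weights"] = weight_frame(report.normalized).to_dict(orient="records")
        d["normalization"] = {
            "min_used": report.normalized.min_used,
            "max_used": report.normalized.max_used,
            "dropped": report.normalized.dropped,
        }
    if report.roc:
        d["classification"] = classification_frame(report).to_dict(orient="records")
    return d


def write_report(report: PairwiseReport, out_dir) -> list[Path]:
    """Write the per-pair bundle: JSON report plus flat CSV tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = "-".join(report.pair)
    written = []

    path = out / f"report_{tag}.json"
    with open(path, "w") as fh:
        json.dump(report_to_dict(report), fh, indent=2, sort_keys=True)
        fh.write("\n")
    written.append(path)

    path = out / f"mediation_{tag}.csv"
    mediation_frame(report.mediation).to_csv(path, index=False)
    written.append(path)

    if report.normalized is not None:
        path = out / f"weights_{tag}.csv"
        weight_frame(report.normalized).to_csv(path, index=False)
        written.append(path)
    if report.composites is not None:
        path = out / f"composites_{tag}.csv"
        report.composites.frame.to_csv(path, index=False)
        written.append(path)
    if report.roc:
        path = out / f"classification_{tag}.csv"
        classification_frame(report).to_csv(path, index=False)
        written.append(path)
    return written
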