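"""Min–max normalization and the eight composite total-score formulas.

Given the selected sub-scores X_1..X_N for a group pair, each is first
oriented (higher = cognitively better), then min–max normalized onto [0,1]
over the pooled two-group subsample:

    X̄_i = (X_i - min X_i) / (max X_i - min X_i)

Eight candidate totals combine the normalized scores. With AUC_i the
discrimination of X̄_i for the pair and σ_i its standard deviation after
normalization:

    S_Σ        = Σ X̄_i                    (plain sum)
    S_Σ2       = Σ X̄_i²                   (squares widen the group gap)
    S_Σ2AUC    = Σ X̄_i² · AUC_i           (AUC-weighted squares)
    S_Σ2AUC2   = Σ X̄_i² · AUC_i²          (AUC²-weighted squares)
    S_Σσ       = Σ X̄_i / σ_i              (spread-scaled sum)
    S_Σ2σ      = Σ X̄_i² / σ_i
    S_Σ2AUCσ   = Σ (X̄_i² / σ_i) · AUC_i
    S_Σ2AUC2σ  = Σ (X̄_i² / σ_i) · AUC_i²

Dividing by σ boosts variables whose values cluster near the range ends
(bimodal, hence nearly separable); AUC weights boost the individually most
discriminative variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .battery import SubtaskSpec, battery_index, orient_score
from .cohort import Cohort, worse_group
from .roc import Direction, auc_mann_whitney

#: canonical column order of the eight formulas (plain sum first)
FORMULA_NAMES = (
    "S_sum",
    "S_sumsq",
    "S_sumsq_auc",
    "S_sumsq_auc2",
    "S_sum_sd",
    "S_sumsq_sd",
    "S_sumsq_auc_sd",
    "S_sumsq_auc2_sd",
)

#: field-notation aliases, in the same order
FORMULA_ALIASES = {
    "S_sum": "SΣ",
    "S_sumsq": "SΣ2",
    "S_sumsq_auc": "SΣ2AUC",
    "S_sumsq_auc2": "SΣ2AUC2",
    "S_sum_sd": "SΣσ",
    "S_sumsq_sd": "SΣ2σ",
    "S_sumsq_auc_sd": "SΣ2AUCσ",
    "S_sumsq_auc2_sd": "SΣ2AUC2σ",
}


class DegenerateColumnError(ValueError):
    """A column with zero range cannot be min–max normalized."""

    def __init__(self, subtask: str):
        self.subtask = subtask
        super().__init__(f"subtask {subtask!r} is constant (max == min)")


def minmax_normalize(values) -> tuple[np.ndarray, float, float]:
    """(x - min) / (max - min) elementwise, plus the extremes used.

    Affine-invariant: normalizing a*x + b (a > 0) gives the same output.
    Raises :class:`DegenerateColumnError` on a constant vector.
    """
    x = np.asarray(values, float)
    if x.size < 2:
        raise ValueError("need at least 2 values to normalize")
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        raise DegenerateColumnError("<anonymous>")
    return (x - lo) / (hi - lo), lo, hi


@dataclass
class NormalizedMatrix:
    """Oriented, normalized selected sub-scores for one group pair, with the
    per-subtask weights (σ after normalization, pairwise AUC) frozen in."""

    pair: tuple[str, str]
    ids: list[str]
    groups: list[str]
    values: pd.DataFrame  # rows: participants, columns: selected subtasks
    min_used: dict[str, float]
    max_used: dict[str, float]
    sd_norm: dict[str, float]
    auc: dict[str, float]
    auc_polarity: dict[str, str]  # which class scored higher pre-reflection
    dropped: list[str] = field(default_factory=list)

    @property
    def subtasks(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class CompositeScoreTable:
    pair: tuple[str, str]
    frame: pd.DataFrame  # columns: id, group, then the eight formula scores
    sd_norm: dict[str, float]
    auc: dict[str, float]


def normalize_selected(
    cohort: Cohort,
    pair: tuple[str, str],
    selected: list[str],
    battery: dict[str, SubtaskSpec] | None = None,
    sd_ddof: int = 1,
) -> NormalizedMatrix:
    """Orient, min–max normalize and weight the selected sub-scores.

    All statistics (min/max, σ, per-variable AUC) are computed on the pooled
    two-group subsample of ``pair`` — weights and cutoffs are pair-specific.
    Degenerate (constant) columns are dropped with a record rather than
    failing the run. Complete cases across the selected set are used.
    """
    if not selected:
        raise ValueError("selected subtask list is empty")
    specs = battery_index() if battery is None else battery
    df = cohort.subset_pair(pair)
    df = df.dropna(subset=list(selected)).reset_index(drop=True)
    worse = worse_group(pair)
    labels = (df["group"] == worse).astype(int).to_numpy()

    cols: dict[str, np.ndarray] = {}
    min_used: dict[str, float] = {}
    max_used: dict[str, float] = {}
    sd_norm: dict[str, float] = {}
    auc: dict[str, float] = {}
    polarity: dict[str, str] = {}
    dropped: list[str] = []
    for sid in selected:
        spec = specs[sid]
        oriented = np.array([orient_score(spec, v) for v in df[sid].to_numpy(float)])
        try:
            normed, lo, hi = minmax_normalize(oriented)
        except DegenerateColumnError:
            dropped.append(sid)
            continue
        cols[sid] = normed
        min_used[sid] = lo
        max_used[sid] = hi
        sd_norm[sid] = float(np.std(normed, ddof=sd_ddof))
        # oriented scores are higher-is-better, so the impaired group sits low;
        # report the >0.5 polarity-folded AUC with the raw polarity retained
        raw_auc, _ = auc_mann_whitney(normed, labels, Direction.POSITIVE_LOW)
        if raw_auc >= 0.5:
            auc[sid] = float(raw_auc)
            polarity[sid] = "impaired_low"
        else:
            auc[sid] = float(1.0 - raw_auc)
            polarity[sid] = "impaired_high"
    if not cols:
        raise DegenerateColumnError(",".join(selected))
    values = pd.DataFrame(cols, index=df["id"])
    return NormalizedMatrix(
        pair=pair,
        ids=list(df["id"]),
        groups=list(df["group"]),
        values=values.reset_index(drop=True),
        min_used=min_used,
        max_used=max_used,
        sd_norm=sd_norm,
        auc=auc,
        auc_polarity=polarity,
        dropped=dropped,
    )


def compute_composites(norm: NormalizedMatrix) -> CompositeScoreTable:
    """Evaluate the eight total-score formulas per participant."""
    subtasks = norm.subtasks
    missing = [s for s in subtasks if s not in norm.sd_norm or s not in norm.auc]
    if missing:
        raise ValueError(f"weights missing for subtasks {missing}")
    x = norm.values[subtasks].to_numpy(float)
    sd = np.array([norm.sd_norm[s] for s in subtasks])
    if np.any(sd <= 0):
        raise ValueError("σ after normalization must be > 0 for every column")
    auc = np.array([norm.auc[s] for s in subtasks])
    x2 = x**2
    scores = {
        "S_sum": x.sum(axis=1),
        "S_sumsq": x2.sum(axis=1),
        "S_sumsq_auc": (x2 * auc).sum(axis=1),
        "S_sumsq_auc2": (x2 * auc**2).sum(axis=1),
        "S_sum_sd": (x / sd).sum(axis=1),
        "S_sumsq_sd": (x2 / sd).sum(axis=1),
        "S_sumsq_auc_sd": (x2 / sd * auc).sum(axis=1),
        "S_sumsq_auc2_sd": (x2 / sd * auc**2).sum(axis=1),
    }
    frame = pd.DataFrame({"id": norm.ids, "group": norm.groups})
    for name in FORMULA_NAMES:
        frame[name] = scores[name]
    return CompositeScoreTable(
        pair=norm.pair, frame=frame, sd_norm=dict(norm.sd_norm), auc=dict(norm.auc)
    )


def weight_frame(norm: NormalizedMatrix) -> pd.DataFrame:
    """Per-subtask weight table: σ after min–max normalization and AUC."""
    return pd.DataFrame(
        {
            "subtask": norm.subtasks,
            "sd_after_minmax": [norm.sd_norm[s] for s in norm.subtasks],
            "auc": [norm.auc[s] for s in norm.subtasks],
            "auc_polarity": [norm.auc_polarity[s] for s in norm.subtasks],
        }
    )
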