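"""Empirical ROC analysis: AUC, Youden-optimal cutoff, quality banding.

The AUC is estimated by the normalized Mann–Whitney statistic — the fraction
of impaired/control pairs in which the impaired participant scores on the
impaired side, ties counted one half — with the Hanley–McNeil standard error.
Cutoffs maximize the Youden index J = sensitivity + specificity - 1 over all
achievable thresholds (midpoints between adjacent distinct scores plus
sentinels at both ends); a participant is called impaired when their score
lies on the impaired side of the cutoff, inclusive.

``direction`` states which side is impaired: ``positive_high`` for raw
error-like scores (impaired participants score high), ``positive_low`` for
oriented/normalized composites (impaired participants score low).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.stats import mannwhitneyu, norm, rankdata


class ROCError(ValueError):
    """Domain error for ROC computations."""


class Direction(str, Enum):
    POSITIVE_LOW = "positive_low"
    POSITIVE_HIGH = "positive_high"


class Quality(str, Enum):
    PERFECT = "perfect"
    EXCELLENT = "excellent"
    GOOD = "good"
    FAIR = "fair"
    POOR = "poor"
    NON_DISCRIMINATIVE = "non_discriminative"


@dataclass(frozen=True)
class ROCResult:
    score_name: str
    pair: tuple[str, str]
    n_pos: int
    n_neg: int
    auc: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    cutoff: float
    sensitivity: float
    specificity: float
    direction: Direction
    quality: Quality

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity - 1.0


def _check_classes(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ROCError("scores and labels must have equal length")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ROCError("both classes must be present")
    return pos, neg


def auc_mann_whitney(
    scores, labels, direction: Direction | str = Direction.POSITIVE_HIGH
) -> tuple[float, float]:
    """Tie-corrected empirical AUC and its Hanley–McNeil standard error.

    Labels are 1 for the impaired (positive) class. The AUC is the
    probability that a random positive lies on the impaired side of a random
    negative, ties counted 1/2; computed from rank sums, which equals the
    normalized Mann–Whitney U.
    """
    pos, neg = _check_classes(scores, labels)
    oriented = np.concatenate([pos, neg])
    if Direction(direction) is Direction.POSITIVE_LOW:
        oriented = -oriented
    n_pos, n_neg = len(pos), len(neg)
    ranks = rankdata(oriented)
    u = ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2.0
    auc = u / (n_pos * n_neg)
    # Hanley & McNeil (1982) variance approximation
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_pos - 1.0) * (q1 - auc**2)
        + (n_neg - 1.0) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    return float(auc), float(np.sqrt(max(var, 0.0)))


def auc_p_value(scores, labels, direction: Direction | str = Direction.POSITIVE_HIGH) -> float:
    """Two-sided p-value versus chance (AUC = 0.5), normal approximation to
    Mann–Whitney with tie correction."""
    pos, neg = _check_classes(scores, labels)
    if Direction(direction) is Direction.POSITIVE_LOW:
        pos, neg = -pos, -neg
    if np.ptp(np.concatenate([pos, neg])) == 0.0:
        return 1.0
    return float(mannwhitneyu(pos, neg, alternative="two-sided",
                              method="asymptotic").pvalue)


def roc_points(scores, labels, direction: Direction | str = Direction.POSITIVE_HIGH):
    """(threshold, fpr, tpr) triples over all achievable thresholds,
    suitable for plotting or trapezoidal integration."""
    pos, neg = _check_classes(scores, labels)
    thresholds = _thresholds(np.concatenate([pos, neg]))
    out = []
    for t in thresholds:
        sens, spec = _confusion(pos, neg, t, Direction(direction))
        out.append((t, 1.0 - spec, sens))
    return out


def _thresholds(values: np.ndarray) -> np.ndarray:
    # midpoints between adjacent distinct scores span every achievable
    # classification; +/-inf sentinels cover the all/none calls
    distinct = np.unique(values)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    return np.concatenate([[-np.inf], mids, [np.inf]])


def _confusion(
    pos: np.ndarray, neg: np.ndarray, t: float, direction: Direction
) -> tuple[float, float]:
    if direction is Direction.POSITIVE_HIGH:
        tp = np.sum(pos >= t)
        tn = np.sum(neg < t)
    else:
        tp = np.sum(pos <= t)
        tn = np.sum(neg > t)
    return float(tp / len(pos)), float(tn / len(neg))


def youden_cutoff(
    scores, labels, direction: Direction | str = Direction.POSITIVE_HIGH
) -> tuple[float, float, float, float]:
    """Cutoff maximizing J = sensitivity + specificity - 1.

    Ties in J are broken in favour of higher sensitivity (screening
    preference), then the lower cutoff. Returns (cutoff, sensitivity,
    specificity, J); cutoffs are midpoints between adjacent observed values,
    with +/-inf sentinels for the degenerate all/none calls.
    """
    direction = Direction(direction)
    pos, neg = _check_classes(scores, labels)
    best: tuple[float, float, float, float] | None = None
    for t in _thresholds(np.concatenate([pos, neg])):
        sens, spec = _confusion(pos, neg, t, direction)
        j = sens + spec - 1.0
        cand = (j, sens, -t)
        if best is None or cand > (best[3], best[1], -best[0]):
            best = (float(t), sens, spec, j)
    assert best is not None
    return best


def bootstrap_auc_ci(
    scores,
    labels,
    n_boot: int = 2000,
    seed: int = 0,
    level: float = 0.95,
    direction: Direction | str = Direction.POSITIVE_HIGH,
) -> tuple[float, float]:
    """Percentile bootstrap interval for the AUC, class-stratified resamples.

    Stratification guarantees both classes appear in every resample;
    deterministic given seed.
    """
    if n_boot < 100:
        raise ROCError("n_boot must be >= 100")
    pos, neg = _check_classes(scores, labels)
    if Direction(direction) is Direction.POSITIVE_LOW:
        pos, neg = -pos, -neg
    rng = np.random.default_rng(seed)
    n_pos, n_neg = len(pos), len(neg)
    aucs = np.empty(n_boot)
    for i in range(n_boot):
        p = pos[rng.integers(0, n_pos, n_pos)]
        n = neg[rng.integers(0, n_neg, n_neg)]
        ranks = rankdata(np.concatenate([p, n]))
        u = ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2.0
        aucs[i] = u / (n_pos * n_neg)
    tail = (1.0 - level) / 2.0 * 100.0
    lo, hi = np.percentile(aucs, [tail, 100.0 - tail])
    return float(lo), float(hi)


def quality_label(auc: float) -> Quality:
    """Discrimination-quality band of an AUC, applied after rounding to two
    decimals: 1.0 perfect, 0.90-0.99 excellent, 0.80-0.89 good, 0.70-0.79
    fair, 0.51-0.69 poor; below 0.51 the score is non-discriminative."""
    if not 0.0 <= auc <= 1.0:
        raise ROCError(f"AUC must lie in [0, 1], got {auc}")
    r = round(auc, 2)
    if r >= 1.0:
        return Quality.PERFECT
    if r >= 0.90:
        return Quality.EXCELLENT
    if r >= 0.80:
        return Quality.GOOD
    if r >= 0.70:
        return Quality.FAIR
    if r >= 0.51:
        return Quality.POOR
    return Quality.NON_DISCRIMINATIVE


def analyze_score(
    scores,
    labels,
    score_name: str,
    pair: tuple[str, str],
    direction: Direction | str = Direction.POSITIVE_HIGH,
    n_boot: int = 2000,
    seed: int = 0,
    level: float = 0.95,
) -> ROCResult:
    """Full ROC summary of one score for one group pair."""
    direction = Direction(direction)
    pos, neg = _check_classes(scores, labels)
    auc, se = auc_mann_whitney(scores, labels, direction)
    ci_low, ci_high = bootstrap_auc_ci(
        scores, labels, n_boot=n_boot, seed=seed, level=level, direction=direction
    )
    p = auc_p_value(scores, labels, direction)
    cutoff, sens, spec, _ = youden_cutoff(scores, labels, direction)
    return ROCResult(
        score_name=score_name,
        pair=pair,
        n_pos=len(pos),
        n_neg=len(neg),
        auc=auc,
        se=se,
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=p,
        cutoff=cutoff,
        sensitivity=sens,
        specificity=spec,
        direction=direction,
        quality=quality_label(auc),
    )
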