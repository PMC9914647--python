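"""ROC estimator, Youden cutoff and quality bands against independent oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_auc_score

from cogscore.roc import (
    Direction,
    Quality,
    ROCError,
    analyze_score,
    auc_mann_whitney,
    auc_p_value,
    bootstrap_auc_ci,
    quality_label,
    roc_points,
    youden_cutoff,
)


def pair_counting_auc(scores, labels):
    """Exhaustive oracle: fraction of (positive, negative) pairs where the
    positive scores higher, ties counted one half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def brute_force_youden(scores, labels, direction):
    """Oracle: scan every distinct score value and midpoint as threshold."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos, neg = scores[labels == 1], scores[labels == 0]
    distinct = np.unique(scores)
    cands = np.concatenate(
        [[-np.inf], distinct, (distinct[:-1] + distinct[1:]) / 2, [np.inf]]
    )
    best_j = -np.inf
    for t in cands:
        if direction == Direction.POSITIVE_HIGH:
            sens = np.mean(pos >= t)
            spec = np.mean(neg < t)
        else:
            sens = np.mean(pos <= t)
            spec = np.mean(neg > t)
        best_j = max(best_j, sens + spec - 1.0)
    return best_j


def random_instance(rng, max_n=12):
    n = int(rng.integers(4, max_n + 1))
    labels = np.zeros(n, int)
    k = int(rng.integers(1, n))
    labels[:k] = 1
    rng.shuffle(labels)
    scores = rng.integers(0, 6, n).astype(float)  # heavy ties on purpose
    if len(np.unique(labels)) < 2:
        return random_instance(rng, max_n)
    return scores, labels


class TestAUC:
    def test_perfect_separation(self):
        auc, se = auc_mann_whitney([1, 2, 3, 4], [0, 0, 1, 1])
        assert auc == 1.0
        assert se >= 0.0

    def test_tied_pairs_counted_half(self):
        # pos {2,2} vs neg {1,2}: two wins and two ties over the four pairs,
        # (1 + 1 + 0.5 + 0.5)/4 = 0.75 by exhaustive pair counting
        scores, labels = [1, 2, 2, 2], [0, 0, 1, 1]
        auc, _ = auc_mann_whitney(scores, labels)
        assert auc == pytest.approx(0.75)
        assert auc == pytest.approx(pair_counting_auc(scores, labels))

    def test_chance_for_identical_distributions(self):
        auc, _ = auc_mann_whitney([3, 3, 3, 3], [0, 1, 0, 1])
        assert auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ROCError):
            auc_mann_whitney([1, 2], [1, 1])

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_pair_counting_and_sklearn(self, seed):
        rng = np.random.default_rng(seed)
        scores, labels = random_instance(rng)
        auc, _ = auc_mann_whitney(scores, labels)
        assert auc == pytest.approx(pair_counting_auc(scores, labels), abs=1e-12)
        assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_trapezoidal_area(self, seed):
        rng = np.random.default_rng(100 + seed)
        scores, labels = random_instance(rng)
        auc, _ = auc_mann_whitney(scores, labels)
        pts = sorted((fpr, tpr) for _, fpr, tpr in
                     roc_points(scores, labels, Direction.POSITIVE_HIGH))
        fpr, tpr = zip(*pts)
        assert auc == pytest.approx(np.trapezoid(tpr, fpr), abs=1e-12)

    @given(seed=st.integers(0, 1000), shift=st.floats(-5, 5))
    @settings(derandomize=True, max_examples=40)
    def test_invariant_under_monotone_transform(self, seed, shift):
        rng = np.random.default_rng(seed)
        scores, labels = random_instance(rng)
        auc0, _ = auc_mann_whitney(scores, labels)
        auc1, _ = auc_mann_whitney(np.exp(scores / 3.0) + shift, labels)
        assert auc0 == pytest.approx(auc1, abs=1e-12)

    def test_complement_symmetry(self):
        rng = np.random.default_rng(7)
        scores, labels = random_instance(rng)
        hi, _ = auc_mann_whitney(scores, labels, Direction.POSITIVE_HIGH)
        lo, _ = auc_mann_whitney(scores, labels, Direction.POSITIVE_LOW)
        assert hi + lo == pytest.approx(1.0)


class TestYouden:
    def test_perfect_separation_j_is_one(self):
        cut, sens, spec, j = youden_cutoff([1, 2, 3, 10], [0, 0, 1, 1])
        assert (sens, spec, j) == (1.0, 1.0, 1.0)
        assert cut == pytest.approx(2.5)  # midpoint between the classes

    def test_degenerate_overlap_has_zero_j(self):
        _, _, _, j = youden_cutoff([5.0, 5.0], [0, 1])
        assert j == pytest.approx(0.0)

    def test_j_identity(self):
        rng = np.random.default_rng(3)
        scores, labels = random_instance(rng)
        _, sens, spec, j = youden_cutoff(scores, labels)
        assert j == pytest.approx(sens + spec - 1.0)

    @pytest.mark.parametrize("direction",
                             [Direction.POSITIVE_HIGH, Direction.POSITIVE_LOW])
    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_scan(self, seed, direction):
        rng = np.random.default_rng(200 + seed)
        scores, labels = random_instance(rng)
        _, _, _, j = youden_cutoff(scores, labels, direction)
        assert j == pytest.approx(
            brute_force_youden(scores, labels, direction), abs=1e-12
        )

    def test_tie_break_prefers_sensitivity(self):
        # thresholds 1.5 (sens 1, spec .5) and 2.5 (sens .5, spec 1) tie at J=.5
        cut, sens, spec, j = youden_cutoff([1, 2, 2, 3], [0, 1, 0, 1])
        assert j == pytest.approx(0.5)
        assert sens == 1.0

    def test_max_j_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(11)
        scores, labels = random_instance(rng)
        _, _, _, j0 = youden_cutoff(scores, labels)
        _, _, _, j1 = youden_cutoff(np.exp(scores), labels)
        assert j0 == pytest.approx(j1)


class TestBootstrapCI:
    def test_perfect_separation_degenerate_interval(self):
        lo, hi = bootstrap_auc_ci([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1],
                                  n_boot=200, seed=0)
        assert (lo, hi) == (1.0, 1.0)

    def test_same_seed_identical_interval(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=40)
        labels = np.repeat([0, 1], 20)
        ci1 = bootstrap_auc_ci(scores, labels, n_boot=300, seed=42)
        ci2 = bootstrap_auc_ci(scores, labels, n_boot=300, seed=42)
        assert ci1 == ci2

    def test_null_interval_straddles_chance(self):
        rng = np.random.default_rng(8)
        hits = 0
        for rep in range(40):
            scores = rng.normal(size=100)
            labels = np.repeat([0, 1], 50)
            lo, hi = bootstrap_auc_ci(scores, labels, n_boot=300, seed=rep)
            hits += lo <= 0.5 <= hi
        assert hits >= 36  # >= 90% coverage of the chance line

    def test_small_n_boot_rejected(self):
        with pytest.raises(ROCError):
            bootstrap_auc_ci([1, 2], [0, 1], n_boot=50, seed=0)


class TestQuality:
    @pytest.mark.parametrize(
        "auc, expected",
        [
            (1.0, Quality.PERFECT),
            (0.996, Quality.PERFECT),     # rounds to 1.0
            (0.994, Quality.EXCELLENT),   # rounds to 0.99
            (0.976, Quality.EXCELLENT),
            (0.90, Quality.EXCELLENT),
            (0.89, Quality.GOOD),
            (0.80, Quality.GOOD),
            (0.758, Quality.FAIR),
            (0.70, Quality.FAIR),
            (0.69, Quality.POOR),
            (0.51, Quality.POOR),
            (0.50, Quality.NON_DISCRIMINATIVE),
            (0.10, Quality.NON_DISCRIMINATIVE),
        ],
    )
    def test_bands(self, auc, expected):
        assert quality_label(auc) is expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ROCError):
            quality_label(1.2)


class TestAnalyzeScore:
    def test_full_summary_consistency(self):
        rng = np.random.default_rng(19)
        scores = np.concatenate([rng.normal(0, 1, 40), rng.normal(1.5, 1, 40)])
        labels = np.repeat([0, 1], 40)
        res = analyze_score(scores, labels, "demo", ("SCD", "HC"),
                            direction=Direction.POSITIVE_HIGH,
                            n_boot=300, seed=2)
        assert res.ci_low <= res.auc <= res.ci_high
        assert res.youden_j == pytest.approx(
            res.sensitivity + res.specificity - 1.0
        )
        assert res.quality is quality_label(res.auc)
        assert res.p_value < 0.01
        assert res.p_value == pytest.approx(
            auc_p_value(scores, labels), abs=1e-12
        )
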