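"""Min–max normalization and the eight composite total-score formulas."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cogscore import generate_cohort, pair_config
from cogscore.composite import (
    FORMULA_NAMES,
    DegenerateColumnError,
    NormalizedMatrix,
    compute_composites,
    minmax_normalize,
    normalize_selected,
    weight_frame,
)

PAIR = ("SCD", "HC")


class TestMinMax:
    def test_arithmetic_example(self):
        out, lo, hi = minmax_normalize([2, 4, 6])
        np.testing.assert_allclose(out, [0.0, 0.5, 1.0])
        assert (lo, hi) == (2.0, 6.0)

    def test_unit_pair_is_identity(self):
        out, _, _ = minmax_normalize([0, 1])
        np.testing.assert_allclose(out, [0.0, 1.0])

    def test_constant_vector_rejected(self):
        with pytest.raises(DegenerateColumnError):
            minmax_normalize([7, 7, 7])

    @given(
        values=st.lists(st.floats(-50, 50), min_size=3, max_size=12,
                        unique=True),
        a=st.floats(0.1, 10.0),
        b=st.floats(-20.0, 20.0),
    )
    @settings(derandomize=True, max_examples=60)
    def test_affine_invariance(self, values, a, b):
        x = np.array(values)
        base, _, _ = minmax_normalize(x)
        scaled, _, _ = minmax_normalize(a * x + b)
        np.testing.assert_allclose(base, scaled, atol=1e-9)

    def test_extremes_attained(self):
        out, _, _ = minmax_normalize(np.random.default_rng(0).normal(size=30))
        assert out.min() == 0.0 and out.max() == 1.0


def _matrix(values: dict, sd: dict, auc: dict, pair=PAIR) -> NormalizedMatrix:
    n = len(next(iter(values.values())))
    return NormalizedMatrix(
        pair=pair,
        ids=[f"P{i}" for i in range(n)],
        groups=["HC"] * (n // 2) + ["SCD"] * (n - n // 2),
        values=pd.DataFrame(values),
        min_used={k: 0.0 for k in values},
        max_used={k: 1.0 for k in values},
        sd_norm=sd,
        auc=auc,
        auc_polarity={k: "impaired_low" for k in values},
    )


class TestComposites:
    def test_exactly_eight_scores(self):
        m = _matrix({"A": [0.0, 1.0]}, {"A": 0.25}, {"A": 0.8})
        table = compute_composites(m)
        score_cols = [c for c in table.frame.columns if c.startswith("S_")]
        assert score_cols == list(FORMULA_NAMES)
        assert len(FORMULA_NAMES) == 8

    def test_single_subtask_hand_derived_values(self):
        """X̄=1, AUC=0.8, σ=0.25: each formula evaluated by hand."""
        m = _matrix({"A": [0.0, 1.0]}, {"A": 0.25}, {"A": 0.8})
        row = compute_composites(m).frame.iloc[1]
        assert row["S_sum"] == pytest.approx(1.0)
        assert row["S_sumsq"] == pytest.approx(1.0)
        assert row["S_sumsq_auc"] == pytest.approx(0.8)
        assert row["S_sumsq_auc2"] == pytest.approx(0.64)
        assert row["S_sum_sd"] == pytest.approx(4.0)
        assert row["S_sumsq_sd"] == pytest.approx(4.0)
        assert row["S_sumsq_auc_sd"] == pytest.approx(3.2)
        assert row["S_sumsq_auc2_sd"] == pytest.approx(2.56)

    def test_zero_input_gives_zero_scores(self):
        m = _matrix({"A": [0.0, 0.0, 1.0]}, {"A": 0.5}, {"A": 0.9})
        assert (compute_composites(m).frame.iloc[0][list(FORMULA_NAMES)] == 0).all()

    def test_squaring_reduces_midrange_values_as_documented(self):
        """0.5² = 0.25 (50% reduction) and 0.9² = 0.81 (10% reduction)."""
        m = _matrix({"A": [0.0, 0.5, 0.9, 1.0]}, {"A": 0.4}, {"A": 0.7})
        frame = compute_composites(m).frame
        assert frame.loc[1, "S_sumsq"] == pytest.approx(0.25)
        assert frame.loc[1, "S_sumsq"] / frame.loc[1, "S_sum"] == pytest.approx(0.5)
        assert frame.loc[2, "S_sumsq"] == pytest.approx(0.81)
        assert frame.loc[2, "S_sumsq"] / frame.loc[2, "S_sum"] == pytest.approx(0.9)

    @given(seed=st.integers(0, 500))
    @settings(derandomize=True, max_examples=40)
    def test_squared_sum_never_exceeds_plain_sum(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.random((8, 3))
        vals[0], vals[1] = 0.0, 1.0  # min-max property per column
        m = _matrix(
            {f"C{j}": vals[:, j] for j in range(3)},
            {f"C{j}": 0.2 + 0.1 * j for j in range(3)},
            {f"C{j}": 0.6 + 0.1 * j for j in range(3)},
        )
        frame = compute_composites(m).frame
        assert (frame["S_sumsq"] <= frame["S_sum"] + 1e-12).all()
        assert (frame[list(FORMULA_NAMES)] >= 0).all().all()

    def test_monotone_in_each_normalized_score(self):
        lo = _matrix({"A": [0.0, 0.3, 1.0]}, {"A": 0.3}, {"A": 0.8})
        hi = _matrix({"A": [0.0, 0.6, 1.0]}, {"A": 0.3}, {"A": 0.8})
        f_lo = compute_composites(lo).frame.iloc[1]
        f_hi = compute_composites(hi).frame.iloc[1]
        for name in FORMULA_NAMES:
            assert f_hi[name] >= f_lo[name]

    def test_missing_weights_rejected(self):
        m = _matrix({"A": [0.0, 1.0]}, {}, {"A": 0.8})
        with pytest.raises(ValueError):
            compute_composites(m)


class TestNormalizeSelected:
    @pytest.fixture()
    def cohort(self):
        cfg = pair_config(
            PAIR, n_per_group=40,
            subtasks={
                "ICT_RST_12": dict(c_direct=8.0, noise_sd=6.0),
                "EMTW_A": dict(intercept=4.0, c_direct=3.0, noise_sd=2.5),
                "VFT": dict(intercept=12.0, c_direct=-3.0, noise_sd=2.5),
            },
            seed=17,
        )
        return generate_cohort(cfg)

    def test_columns_attain_unit_range(self, cohort):
        norm = normalize_selected(cohort, PAIR, ["ICT_RST_12", "EMTW_A", "VFT"])
        for col in norm.subtasks:
            assert norm.values[col].min() == 0.0
            assert norm.values[col].max() == 1.0
            assert norm.sd_norm[col] > 0
            assert 0.5 <= norm.auc[col] <= 1.0

    def test_orientation_precedes_normalization(self, cohort):
        """For a reflected bounded error count, min–max of the oriented score
        equals 1 - min–max of the raw score."""
        norm = normalize_selected(cohort, PAIR, ["EMTW_A"])
        raw = cohort.subset_pair(PAIR)["EMTW_A"].to_numpy(float)
        raw_norm, _, _ = minmax_normalize(raw)
        np.testing.assert_allclose(
            norm.values["EMTW_A"].to_numpy(), 1.0 - raw_norm, atol=1e-12
        )

    def test_impaired_group_scores_low_after_orientation(self, cohort):
        norm = normalize_selected(cohort, PAIR, ["ICT_RST_12", "VFT"])
        df = pd.DataFrame({"group": norm.groups})
        for col in norm.subtasks:
            df[col] = norm.values[col].to_numpy()
            assert (
                df.loc[df.group == "SCD", col].mean()
                < df.loc[df.group == "HC", col].mean()
            )

    def test_degenerate_column_dropped_with_record(self, cohort):
        frame = cohort.subset_pair(PAIR).copy()
        frame["EMTW_A"] = 3.0
        from cogscore.cohort import Cohort

        norm = normalize_selected(Cohort(frame=frame), PAIR,
                                  ["ICT_RST_12", "EMTW_A"])
        assert norm.dropped == ["EMTW_A"]
        assert norm.subtasks == ["ICT_RST_12"]

    def test_weight_table_layout(self, cohort):
        norm = normalize_selected(cohort, PAIR, ["ICT_RST_12", "EMTW_A"])
        wf = weight_frame(norm)
        assert list(wf.columns) == ["subtask", "sd_after_minmax", "auc",
                                    "auc_polarity"]
        assert len(wf) == 2
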