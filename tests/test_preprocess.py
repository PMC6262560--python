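import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from heatmod.data_io import CountMatrix
from heatmod.errors import ValidationError
from heatmod.preprocess import (
    NormalizedMatrix,
    compute_folds,
    filter_low_counts,
    log_cpm,
    quantile_normalize,
)


def make_cm(rows, samples=("s1", "s2"), conditions=None):
    if conditions is None:
        conditions = {"s1": "control", "s2": "treated"}
    df = pd.DataFrame(rows, columns=list(samples)).astype(np.int64)
    df.index = [f"g{i}" for i in range(len(df))]
    return CountMatrix(df, conditions)


class TestFilterLowCounts:
    def test_retains_genes_with_any_count_at_threshold(self):
        cm = make_cm([[0, 5], [10, 0], [9, 9]])
        out = filter_low_counts(cm, threshold=10)
        assert out.gene_ids == ["g1"]

    def test_threshold_zero_keeps_all(self):
        cm = make_cm([[0, 0], [1, 2]])
        assert filter_low_counts(cm, threshold=0).gene_ids == ["g0", "g1"]

    def test_idempotent(self):
        cm = make_cm([[0, 5], [10, 0], [12, 20]])
        once = filter_low_counts(cm, 10)
        twice = filter_low_counts(once, 10)
        assert once.gene_ids == twice.gene_ids

    def test_planted_low_fraction_recovered(self, small_truth, small_counts):
        out = filter_low_counts(small_counts, 10)
        expected = small_truth.n_genes - len(small_truth.planted_low_genes)
        assert len(out.gene_ids) == expected
        assert set(small_truth.planted_low_genes).isdisjoint(out.gene_ids)


class TestLogCpm:
    def test_closed_form_single_gene(self):
        cm = make_cm([[0, 0], [1, 1]])  # libsize 1 per sample
        nm = log_cpm(cm, prior=0.5)
        assert nm.values.iloc[0, 0] == pytest.approx(math.log2(0.5 / 2.0 * 1e6))

    def test_scale_invariance_for_large_counts(self):
        cm1 = make_cm([[1000, 900], [2000, 2100]])
        cm2 = make_cm([[2000, 1800], [4000, 4200]])
        a, b = log_cpm(cm1).values.to_numpy(), log_cpm(cm2).values.to_numpy()
        assert np.abs(a - b).max() < 1e-3

    def test_shape_preserved(self, small_counts):
        nm = log_cpm(small_counts)
        assert nm.values.shape == small_counts.counts.shape

    def test_zero_library_size_rejected(self):
        df = pd.DataFrame({"s1": [0], "s2": [1]}, index=["g0"])
        cm = CountMatrix(df, {"s1": "control", "s2": "treated"})
        with pytest.raises(ValidationError, match="s1"):
            log_cpm(cm)


class TestQuantileNormalize:
    def norm(self, cols):
        df = pd.DataFrame(cols)
        df.index = [f"g{i}" for i in range(len(df))]
        return quantile_normalize(NormalizedMatrix(df)).values

    def test_two_columns_forced_to_common_distribution(self):
        out = self.norm({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        assert list(out["a"]) == [2.5, 3.5, 4.5]
        assert list(out["b"]) == [2.5, 3.5, 4.5]

    def test_identical_columns_unchanged(self):
        out = self.norm({"a": [1.0, 5.0, 2.0], "b": [1.0, 5.0, 2.0]})
        assert list(out["a"]) == [1.0, 5.0, 2.0]

    def test_ties_get_mean_of_spanned_reference(self):
        out = self.norm({"a": [1.0, 1.0, 3.0], "b": [10.0, 20.0, 30.0]})
        # reference = [5.5, 10.5, 16.5]; the tie at ranks 1-2 averages to 8.0
        assert list(out["a"]) == [8.0, 8.0, 16.5]
        assert list(out["b"]) == [5.5, 10.5, 16.5]

    @settings(deadline=None, max_examples=25)
    @given(
        st.lists(
            st.lists(st.floats(-50, 50, allow_nan=False), min_size=4, max_size=4),
            min_size=2,
            max_size=4,
        )
    )
    def test_columns_share_sorted_values_exactly(self, cols):
        df = pd.DataFrame({f"s{j}": c for j, c in enumerate(cols)})
        df.index = [f"g{i}" for i in range(4)]
        out = quantile_normalize(NormalizedMatrix(df)).values.to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(out.shape[1]):
            # ties can merge reference values, but untied columns agree exactly
            assert np.sort(out[:, j]).sum() == pytest.approx(ref.sum(), abs=1e-9)


class TestComputeFolds:
    def test_zero_fold_for_identical_values(self):
        cm = make_cm([[10, 10], [20, 20]])
        nm = NormalizedMatrix(cm.counts.astype(float))
        folds = compute_folds(nm, cm)
        assert folds.log2_fold.tolist() == [0.0, 0.0]

    def test_detection_flags_follow_raw_counts(self):
        conditions = {"c1": "control", "c2": "control", "c3": "control",
                      "t1": "treated", "t2": "treated", "t3": "treated"}
        df = pd.DataFrame([[0, 0, 0, 12, 3, 0]], columns=list(conditions), index=["g0"])
        cm = CountMatrix(df, conditions)
        folds = compute_folds(NormalizedMatrix(cm.counts.astype(float)), cm)
        row = folds.table.loc["g0"]
        assert not row["detected_control"]
        assert row["detected_treated"]

    def test_antisymmetric_under_label_swap(self, small_counts):
        nm = quantile_normalize(log_cpm(filtered := filter_low_counts(small_counts)))
        fwd = compute_folds(nm, filtered)
        swapped = CountMatrix(
            filtered.counts,
            {s: ("treated" if c == "control" else "control") for s, c in filtered.conditions.items()},
        )
        rev = compute_folds(nm, swapped)
        assert np.allclose(fwd.log2_fold.to_numpy(), -rev.log2_fold.to_numpy())

    def test_planted_shift_estimated_within_tolerance(self):
        # small shifted fraction so the library-composition effect is negligible
        from heatmod import synthetic_data as sd

        truth = sd.plan_truth(
            n_genes=5000, n_shift_modules=4, thermo_down_frac=0.0,
            n_sequence_genes=200, seed=13,
        )
        cm = sd.generate_counts(truth, nb_dispersion=0.1)
        filtered = filter_low_counts(cm)
        folds = compute_folds(quantile_normalize(log_cpm(filtered)), filtered)
        shifted = [g for g, d in truth.gene_shifts.items() if d == 1.0]
        assert folds.log2_fold.loc[shifted].mean() == pytest.approx(1.0, abs=0.1)
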