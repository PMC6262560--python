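import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from heatmod.errors import ValidationError
from heatmod.gene_sets import GeneSet, GeneSetCollection
from heatmod.module_contrast import (
    contrast_statistic,
    derive_seed,
    exact_permutation_pvalue,
    run_contrast_analysis,
    sampling_null_pvalue,
    storey_qvalues,
)
from tests.conftest import make_fold_table


@pytest.fixture
def pm_folds():
    """Universe {+1, +1, -1, -1}: the worked enumeration instance."""
    return make_fold_table([1.0, 1.0, -1.0, -1.0])


class TestContrastStatistic:
    def test_whole_universe_gives_zero(self, pm_folds):
        assert contrast_statistic(pm_folds, ["g0", "g1", "g2", "g3"]) == pytest.approx(0.0)

    def test_positive_pair_contrast_is_one(self, pm_folds):
        assert contrast_statistic(pm_folds, ["g0", "g1"]) == pytest.approx(1.0)

    def test_singleton_module(self, pm_folds):
        assert contrast_statistic(pm_folds, ["g0"]) == pytest.approx(1.0)

    def test_empty_module_rejected(self, pm_folds):
        with pytest.raises(ValidationError):
            contrast_statistic(pm_folds, [])

    def test_partition_conservation(self, fold_table_factory):
        rng = np.random.default_rng(2)
        folds = fold_table_factory(rng.normal(size=20))
        genes = folds.universe
        parts = [genes[:5], genes[5:12], genes[12:]]
        total = sum(
            len(p) * (contrast_statistic(folds, p) + folds.log2_fold.mean()) for p in parts
        )
        assert total == pytest.approx(20 * folds.log2_fold.mean())


class TestSamplingNullPvalue:
    def test_matches_enumeration_on_worked_instance(self, pm_folds):
        p = sampling_null_pvalue(pm_folds, ["g0", "g1"], B=20_000, rng_seed=5)
        assert p == pytest.approx(1 / 3, abs=0.02)

    def test_constant_folds_give_p_one(self, fold_table_factory):
        folds = fold_table_factory([0.5] * 6)
        assert sampling_null_pvalue(folds, ["g0", "g1"], B=500, rng_seed=1) == 1.0

    def test_deterministic_under_seed(self, pm_folds):
        a = sampling_null_pvalue(pm_folds, ["g0", "g1"], B=2000, rng_seed=42)
        b = sampling_null_pvalue(pm_folds, ["g0", "g1"], B=2000, rng_seed=42)
        assert a == b

    def test_p_floor_respected(self, fold_table_factory):
        rng = np.random.default_rng(0)
        folds = fold_table_factory(np.concatenate([rng.normal(size=50), [50.0] * 5]))
        p = sampling_null_pvalue(folds, [f"g{i}" for i in range(50, 55)], B=1000, rng_seed=0)
        assert p >= 1 / 1001

    def test_module_as_large_as_universe_rejected(self, pm_folds):
        with pytest.raises(ValidationError):
            sampling_null_pvalue(pm_folds, ["g0", "g1", "g2", "g3"], B=10, rng_seed=0)


class TestExactPermutationPvalue:
    def test_worked_instance(self, pm_folds):
        assert exact_permutation_pvalue(pm_folds, ["g0", "g1"]) == pytest.approx(2 / 6)

    def test_complement_symmetry(self, fold_table_factory):
        rng = np.random.default_rng(3)
        folds = fold_table_factory(rng.normal(size=10))
        members = ["g0", "g3", "g7"]
        complement = [g for g in folds.universe if g not in members]
        assert exact_permutation_pvalue(folds, members) == pytest.approx(
            exact_permutation_pvalue(folds, complement)
        )

    def test_constant_folds_give_one(self, fold_table_factory):
        folds = fold_table_factory([2.0] * 5)
        assert exact_permutation_pvalue(folds, ["g0", "g1"]) == 1.0

    def test_cap_enforced(self, fold_table_factory):
        folds = fold_table_factory(np.arange(40, dtype=float))
        with pytest.raises(ValidationError, match="sampling"):
            exact_permutation_pvalue(folds, [f"g{i}" for i in range(20)], cap=1000)


class TestStoreyQvalues:
    def test_hand_step_up_with_forced_pi0(self):
        q = storey_qvalues([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_bounded_by_pi0(self):
        q = storey_qvalues([1.0] * 20)
        assert np.all(q <= 1.0)
        assert np.all(q == q[0])

    def test_uniform_pvalues_give_pi0_near_one(self):
        p = np.random.default_rng(3).uniform(size=10_000)
        q = storey_qvalues(p)
        pi0 = q[np.argmax(p)] / p.max()  # q of the largest p is pi0 * p_max
        assert 0.9 <= pi0 <= 1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            storey_qvalues([0.5, 1.5])

    @settings(deadline=None, max_examples=30)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=40))
    def test_monotone_in_p_and_bounded(self, ps):
        q = storey_qvalues(ps)
        order = np.argsort(ps, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all((q >= 0) & (q <= 1))


class TestRunContrastAnalysis:
    def test_universe_module_gets_zero_contrast_p_one(self, fold_table_factory):
        folds = fold_table_factory([1.0, 2.0, 3.0])
        gsc = GeneSetCollection([GeneSet("ALL", "all genes", ("g0", "g1", "g2"))])
        res = run_contrast_analysis(folds, gsc, B=100, rng_seed=0)
        assert res[0].contrast == pytest.approx(0.0)
        assert res[0].p_value == 1.0

    def test_results_independent_of_collection_order(self, fold_table_factory):
        rng = np.random.default_rng(8)
        folds = fold_table_factory(rng.normal(size=30))
        sets = [
            GeneSet(f"S{i}", f"S{i}", tuple(f"g{j}" for j in rng.choice(30, 5, replace=False)))
            for i in range(6)
        ]
        res_fwd = run_contrast_analysis(folds, GeneSetCollection(sets), B=500, rng_seed=4)
        res_rev = run_contrast_analysis(folds, GeneSetCollection(sets[::-1]), B=500, rng_seed=4)
        by_id = lambda rs: {r.set_id: (r.p_value, r.contrast) for r in rs}
        assert by_id(res_fwd) == by_id(res_rev)

    def test_sorted_by_q_then_contrast(self, fold_table_factory):
        rng = np.random.default_rng(9)
        folds = fold_table_factory(rng.normal(size=40))
        sets = [
            GeneSet(f"S{i}", f"S{i}", tuple(f"g{j}" for j in rng.choice(40, 6, replace=False)))
            for i in range(8)
        ]
        res = run_contrast_analysis(folds, GeneSetCollection(sets), B=200, rng_seed=1)
        qs = [r.q_value for r in res]
        assert qs == sorted(qs)

    def test_contrast_field_consistency(self, small_folds):
        rng = np.random.default_rng(10)
        genes = small_folds.universe
        sets = [
            GeneSet(f"S{i}", f"S{i}", tuple(rng.choice(genes, 20, replace=False)))
            for i in range(4)
        ]
        for r in run_contrast_analysis(small_folds, GeneSetCollection(sets), B=100, rng_seed=0):
            assert r.contrast == pytest.approx(r.mean_fold_module - r.mean_fold_total)
            assert r.p_value >= 1 / 101


class TestDeriveSeed:
    def test_stable_and_distinct(self):
        assert derive_seed(1, "a") == derive_seed(1, "a")
        assert derive_seed(1, "a") != derive_seed(1, "b")
        assert 0 <= derive_seed(123, "x") < 2**31
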