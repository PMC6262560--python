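from itertools import combinations
from math import comb

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from heatmod.data_io import SequenceRecord
from heatmod.errors import ValidationError
from heatmod.thermo_analysis import (
    at_fraction,
    bridge_tabulation,
    direction_sign_test,
    select_thermosensitive,
)
from tests.conftest import make_fold_table


def mw_enumeration_p(x, y):
    """Two-sided exact Mann-Whitney by enumerating group assignments.

    Extremeness is |U - n1*n2/2|; valid for tie-free pooled values.
    """
    pooled = list(x) + list(y)
    n1 = len(x)

    def u_stat(group1, group2):
        return sum(a > b for a in group1 for b in group2)

    u_obs = u_stat(x, y)
    center = n1 * (len(pooled) - n1) / 2
    hits = total = 0
    for sel in combinations(range(len(pooled)), n1):
        g1 = [pooled[i] for i in sel]
        g2 = [pooled[i] for i in range(len(pooled)) if i not in sel]
        total += 1
        if abs(u_stat(g1, g2) - center) >= abs(u_obs - center) - 1e-12:
            hits += 1
    return hits / total


def binom_minlike_p(k, n):
    """Two-sided binomial p at 1/2: sum of outcomes no likelier than k."""
    pk = comb(n, k)
    return sum(comb(n, j) for j in range(n + 1) if comb(n, j) <= pk) / 2**n


class TestAtFraction:
    def test_balanced_sequence(self):
        assert at_fraction(SequenceRecord("g", "ATGC")) == pytest.approx(0.5)

    def test_pure_at(self):
        assert at_fraction(SequenceRecord("g", "AAAA")) == pytest.approx(1.0)

    def test_ns_excluded_from_both_sides(self):
        assert at_fraction(SequenceRecord("g", "ATNNGC")) == pytest.approx(0.5)

    def test_all_n_rejected(self):
        with pytest.raises(ValidationError):
            at_fraction(SequenceRecord("g", "NNNN"))

    @settings(deadline=None, max_examples=40)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=200))
    def test_at_plus_gc_is_one(self, seq):
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert at_fraction(SequenceRecord("g", seq)) + gc == pytest.approx(1.0, abs=1e-12)


class TestSelectThermosensitive:
    def test_top_gene_flagged_at_09_quantile(self):
        fracs = {f"g{i}": 0.3 + 0.05 * i for i in range(10)}
        out = select_thermosensitive(fracs, quantile=0.9)
        flagged = {a.gene_id for a in out if a.thermosensitive}
        assert flagged == {"g9"}

    def test_all_equal_all_flagged(self):
        out = select_thermosensitive({f"g{i}": 0.5 for i in range(5)})
        assert all(a.thermosensitive for a in out)

    def test_planted_top_decile_recovered(self, small_truth):
        from heatmod import synthetic_data as sd

        records = sd.generate_sequences(small_truth)
        fracs = {r.gene_id: at_fraction(r) for r in records}
        out = select_thermosensitive(fracs, quantile=0.9)
        flagged = {a.gene_id for a in out if a.thermosensitive}
        assert flagged == set(small_truth.planted_thermosensitive)

    def test_empty_collection_rejected(self):
        with pytest.raises(ValidationError):
            select_thermosensitive({})


class TestDirectionSignTest:
    def test_eleven_of_twelve_exact_binomial(self, fold_table_factory):
        vals = np.concatenate([[-1.0] * 11, [1.0], np.linspace(2, 3, 20)])
        folds = fold_table_factory(vals)
        res = direction_sign_test(folds, [f"g{i}" for i in range(12)])
        assert (res.n, res.n_down) == (12, 11)
        assert res.p_binomial == pytest.approx(26 / 4096, abs=1e-12)

    def test_balanced_two_gives_p_one(self, fold_table_factory):
        folds = fold_table_factory([-1.0, 1.0, 0.5, 0.7])
        res = direction_sign_test(folds, ["g0", "g1"])
        assert res.p_binomial == 1.0

    def test_rank_test_worked_example(self, fold_table_factory):
        folds = fold_table_factory([1.0, 2.0, 3.0, 4.0])
        res = direction_sign_test(folds, ["g0", "g1"])
        assert res.p_rank == pytest.approx(2 / 6, abs=1e-12)

    def test_zero_folds_dropped(self, fold_table_factory):
        folds = fold_table_factory([0.0, -1.0, 2.0, 3.0])
        res = direction_sign_test(folds, ["g0", "g1"])
        assert res.n == 1 and res.n_down == 1

    def test_symmetric_under_negation(self, fold_table_factory):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=30)
        vals[vals == 0] = 0.1
        members = [f"g{i}" for i in range(8)]
        a = direction_sign_test(make_fold_table(vals), members)
        b = direction_sign_test(make_fold_table(-vals), members)
        assert b.n_down == a.n - a.n_down
        assert a.p_binomial == pytest.approx(b.p_binomial, abs=1e-12)

    def test_binomial_matches_enumeration_small_n(self, fold_table_factory):
        for n, n_down in [(3, 0), (5, 4), (8, 2), (8, 8)]:
            vals = np.concatenate(
                [[-1.0] * n_down, [1.0] * (n - n_down), np.linspace(5, 6, 10)]
            )
            folds = fold_table_factory(vals)
            res = direction_sign_test(folds, [f"g{i}" for i in range(n)])
            assert res.p_binomial == pytest.approx(binom_minlike_p(n_down, n), abs=1e-12)

    def test_rank_matches_enumeration_small_groups(self, fold_table_factory):
        rng = np.random.default_rng(11)
        for n1, n2 in [(2, 3), (3, 3), (4, 5), (6, 6)]:
            vals = rng.normal(size=n1 + n2)
            folds = fold_table_factory(vals)
            members = [f"g{i}" for i in range(n1)]
            res = direction_sign_test(folds, members)
            expected = mw_enumeration_p(vals[:n1], vals[n1:])
            assert res.p_rank == pytest.approx(expected, abs=1e-12)


class TestBridgeTabulation:
    def build(self, edges):
        g = nx.Graph()
        for a, b, score, action in edges:
            g.add_edge(a, b, score=score, action=action)
        return g

    def test_activation_edge_reported(self):
        g = self.build([("BRCA1", "MDM2", 0.95, "activation")])
        out = bridge_tabulation(g, {"BRCA1"}, {"MDM2"})
        assert len(out.edges) == 1
        assert out.edges.iloc[0]["action"] == "activation"
        assert not out.has_inhibiting

    def test_low_confidence_edge_excluded(self):
        g = self.build([("BRCA1", "MDM2", 0.85, "activation")])
        assert len(bridge_tabulation(g, {"BRCA1"}, {"MDM2"}).edges) == 0

    def test_inhibiting_edge_raises_contradiction_flag(self):
        g = self.build(
            [("BRCA1", "MDM2", 0.95, "activation"), ("ATM", "KRAS", 0.92, "inhibition")]
        )
        out = bridge_tabulation(g, {"BRCA1", "ATM"}, {"MDM2", "KRAS"})
        assert out.has_inhibiting
        assert out.action_counts == {"activation": 1, "inhibition": 1}

    def test_within_class_edges_ignored(self):
        g = self.build([("BRCA1", "ATM", 0.99, "activation")])
        assert len(bridge_tabulation(g, {"BRCA1", "ATM"}, {"MDM2"}).edges) == 0
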