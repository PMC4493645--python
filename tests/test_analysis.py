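"""Breadth, bimodality, consistency and integration analyses."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tissuescore.analysis import (
    BreadthHistogram,
    bimodality_fraction,
    build_mrna_reference,
    expression_breadth,
    integrated_vs_single,
    overlap_report,
    pool_evidence,
    shared_universe,
    venn_counts,
)
from tissuescore.calibration import ConfidenceCutoffs
from tissuescore.tables import AssociationTable, GoldStandard

CUT = ConfidenceCutoffs(1, 10, 100)


def _table(records, name="toy"):
    return AssociationTable.from_records(name, "expression_units", records)


class TestExpressionBreadth:
    def test_hand_classified_fixture(self):
        # g1 high everywhere, g2 high once, g3 never above low
        records = [
            ("g1", "t1", 150), ("g1", "t2", 200), ("g1", "t3", 300),
            ("g2", "t1", 120), ("g2", "t2", 50), ("g2", "t3", 5),
            ("g3", "t1", 0.5), ("g3", "t2", 0.2), ("g3", "t3", 0.1),
        ]
        breadth, hist = expression_breadth(_table(records), CUT, "high", n_tissues=3)
        assert breadth.to_dict() == {"g1": 3, "g2": 1, "g3": 0}
        assert hist.counts.tolist() == [1, 1, 0, 1]

    def test_extremes(self):
        records = [("g1", f"t{j}", 1000) for j in range(21)]
        breadth, _ = expression_breadth(_table(records), CUT, "high", n_tissues=21)
        assert breadth["g1"] == 21

    def test_level_monotonicity_per_gene(self):
        rng = np.random.default_rng(4)
        records = [
            (f"g{i}", f"t{j}", float(rng.uniform(0, 200)))
            for i in range(30)
            for j in range(8)
        ]
        table = _table(records)
        b_low, _ = expression_breadth(table, CUT, "low", n_tissues=8)
        b_med, _ = expression_breadth(table, CUT, "medium", n_tissues=8)
        b_high, _ = expression_breadth(table, CUT, "high", n_tissues=8)
        assert (b_high <= b_med).all() and (b_med <= b_low).all()

    def test_histogram_mass_equals_expressed_genes(self):
        records = [("g1", "t1", 50), ("g2", "t1", 0.1)]
        _, hist = expression_breadth(_table(records), CUT, "medium", n_tissues=3)
        assert hist.n_expressed_genes == 1


class TestBimodality:
    def test_all_specific(self):
        hist = BreadthHistogram([0, 10, 0, 0, 0, 0, 0, 0], "medium", 7)
        assert bimodality_fraction(hist, 1) == 1.0

    def test_uniform_distribution(self):
        hist = BreadthHistogram([0] + [5] * 20, "medium", 20)
        assert bimodality_fraction(hist, 3) == pytest.approx(6 / 20)

    def test_two_spike(self):
        counts = np.zeros(22, dtype=int)
        counts[1] = 50
        counts[21] = 50
        hist = BreadthHistogram(counts, "medium", 21)
        assert bimodality_fraction(hist, 3) == 1.0

    def test_k_bounds(self):
        hist = BreadthHistogram([0, 1, 1, 1, 1, 1, 1], "medium", 6)
        with pytest.raises(ValueError):
            bimodality_fraction(hist, 3)  # 3 >= 6/2


class TestSharedUniverse:
    def test_identical_tables(self):
        t = _table([("g1", "t1", 1), ("g2", "t2", 1)])
        genes, tissues = shared_universe([t, t])
        assert genes == {"g1", "g2"} and tissues == {"t1", "t2"}

    def test_staggered_coverage(self):
        t1 = _table([("g1", "t1", 1), ("g2", "t2", 1), ("g3", "t3", 1)], "a")
        t2 = _table([("g2", "t1", 1), ("g3", "t2", 1)], "b")
        t3 = _table([("g2", "t2", 1), ("g3", "t1", 1), ("g4", "t2", 1)], "c")
        genes, tissues = shared_universe([t1, t2, t3])
        assert genes == {"g2", "g3"} and tissues == {"t1", "t2"}

    def test_disjoint_genes_error(self):
        t1 = _table([("g1", "t1", 1)], "a")
        t2 = _table([("g2", "t1", 1)], "b")
        with pytest.raises(ValueError):
            shared_universe([t1, t2])


class TestVennCounts:
    def test_two_disjoint_sets(self):
        counts = venn_counts({"a": {1, 2}, "b": {3, 4, 5}})
        assert counts == {"10": 2, "01": 3}

    def test_five_identical_sets(self):
        s = {1, 2, 3}
        counts = venn_counts({n: s for n in "abcde"})
        assert counts == {"11111": 3}

    def test_brute_force_oracle_on_random_sets(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            sets = {
                n: set(rng.choice(50, size=rng.integers(0, 30), replace=False))
                for n in ("x", "y", "z")
            }
            counts = venn_counts(sets)
            union = set().union(*sets.values())
            expected = {}
            for e in union:
                pat = "".join("1" if e in sets[n] else "0" for n in ("x", "y", "z"))
                expected[pat] = expected.get(pat, 0) + 1
            assert counts == expected
            assert sum(counts.values()) == len(union)

    def test_per_set_totals_recoverable(self):
        sets = {"a": {1, 2, 3}, "b": {2, 3, 4}}
        counts = venn_counts(sets)
        total_a = sum(c for p, c in counts.items() if p[0] == "1")
        assert total_a == 3

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        st.lists(
            st.sets(st.integers(0, 30)), min_size=1, max_size=5
        ).filter(lambda ls: any(ls))
    )
    def test_mass_conservation_on_arbitrary_sets(self, sets_list):
        named = {f"s{i}": s for i, s in enumerate(sets_list)}
        counts = venn_counts(named)
        assert sum(counts.values()) == len(set().union(*sets_list))
        for i, name in enumerate(named):
            total = sum(c for p, c in counts.items() if p[i] == "1")
            assert total == len(named[name])


class TestOverlapReport:
    def test_single_set_all_unique(self):
        rep = overlap_report({"1": 7}, ["only"])
        assert rep["unique_to"]["only"] == 100.0
        assert rep["shared_by_all_pct"] == 100.0

    def test_exclusive_percentages_sum_to_100(self):
        counts = {"110": 5, "011": 7, "100": 1, "111": 2}
        rep = overlap_report(counts)
        assert sum(rep["pattern_pct"].values()) == pytest.approx(100.0)

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            overlap_report({})


class TestMrnaReference:
    def _tables(self):
        # pair (g1,t1) high in 3/5 tables, (g2,t1) high in 2/5
        tables = []
        for i in range(5):
            recs = [("g1", "t1", 500 if i < 3 else 5)]
            recs.append(("g2", "t1", 500 if i < 2 else 5))
            tables.append(_table(recs, f"d{i}"))
        return tables

    def _cutoffs(self):
        return {f"d{i}": CUT for i in range(5)}

    def test_min_support_three(self):
        ref = build_mrna_reference(self._tables(), self._cutoffs(), 3)
        assert ref == {("g1", "t1")}

    def test_min_support_one_is_union_of_high(self):
        ref = build_mrna_reference(self._tables(), self._cutoffs(), 1)
        assert ref == {("g1", "t1"), ("g2", "t1")}

    def test_antitone_in_min_support(self):
        tables, cutoffs = self._tables(), self._cutoffs()
        refs = [build_mrna_reference(tables, cutoffs, m) for m in range(1, 6)]
        for a, b in zip(refs, refs[1:]):
            assert b <= a

    def test_min_support_above_table_count_rejected(self):
        with pytest.raises(ValueError):
            build_mrna_reference(self._tables(), self._cutoffs(), 6)


class TestPoolEvidence:
    def test_union_of_disjoint_tables(self):
        t1 = _table([("g1", "t1", 500)], "a")
        t2 = _table([("g2", "t2", 500)], "b")
        pooled = pool_evidence([t1, t2], {"a": CUT, "b": CUT}, "high")
        assert pooled == {("g1", "t1"), ("g2", "t2")}

    def test_level_filter(self):
        t1 = _table([("g1", "t1", 50), ("g2", "t1", 500)], "a")
        pooled = pool_evidence([t1], {"a": CUT}, "high")
        assert pooled == {("g2", "t1")}


class TestIntegratedVsSingle:
    def test_identical_sets_identical_fractions(self):
        records = [("g1", "t1", 9.0), ("g2", "t1", 5.0), ("g3", "t1", 1.0)]
        single = _table(records, "gnf")
        gold = GoldStandard.from_pairs([("g1", "t1"), ("g3", "t1")])
        integrated = {("g1", "t1"), ("g2", "t1"), ("g3", "t1")}
        comp = integrated_vs_single(integrated, single, gold)
        assert comp.fraction_integrated == comp.fraction_single
        assert comp.n_extra == 0

    def test_gold_equals_universe(self):
        records = [("g1", "t1", 2.0), ("g2", "t1", 1.0)]
        single = _table(records, "gnf")
        gold = GoldStandard.from_pairs([("g1", "t1"), ("g2", "t1")])
        comp = integrated_vs_single({("g1", "t1")}, single, gold)
        assert comp.fraction_integrated == 1.0
        assert comp.fraction_single == 1.0

    def test_toy_enumeration(self):
        # universe 3 genes x 2 tissues; gold 3 pairs; integrated 3 pairs (2 in gold)
        gold = GoldStandard.from_pairs([("g1", "t1"), ("g2", "t1"), ("g3", "t2")])
        records = [
            ("g1", "t1", 10.0), ("g1", "t2", 9.0), ("g2", "t1", 8.0),
            ("g2", "t2", 3.0), ("g3", "t1", 2.0), ("g3", "t2", 1.0),
        ]
        single = _table(records, "gnf")
        integrated = {("g1", "t1"), ("g3", "t2"), ("g2", "t2")}
        comp = integrated_vs_single(integrated, single, gold)
        assert comp.fraction_integrated == pytest.approx(2 / 3)
        # top-3 by score: (g1,t1),(g1,t2),(g2,t1) -> 2 in gold
        assert comp.fraction_single == pytest.approx(2 / 3)
        assert comp.n_extra == 0

    def test_integrated_larger_than_single_errors(self):
        single = _table([("g1", "t1", 1.0)], "gnf")
        gold = GoldStandard.from_pairs([("g1", "t1"), ("g2", "t1")])
        with pytest.raises(ValueError):
            integrated_vs_single(
                {("g1", "t1"), ("g2", "t1")},
                single,
                gold,
                universe=({"g1", "g2"}, {"t1"}),
            )
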