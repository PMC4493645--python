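"""Per-dataset filtering, digestion, mapping and aggregation rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tissuescore.calibration import ConfidenceCutoffs, TransformSpec
from tissuescore.datasets import (
    DatasetProfile,
    RawMeasurement,
    aggregate_gene_scores,
    build_association_table,
    filter_probe_sets,
    map_aliases,
    map_peptides_to_genes,
    translate_staining,
    tryptic_digest,
)
from tissuescore.ontology import MajorTissueSet


class TestFilterProbeSets:
    @pytest.mark.parametrize(
        "pid,kept",
        [
            ("AFFX-BioB-5_at", False),  # control probe set
            ("201000_x_at", False),  # cross-hybridizing suffix
            ("201000_r_at", False),
            ("201000_i_at", False),
            ("201000_f_at", False),
            ("201000_at", True),
            ("201000_s_at", True),  # _s_at is not in the removal list
        ],
    )
    def test_rules(self, pid, kept):
        assert (filter_probe_sets([pid]) == [pid]) is kept

    def test_is_projection_and_order_preserving(self):
        ids = ["b_at", "AFFX-1", "a_x_at", "c_at", "d_f_at"]
        once = filter_probe_sets(ids)
        assert once == ["b_at", "c_at"]
        assert filter_probe_sets(once) == once


class TestMapAliases:
    def test_rename_drop_and_fanout(self):
        ms = [
            RawMeasurement("s1", "ext1", "liver", 1.0),
            RawMeasurement("s2", "ext2", "liver", 2.0),
            RawMeasurement("s3", "ext3", "liver", 3.0),
        ]
        aliases = {"ext1": ("G1",), "ext3": ("G3", "G4")}
        out = map_aliases(ms, aliases)
        assert [(m.gene, m.value) for m in out] == [
            ("G1", 1.0),
            ("G3", 3.0),
            ("G4", 3.0),
        ]


class TestAggregate:
    @pytest.mark.parametrize(
        "values,method,expected",
        [([2, 4], "mean", 3), ([5, 7], "sum", 12), ([4.5], "mean", 4.5)],
    )
    def test_basic(self, values, method, expected):
        assert aggregate_gene_scores(values, method) == expected

    def test_empty_list_errors(self):
        with pytest.raises(ValueError):
            aggregate_gene_scores([], "mean")


class TestTranslateStaining:
    @pytest.mark.parametrize(
        "label,value",
        [("not detected", 0), ("low", 1), ("medium", 3), ("high", 6), ("High", 6)],
    )
    def test_levels(self, label, value):
        assert translate_staining(label) == value

    def test_unknown_label_named_in_error(self):
        with pytest.raises(ValueError, match="moderate"):
            translate_staining("moderate")


def _brute_force_digest(seq, max_missed):
    """Oracle: every substring spanning <= max_missed internal K/R boundaries
    whose ends coincide with cleavage boundaries."""
    if not seq:
        return []
    cuts = [0] + [i + 1 for i in range(len(seq) - 1) if seq[i] in "KR"] + [len(seq)]
    frags = []
    for a in range(len(cuts) - 1):
        for b in range(a + 1, len(cuts)):
            if b - a - 1 <= max_missed:
                frags.append((seq[cuts[a] : cuts[b]], cuts[a]))
    return sorted(frags)


class TestTrypticDigest:
    def test_cleaves_after_k_and_r(self):
        assert [p for p, _ in tryptic_digest("MKLR", 0)] == ["MK", "LR"]

    def test_no_cleavage_sites(self):
        assert [p for p, _ in tryptic_digest("AAAA", 2)] == ["AAAA"]

    def test_missed_cleavage_enumeration(self):
        got = [p for p, _ in tryptic_digest("AKBKC", 2)]
        assert got == ["AK", "BK", "C", "AKBK", "BKC", "AKBKC"]

    def test_empty_sequence(self):
        assert tryptic_digest("", 2) == []

    def test_start_positions(self):
        assert tryptic_digest("MKLR", 0) == [("MK", 0), ("LR", 2)]

    def test_zero_missed_fragments_reconstruct_sequence(self):
        rng = np.random.default_rng(11)
        aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for _ in range(200):
            seq = "".join(rng.choice(aas, size=30))
            frags = tryptic_digest(seq, 0)
            assert "".join(p for p, _ in frags) == seq

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(
        st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=0, max_size=40),
        st.integers(0, 3),
    )
    def test_digest_matches_brute_force_on_arbitrary_sequences(self, seq, m):
        assert sorted(tryptic_digest(seq, m)) == _brute_force_digest(seq, m)

    def test_fragment_count_formula_and_brute_force_oracle(self):
        # with c internal cleavage sites: sum_{j=0..m} max(0, c+1-j) fragments
        rng = np.random.default_rng(12)
        aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for _ in range(1000):
            seq = "".join(rng.choice(aas, size=30))
            m = int(rng.integers(0, 4))
            got = tryptic_digest(seq, m)
            assert sorted(got) == _brute_force_digest(seq, m)
            c = sum(1 for i in range(len(seq) - 1) if seq[i] in "KR")
            assert len(got) == sum(max(0, c + 1 - j) for j in range(m + 1))


class TestMapPeptidesToGenes:
    PROTEOME = {"G1": "MKAAARLLLK", "G2": "MKCCCR"}

    def test_unique_peptides_counted_once_per_tissue(self):
        observed = [
            ("AAAR", "liver", True),
            ("LLLK", "liver", True),
            ("AAARLLLK", "liver", True),  # one missed cleavage
            ("AAAR", "liver", True),  # duplicate observation
            ("CCCR", "liver", True),
        ]
        table = map_peptides_to_genes(observed, self.PROTEOME, max_missed=2)
        scores = {
            (g, t): s
            for g, t, s in table.data[["gene", "tissue", "score"]].itertuples(False)
        }
        assert scores == {("G1", "liver"): 3, ("G2", "liver"): 1}

    def test_shared_peptide_discarded(self):
        # MK is a tryptic peptide of both proteins -> evidence for neither
        table = map_peptides_to_genes([("MK", "liver", True)], self.PROTEOME)
        assert len(table) == 0

    def test_absent_and_unmatched_peptides_ignored(self):
        observed = [("AAAR", "liver", False), ("WWWW", "liver", True)]
        table = map_peptides_to_genes(observed, self.PROTEOME)
        assert len(table) == 0

    def test_scores_are_nonnegative_integers_for_known_genes(self):
        rng = np.random.default_rng(3)
        aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        proteome = {
            f"G{i}": "".join(rng.choice(aas, size=25)) for i in range(8)
        }
        peptides = [p for seq in proteome.values() for p, _ in tryptic_digest(seq, 2)]
        observed = [
            (rng.choice(peptides), f"t{rng.integers(3)}", True) for _ in range(200)
        ]
        table = map_peptides_to_genes(observed, proteome)
        assert set(table.data["gene"]) <= set(proteome)
        assert (table.data["score"] == table.data["score"].astype(int)).all()
        assert (table.data["score"] >= 0).all()


def _profile(name="toy", family="expression_units", aggregation="mean", probe_filter=False):
    return DatasetProfile(
        name=name,
        score_family=family,
        aggregation=aggregation,
        cutoffs=ConfidenceCutoffs(1, 2, 3),
        transform=TransformSpec("linear", {"a": 1.0, "b": 0.0}),
        probe_filter=probe_filter,
    )


class TestBuildAssociationTable:
    def test_mean_of_two_probe_sets(self):
        ms = [
            RawMeasurement("p1_at", "G1", "liver", 10.0),
            RawMeasurement("p2_at", "G1", "liver", 20.0),
        ]
        table = build_association_table(ms, _profile(probe_filter=True))
        assert table.data.iloc[0]["score"] == 15.0

    def test_est_clusters_summed(self):
        ms = [
            RawMeasurement("c1", "G1", "liver", 4.0),
            RawMeasurement("c2", "G1", "liver", 6.0),
        ]
        table = build_association_table(
            ms, _profile(family="est_count", aggregation="sum")
        )
        assert table.data.iloc[0]["score"] == 10.0

    def test_adult_and_fetal_samples_averaged_on_shared_term(self, toy_dag):
        # two samples whose labels resolve to the same ontology term
        ms = [
            RawMeasurement("s_adult", "G1", "Liver", 4.0),
            RawMeasurement("s_fetal", "G1", "hepatic tissue", 8.0),
        ]
        table = build_association_table(
            ms, _profile(family="peptide_count"), dag=toy_dag
        )
        assert list(table.data["tissue"]) == ["T:liver"]
        assert table.data.iloc[0]["score"] == 6.0

    def test_probe_filter_only_when_profile_asks(self):
        ms = [RawMeasurement("AFFX-1", "G1", "liver", 5.0)]
        assert len(build_association_table(ms, _profile(probe_filter=True))) == 0
        assert len(build_association_table(ms, _profile(probe_filter=False))) == 1

    def test_subregion_scores_propagate_to_major(self, toy_dag):
        majors = MajorTissueSet(("T:brain", "T:liver"))
        ms = [
            RawMeasurement("s1", "G1", "cerebral cortex", 7.0),
            RawMeasurement("s2", "G1", "brain", 9.0),
        ]
        table = build_association_table(ms, _profile(), dag=toy_dag, majors=majors)
        assert list(table.data["tissue"]) == ["T:brain"]
        assert table.data.iloc[0]["score"] == 8.0

    def test_unresolvable_tissue_dropped_and_empty_table_ok(self, toy_dag):
        ms = [RawMeasurement("s1", "G1", "retina and testis", 5.0)]
        table = build_association_table(ms, _profile(), dag=toy_dag)
        assert len(table) == 0

    def test_unique_keys_on_random_inputs(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            ms = [
                RawMeasurement(
                    f"s{i}",
                    f"G{rng.integers(4)}",
                    f"tis{rng.integers(3)}",
                    float(rng.integers(0, 50)),
                )
                for i in range(int(rng.integers(1, 40)))
            ]
            table = build_association_table(ms, _profile())
            assert not table.data.duplicated(["gene", "tissue"]).any()
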