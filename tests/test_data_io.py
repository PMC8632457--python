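import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adsim.data_io import (
    DiseaseGeneMap,
    InteractionNetwork,
    ParseError,
    SimilarityMatrix,
    StructuralError,
    WeightedFunctionalNetwork,
    read_disease_gene_table,
    read_edge_list,
    read_obo,
    read_similarity_matrix,
    read_term_mapping,
    TermMapping,
    write_similarity_matrix,
)


class TestDiseaseGeneTable:
    def test_duplicate_rows_and_case_collapse(self, tmp_path):
        p = tmp_path / "dg.tsv"
        p.write_text("D1\ttnf\nD1\tTNF\nD2\tIL6\n")
        dmap = read_disease_gene_table(p)
        assert dmap.entries == {"D1": {"TNF"}, "D2": {"IL6"}}

    def test_gmt_format(self, tmp_path):
        p = tmp_path / "dg.gmt"
        p.write_text("D1\tdesc\ttnf\tIL6\nD2\t\tCTLA4\n")
        dmap = read_disease_gene_table(p, fmt="gmt")
        assert dmap.entries == {"D1": {"TNF", "IL6"}, "D2": {"CTLA4"}}

    def test_malformed_row_names_line_number(self, tmp_path):
        p = tmp_path / "dg.tsv"
        p.write_text("D1\tTNF\nD1\t\n")
        with pytest.raises(ParseError, match=":2"):
            read_disease_gene_table(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "dg.tsv"
        p.write_text("")
        with pytest.raises(ParseError, match="empty"):
            read_disease_gene_table(p)

    def test_empty_gene_set_invariant(self):
        with pytest.raises(ValueError, match="empty gene set"):
            DiseaseGeneMap({"D1": frozenset()})

    def test_union_size_consistency(self):
        dmap = DiseaseGeneMap.from_raw({"D1": ["a", "b"], "D2": ["b", "c"]})
        assert len(dmap.all_genes()) == len({"A", "B", "C"})


class TestEdgeList:
    def test_reversed_duplicates_merge(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("A\tB\nB\tA\n")
        net = read_edge_list(p)
        assert net.edges == {("A", "B")}

    def test_weighted_extrema_cached(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("A\tB\t1.0\nC\tD\t3.0\n")
        net = read_edge_list(p, weighted=True)
        assert isinstance(net, WeightedFunctionalNetwork)
        assert net.lls_min == 1.0 and net.lls_max == 3.0

    def test_self_loop_skipped_with_warning(self, tmp_path, caplog):
        p = tmp_path / "e.tsv"
        p.write_text("A\tA\t2.0\nA\tB\t1.0\n")
        with caplog.at_level("WARNING", logger="adsim"):
            net = read_edge_list(p, weighted=True)
        assert len(net) == 1
        assert any("self-loop" in r.message for r in caplog.records)

    def test_non_numeric_weight_rejected(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("A\tB\theavy\n")
        with pytest.raises(ParseError, match="non-numeric"):
            read_edge_list(p, weighted=True)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        pairs=st.lists(
            st.tuples(
                st.sampled_from("ABCDEF"), st.sampled_from("ABCDEF")
            ).filter(lambda p: p[0] != p[1]),
            min_size=1,
            max_size=12,
        ),
        rnd=st.randoms(use_true_random=False),
    )
    def test_row_order_and_reversal_invariance(self, tmp_path_factory, pairs, rnd):
        """The parsed network is invariant under row permutation and edge reversal."""
        tmp = tmp_path_factory.mktemp("edges")
        p1, p2 = tmp / "a.tsv", tmp / "b.tsv"
        p1.write_text("".join(f"{a}\t{b}\n" for a, b in pairs))
        flipped = [(b, a) if rnd.random() < 0.5 else (a, b) for a, b in pairs]
        rnd.shuffle(flipped)
        p2.write_text("".join(f"{a}\t{b}\n" for a, b in flipped))
        assert read_edge_list(p1).edges == read_edge_list(p2).edges


OBO_CHAIN = """format-version: 1.2
ontology: test

[Term]
id: a
name: a

[Term]
id: b
name: b
is_a: a

[Term]
id: c
name: c
is_a: b
"""


class TestObo:
    def test_chain_root_and_edges(self, tmp_path):
        p = tmp_path / "o.obo"
        p.write_text(OBO_CHAIN)
        onto = read_obo(p)
        assert onto.root == "a"
        assert onto.isa_edges == {("b", "a"), ("c", "b")}

    def test_obsolete_terms_excluded(self, tmp_path):
        p = tmp_path / "o.obo"
        p.write_text(OBO_CHAIN + "\n[Term]\nid: d\nname: d\nis_a: a\nis_obsolete: true\n")
        onto = read_obo(p)
        assert "d" not in onto.terms

    def test_cycle_rejected(self, tmp_path):
        p = tmp_path / "o.obo"
        p.write_text(
            "format-version: 1.2\nontology: test\n\n"
            "[Term]\nid: a\nname: a\nis_a: b\n\n[Term]\nid: b\nname: b\nis_a: a\n"
        )
        with pytest.raises(StructuralError, match="cycle"):
            read_obo(p)

    def test_ambiguous_root_needs_explicit_choice(self, tmp_path):
        p = tmp_path / "o.obo"
        p.write_text(
            "format-version: 1.2\nontology: test\n\n"
            "[Term]\nid: a\nname: a\n\n[Term]\nid: b\nname: b\n\n"
            "[Term]\nid: c\nname: c\nis_a: a\n"
        )
        with pytest.raises(StructuralError, match="root not unique"):
            read_obo(p)
        # term b does not reach the chosen root, so construction still fails
        with pytest.raises(StructuralError, match="does not reach root"):
            read_obo(p, root="a")


class TestSimilarityMatrixIO:
    def test_round_trip_preserves_printed_precision(self, tmp_path):
        m = SimilarityMatrix(
            ["D1", "D2"],
            np.array([[1.0, 0.704362256], [0.704362256, 1.0]]),
            "integrated",
        )
        path = tmp_path / "m.tsv"
        write_similarity_matrix(m, path)
        assert "0.704362256" in path.read_text()
        back = read_similarity_matrix(path, "integrated")
        assert back.diseases == m.diseases
        np.testing.assert_allclose(back.values, m.values, atol=1e-9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(n=st.integers(2, 6), rnd=st.randoms(use_true_random=False))
    def test_random_matrix_round_trip(self, tmp_path_factory, n, rnd):
        vals = np.array([[rnd.random() for _ in range(n)] for _ in range(n)])
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 1.0)
        m = SimilarityMatrix([f"D{i}" for i in range(n)], vals, "funsim")
        path = tmp_path_factory.mktemp("mat") / "m.tsv"
        write_similarity_matrix(m, path)
        back = read_similarity_matrix(path, "funsim")
        np.testing.assert_allclose(back.values, m.values, atol=1e-9)

    def test_asymmetric_matrix_refused(self, tmp_path):
        with pytest.raises(ValueError, match="asymmetric"):
            SimilarityMatrix(["a", "b"], np.array([[1.0, 0.5], [0.2, 1.0]]), "netsim")
        m = SimilarityMatrix(["a", "b"], np.array([[1.0, 0.5], [0.5, 1.0]]), "netsim")
        m.values[0, 1] = 0.9  # mutated behind the type's back
        with pytest.raises(ValueError, match="refusing"):
            write_similarity_matrix(m, tmp_path / "m.tsv")

    def test_unknown_tag_rejected(self):
        with pytest.raises(ValueError, match="tag"):
            SimilarityMatrix(["a"], np.array([[1.0]]), "cosine")


class TestTermMapping:
    def test_injectivity_enforced(self):
        with pytest.raises(ValueError, match="injective"):
            TermMapping({"D1": "t1", "D2": "t1"})

    def test_read_mapping(self, tmp_path):
        p = tmp_path / "map.tsv"
        p.write_text("D1\tt1\nD2\tt2\n")
        tm = read_term_mapping(p)
        assert tm.term("D1") == "t1"
        assert tm.term("D3") is None


def test_self_loops_rejected_by_network_type():
    import networkx as nx

    g = nx.Graph([("A", "A")])
    with pytest.raises(ValueError, match="self-loop"):
        InteractionNetwork(g)
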