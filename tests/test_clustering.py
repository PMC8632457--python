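import itertools
import random

import numpy as np
import pytest

from adsim.clustering import (
    cluster_shared_genes,
    hierarchical_cluster,
    significant_clusters,
    similarity_row_distance,
    write_cluster_report,
)
from adsim.data_io import DiseaseGeneMap, SimilarityMatrix

from tests.oracles import brute_row_distance


def sim(diseases, values):
    return SimilarityMatrix(diseases, np.asarray(values, dtype=float), "integrated")


def random_sim(rng, n):
    v = np.ones((n, n))
    for i, j in itertools.combinations(range(n), 2):
        v[i, j] = v[j, i] = rng.random()
    return sim([f"D{i}" for i in range(n)], v)


class TestRowDistance:
    def test_identical_rows_have_zero_distance(self):
        m = sim(["A", "B"], [[1.0, 1.0], [1.0, 1.0]])
        assert similarity_row_distance(m, "A", "B") == 0.0

    def test_single_coordinate_difference(self):
        # rows differ only in the third coordinate, by 0.6
        m = sim(
            ["A", "B", "C"],
            [[1.0, 1.0, 0.8], [1.0, 1.0, 0.2], [0.8, 0.2, 1.0]],
        )
        assert similarity_row_distance(m, "A", "B") == pytest.approx(0.6)

    def test_matches_coordinate_sum_oracle(self):
        rng = random.Random(9)
        for _ in range(20):
            m = random_sim(rng, 5)
            v = m.values.copy()
            np.fill_diagonal(v, 1.0)
            for i, j in itertools.combinations(range(5), 2):
                got = similarity_row_distance(m, m.diseases[i], m.diseases[j])
                assert got == pytest.approx(brute_row_distance(v.tolist(), i, j), abs=1e-12)

    def test_metric_properties_on_random_matrices(self):
        rng = random.Random(13)
        for _ in range(10):
            m = random_sim(rng, 6)
            d = m.diseases
            for a, b, c in itertools.permutations(d, 3):
                dab = similarity_row_distance(m, a, b)
                assert dab == similarity_row_distance(m, b, a)
                assert dab <= (
                    similarity_row_distance(m, a, c)
                    + similarity_row_distance(m, c, b)
                    + 1e-9
                )

    def test_undefined_entries_rejected(self):
        m = sim(["A", "B", "C"], [[1, np.nan, 0.5], [np.nan, 1, 0.5], [0.5, 0.5, 1]])
        with pytest.raises(ValueError, match="undefined"):
            similarity_row_distance(m, "A", "C")


class TestHierarchicalCluster:
    def test_two_diseases_single_merge_at_their_distance(self):
        m = sim(["A", "B"], [[1.0, 0.4], [0.4, 1.0]])
        dend = hierarchical_cluster(m)
        assert dend.linkage_matrix.shape == (1, 4)
        expected = similarity_row_distance(m, "A", "B")
        assert dend.linkage_matrix[0, 2] == pytest.approx(expected)

    def test_equidistant_leaves_cluster_deterministically(self):
        v = 0.5 * np.ones((3, 3))
        np.fill_diagonal(v, 1.0)
        m = sim(["A", "B", "C"], v)
        d1 = hierarchical_cluster(m)
        d2 = hierarchical_cluster(m)
        np.testing.assert_array_equal(d1.linkage_matrix, d2.linkage_matrix)
        assert d1.leaf_order == d2.leaf_order

    def test_unknown_linkage_rejected(self):
        m = sim(["A", "B"], [[1.0, 0.4], [0.4, 1.0]])
        with pytest.raises(ValueError, match="linkage"):
            hierarchical_cluster(m, linkage="median")

    def test_undefined_entries_drop_diseases_with_report(self):
        v = np.array(
            [[1.0, 0.5, np.nan], [0.5, 1.0, 0.6], [np.nan, 0.6, 1.0]]
        )
        m = sim(["A", "B", "C"], v)
        dend = hierarchical_cluster(m)
        assert len(dend.labels) == 2
        assert len(dend.dropped) == 1

    def test_planted_clusters_recovered_by_cutting(self, small_config):
        from scipy.cluster.hierarchy import fcluster

        from adsim.pipeline import PipelineConfig, run_pipeline

        res = run_pipeline(
            PipelineConfig(synthetic=small_config, top_k=10), write=False
        )
        dend = res.dendrogram
        cut = fcluster(dend.linkage_matrix, 3, criterion="maxclust")
        truth = res.bundle.truth
        # cutting into 3 groups must reproduce the planted partition
        partition = {}
        for label, disease in zip(cut, dend.labels):
            partition.setdefault(label, set()).add(disease)
        expected = {}
        for d, c in truth.items():
            expected.setdefault(c, set()).add(d)
        assert sorted(map(sorted, partition.values())) == sorted(
            map(sorted, expected.values())
        )


class TestSignificantClusters:
    def test_uniformly_high_similarity_is_one_cluster(self):
        v = 0.9 * np.ones((4, 4))
        np.fill_diagonal(v, 1.0)
        m = sim(["A", "B", "C", "D"], v)
        report = significant_clusters(hierarchical_cluster(m), m, threshold=0.3)
        assert report.clusters == [frozenset("ABCD")]
        assert report.unclustered == frozenset()

    def test_uniformly_low_similarity_yields_no_cluster(self):
        v = 0.1 * np.ones((4, 4))
        np.fill_diagonal(v, 1.0)
        m = sim(["A", "B", "C", "D"], v)
        report = significant_clusters(hierarchical_cluster(m), m, threshold=0.3)
        assert report.clusters == []
        assert report.unclustered == frozenset("ABCD")

    def test_clusters_verify_all_pairs_above_threshold(self):
        rng = random.Random(31)
        for _ in range(10):
            m = random_sim(rng, 7)
            report = significant_clusters(hierarchical_cluster(m), m, threshold=0.5)
            seen = set()
            for cluster in report.clusters:
                assert not (cluster & seen)  # disjoint
                seen |= cluster
                for a, b in itertools.combinations(sorted(cluster), 2):
                    assert m.loc(a, b) > 0.5

    def test_raising_threshold_never_grows_clusters(self):
        rng = random.Random(41)
        for _ in range(10):
            m = random_sim(rng, 7)
            dend = hierarchical_cluster(m)
            sizes = []
            for th in (0.2, 0.4, 0.6, 0.8):
                report = significant_clusters(dend, m, threshold=th)
                sizes.append(sum(len(c) for c in report.clusters))
            assert sizes == sorted(sizes, reverse=True)

    def test_component_extraction_agrees_on_clean_case(self):
        v = np.array(
            [
                [1.0, 0.8, 0.1, 0.1],
                [0.8, 1.0, 0.1, 0.1],
                [0.1, 0.1, 1.0, 0.7],
                [0.1, 0.1, 0.7, 1.0],
            ]
        )
        m = sim(["A", "B", "C", "D"], v)
        dend = hierarchical_cluster(m)
        clades = significant_clusters(dend, m, threshold=0.3)
        comps = significant_clusters(dend, m, threshold=0.3, extraction="components")
        assert clades.clusters == comps.clusters == [frozenset("AB"), frozenset("CD")]

    def test_invalid_threshold_rejected(self):
        m = sim(["A", "B"], [[1.0, 0.4], [0.4, 1.0]])
        dend = hierarchical_cluster(m)
        with pytest.raises(ValueError):
            significant_clusters(dend, m, threshold=1.5)


class TestClusterSharedGenes:
    def test_pairwise_intersection(self):
        dmap = DiseaseGeneMap.from_raw({"D1": ["A", "B"], "D2": ["B", "C"]})
        from adsim.clustering import ClusterReport

        report = ClusterReport(clusters=[frozenset({"D1", "D2"})])
        report = cluster_shared_genes(report, dmap)
        assert report.shared_genes == [frozenset({"B"})]

    def test_disjoint_member_empties_intersection(self):
        dmap = DiseaseGeneMap.from_raw(
            {"D1": ["A", "B"], "D2": ["B", "C"], "D3": ["Z"]}
        )
        from adsim.clustering import ClusterReport

        report = ClusterReport(clusters=[frozenset({"D1", "D2", "D3"})])
        report = cluster_shared_genes(report, dmap)
        assert report.shared_genes == [frozenset()]


def test_newick_export_parses_and_matches_leaves(tmp_path):
    import dendropy

    rng = random.Random(8)
    m = random_sim(rng, 6)
    dend = hierarchical_cluster(m)
    newick = dend.to_newick()
    tree = dendropy.Tree.get(data=newick, schema="newick")
    leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    assert leaves == set(m.diseases)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            assert edge.length >= -1e-9


def test_cluster_report_tsv(tmp_path):
    from adsim.clustering import ClusterReport

    dmap = DiseaseGeneMap.from_raw({"D1": ["A", "B"], "D2": ["B", "C"]})
    report = cluster_shared_genes(
        ClusterReport(clusters=[frozenset({"D1", "D2"})], threshold=0.3), dmap
    )
    path = tmp_path / "clusters.tsv"
    write_cluster_report(report, path)
    lines = path.read_text().splitlines()
    assert lines[0].startswith("cluster")
    assert "D1,D2" in lines[1] and "B" in lines[1]
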