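"""Candidate disease–gene network and relevant-gene extraction.

Candidate disease pairs and their associated genes form a two-layer graph:
disease–gene association edges (bipartite) plus disease–disease similarity
edges between the candidate pairs.  A gene's degree in this network equals
the number of candidate diseases it is associated with; genes linked to at
least ``min_degree`` diseases (default 3) are reported as relevant genes,
ranked by degree.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .data_io import DiseaseGeneMap
from .integration import CandidatePairSet, Pair


@dataclass
class DiseaseGeneNetwork:
    """Bipartite disease–gene graph plus disease–disease similarity edges.

    Gene nodes connect only to disease nodes; similarity edges never touch
    genes, so a gene's degree counts its associated diseases.
    """

    graph: nx.Graph
    disease_nodes: frozenset[str]
    gene_nodes: frozenset[str]
    similarity_edges: frozenset[Pair]

    def gene_degree(self, gene: str) -> int:
        return self.graph.degree(gene)


def build_network(
    pairs: CandidatePairSet | set[Pair], dmap: DiseaseGeneMap
) -> DiseaseGeneNetwork:
    """Assemble the network from candidate pairs and the disease–gene map."""
    pair_set = pairs.pairs if isinstance(pairs, CandidatePairSet) else set(pairs)
    diseases: set[str] = set()
    for d1, d2 in pair_set:
        diseases |= {d1, d2}
    for d in diseases:
        if d not in dmap.entries:
            raise KeyError(f"disease {d!r} not in disease-gene map")

    g = nx.Graph()
    genes: set[str] = set()
    for d in diseases:
        g.add_node(d, kind="disease")
        for gene in dmap.genes(d):
            # disease and gene namespaces could collide in pathological input
            if gene in diseases:
                raise ValueError(f"identifier {gene!r} is both a disease and a gene")
            g.add_node(gene, kind="gene")
            g.add_edge(d, gene, kind="association")
            genes.add(gene)
    for d1, d2 in pair_set:
        g.add_edge(d1, d2, kind="similarity")
    return DiseaseGeneNetwork(
        graph=g,
        disease_nodes=frozenset(diseases),
        gene_nodes=frozenset(genes),
        similarity_edges=frozenset(pair_set),
    )


def relevant_genes(net: DiseaseGeneNetwork, min_degree: int = 3) -> pd.DataFrame:
    """Genes associated with >= ``min_degree`` candidate diseases.

    Returns a (gene, degree) table sorted by descending degree, then
    lexicographically.  Degree counts association edges only (similarity
    edges never touch gene nodes by construction).
    """
    if min_degree < 1:
        raise ValueError("min_degree must be >= 1")
    rows = [
        {"gene": gene, "degree": net.gene_degree(gene)}
        for gene in net.gene_nodes
        if net.gene_degree(gene) >= min_degree
    ]
    frame = pd.DataFrame(rows, columns=["gene", "degree"])
    return frame.sort_values(
        by=["degree", "gene"], ascending=[False, True], ignore_index=True
    )


def export_network(net: DiseaseGeneNetwork, edges_path, nodes_path) -> None:
    """Write the network as an edge-list TSV plus a node-attribute TSV."""
    edge_rows = [
        {"source": min(a, b), "target": max(a, b), "edge_type": data["kind"]}
        for a, b, data in net.graph.edges(data=True)
    ]
    pd.DataFrame(edge_rows, columns=["source", "target", "edge_type"]).sort_values(
        by=["edge_type", "source", "target"], ignore_index=True
    ).to_csv(edges_path, sep="\t", index=False)
    node_rows = [
        {
            "node": v,
            "node_type": net.graph.nodes[v]["kind"],
            "degree": net.graph.degree(v),
        }
        for v in sorted(net.graph.nodes)
    ]
    pd.DataFrame(node_rows, columns=["node", "node_type", "degree"]).to_csv(
        nodes_path, sep="\t", index=False
    )
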