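"""Hierarchical clustering of the integrated similarity matrix.

Diseases are clustered on the Euclidean distances between their full
similarity-profile rows (diagonal set to 1 first, so each row includes the
disease's own column):

    E(d1, d2) = sqrt( sum_i (x_1i - x_2i)^2 )

Agglomerative linkage (default: average/UPGMA) produces a dendrogram;
"significant" clusters are the maximal dendrogram clades of size >= 2 in
which every within-clade pair's integrated similarity exceeds a threshold
(default 0.3).  An alternative extraction — connected components of the
thresholded similarity graph — is available for sensitivity analysis.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .data_io import DiseaseGeneMap, SimilarityMatrix

logger = logging.getLogger("adsim")

LINKAGE_METHODS = ("average", "complete", "single", "ward")


@dataclass
class DendrogramResult:
    """Agglomerative merge tree over disease similarity profiles."""

    labels: list[str]  # leaf labels in distance-matrix order
    linkage_matrix: np.ndarray  # scipy linkage encoding
    method: str
    dropped: list[str] = field(default_factory=list)  # diseases with undefined rows

    @property
    def leaf_order(self) -> list[str]:
        order = hierarchy.leaves_list(self.linkage_matrix)
        return [self.labels[i] for i in order]

    def clades(self) -> list[frozenset[str]]:
        """Leaf sets of all internal nodes, leaves first."""
        n = len(self.labels)
        members: dict[int, frozenset[str]] = {
            i: frozenset([self.labels[i]]) for i in range(n)
        }
        out: list[frozenset[str]] = []
        for step, (a, b, _, _) in enumerate(self.linkage_matrix):
            merged = members[int(a)] | members[int(b)]
            members[n + step] = merged
            out.append(merged)
        return out

    def to_newick(self) -> str:
        """Newick string with branch lengths derived from merge heights."""
        tree = hierarchy.to_tree(self.linkage_matrix)

        def walk(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.10g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.10g}"

        return f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});"


@dataclass
class ClusterReport:
    """Significant disease clusters with their shared genes."""

    clusters: list[frozenset[str]]
    shared_genes: list[frozenset[str]] = field(default_factory=list)
    threshold: float = 0.3
    unclustered: frozenset[str] = frozenset()
    extraction: str = "clades"


def _complete_submatrix(m: SimilarityMatrix) -> tuple[list[str], np.ndarray, list[str]]:
    """Diagonal set to 1; diseases with undefined entries dropped (reported)."""
    values = m.values.copy()
    np.fill_diagonal(values, 1.0)
    labels = list(m.diseases)
    dropped: list[str] = []
    while np.isnan(values).any():
        nan_counts = np.isnan(values).sum(axis=1)
        worst = int(np.argmax(nan_counts))
        dropped.append(labels[worst])
        labels = labels[:worst] + labels[worst + 1 :]
        values = np.delete(np.delete(values, worst, axis=0), worst, axis=1)
    if dropped:
        logger.warning(
            "clustering: dropped diseases with undefined similarity entries: %s", dropped
        )
    return labels, values, dropped


def similarity_row_distance(m: SimilarityMatrix, d1: str, d2: str) -> float:
    """Euclidean distance between two diseases' full similarity-profile rows."""
    i, j = m.diseases.index(d1), m.diseases.index(d2)
    values = m.values.copy()
    np.fill_diagonal(values, 1.0)
    r1, r2 = values[i], values[j]
    if np.isnan(r1).any() or np.isnan(r2).any():
        raise ValueError(f"undefined entries in rows of {d1!r} or {d2!r}")
    return float(np.sqrt(np.sum((r1 - r2) ** 2)))


def distance_matrix(m: SimilarityMatrix) -> tuple[list[str], np.ndarray, list[str]]:
    """Pairwise profile-row distances; returns (labels, matrix, dropped)."""
    labels, values, dropped = _complete_submatrix(m)
    diff = values[:, None, :] - values[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    np.fill_diagonal(dist, 0.0)
    return labels, dist, dropped


def hierarchical_cluster(
    m: SimilarityMatrix, linkage: str = "average"
) -> DendrogramResult:
    """Agglomerative clustering of the profile-row distance matrix."""
    if linkage not in LINKAGE_METHODS:
        raise ValueError(f"unknown linkage {linkage!r}; choose from {LINKAGE_METHODS}")
    labels, dist, dropped = distance_matrix(m)
    if len(labels) < 2:
        raise ValueError("fewer than 2 diseases with complete similarity rows")
    condensed = squareform(dist, checks=False)
    z = hierarchy.linkage(condensed, method=linkage)
    return DendrogramResult(labels=labels, linkage_matrix=z, method=linkage, dropped=dropped)


def significant_clusters(
    dend: DendrogramResult,
    m: SimilarityMatrix,
    threshold: float = 0.3,
    extraction: str = "clades",
) -> ClusterReport:
    """Extract significant clusters from the dendrogram.

    ``extraction="clades"`` (default): maximal dendrogram clades of size >= 2
    whose every within-clade pair has integrated similarity > threshold.
    ``extraction="components"``: connected components (size >= 2) of the
    graph linking pairs above threshold, then filtered by the same all-pairs
    rule — a dendrogram-free alternative for sensitivity analysis.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    frame = m.to_frame()
    for d in frame.index:
        frame.loc[d, d] = 1.0

    def passes(group: frozenset[str]) -> bool:
        return all(
            frame.loc[a, b] > threshold for a, b in itertools.combinations(sorted(group), 2)
        )

    universe = frozenset(dend.labels)
    if extraction == "clades":
        passing = [c for c in dend.clades() if len(c) >= 2 and passes(c)]
        clusters = [c for c in passing if not any(c < other for other in passing)]
    elif extraction == "components":
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(dend.labels)
        for a, b in itertools.combinations(dend.labels, 2):
            v = frame.loc[a, b]
            if not math.isnan(v) and v > threshold:
                g.add_edge(a, b)
        clusters = [
            frozenset(comp)
            for comp in nx.connected_components(g)
            if len(comp) >= 2 and passes(frozenset(comp))
        ]
    else:
        raise ValueError(f"unknown extraction {extraction!r}")
    clusters = sorted(clusters, key=lambda c: sorted(c))
    clustered = frozenset().union(*clusters) if clusters else frozenset()
    return ClusterReport(
        clusters=clusters,
        threshold=threshold,
        unclustered=universe - clustered,
        extraction=extraction,
    )


def cluster_shared_genes(report: ClusterReport, dmap: DiseaseGeneMap) -> ClusterReport:
    """Attach to each cluster the intersection of all member gene sets."""
    shared: list[frozenset[str]] = []
    for cluster in report.clusters:
        for d in cluster:
            if d not in dmap.entries:
                raise KeyError(f"disease {d!r} not in disease-gene map")
        sets = [dmap.genes(d) for d in sorted(cluster)]
        inter = sets[0]
        for s in sets[1:]:
            inter = inter & s
        shared.append(frozenset(inter))
    report.shared_genes = shared
    return report


def write_cluster_report(report: ClusterReport, path) -> None:
    """TSV: cluster id, member diseases, shared genes."""
    with open(path, "w") as fh:
        fh.write("cluster\tthreshold\tmembers\tshared_genes\n")
        for i, cluster in enumerate(report.clusters, start=1):
            genes = (
                ",".join(sorted(report.shared_genes[i - 1]))
                if report.shared_genes
                else ""
            )
            fh.write(
                f"{i}\t{report.threshold:g}\t{','.join(sorted(cluster))}\t{genes}\n"
            )
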