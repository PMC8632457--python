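"""Network similarity between diseases from PPI topology profiles.

Each gene in the protein–protein interaction network is profiled by five
topological properties: degree, clustering coefficient, betweenness
centrality, average shortest path length and neighborhood connectivity.
A disease's profile is the component-wise arithmetic mean over its genes
that are present in the network, giving a 5-vector T = (R, C, B, S, H).
The network similarity (NetSim) of two diseases is the Pearson correlation
coefficient between their T vectors.

Conventions (the source data offer no single standard):

* betweenness is normalised to [0, 1] by 2/((n-1)(n-2)) within each node's
  connected component of size n;
* average shortest path length is taken over the node's component only
  (infinite distances are not averageable);
* genes absent from the network are excluded from the disease average, not
  imputed as zeros;
* a pair whose correlation is undefined (constant profile vector) is
  reported as missing (NaN) and excluded from downstream ranking.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .data_io import DiseaseGeneMap, InteractionNetwork, SimilarityMatrix

logger = logging.getLogger("adsim")

PROPERTY_NAMES = ("degree", "clustering", "betweenness", "avg_path", "neighborhood")


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r via the explicit formula; exactly symmetric in (x, y)."""
    xm = x - x.mean()
    ym = y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm * xm).sum() * (ym * ym).sum()))


class UndefinedVectorError(ValueError):
    """None of a disease's genes occur in the interaction network."""

    def __init__(self, disease: str):
        self.disease = disease
        super().__init__(f"no genes of disease {disease!r} occur in the network")


@dataclass(frozen=True)
class GeneTopologyProfile:
    """Per-gene 5-property topology profile.

    ``avg_path`` is None for isolated nodes (no other node is reachable);
    such genes are excluded from the S average with a warning.
    """

    gene: str
    degree: int
    clustering: float
    betweenness: float
    avg_path: float | None
    neighborhood: float


@dataclass(frozen=True)
class TopologyVector:
    """Per-disease mean topology profile T = (R, C, B, S, H)."""

    disease: str
    R: float
    C: float
    B: float
    S: float
    H: float
    n_genes_in_network: int

    def as_array(self) -> np.ndarray:
        return np.array([self.R, self.C, self.B, self.S, self.H], dtype=float)


def gene_topology(net: InteractionNetwork) -> dict[str, GeneTopologyProfile]:
    """Compute the five topological properties for every node of the network.

    Betweenness and average path length are computed within each connected
    component; the betweenness of nodes in components of size < 3 is 0 (the
    normalisation denominator vanishes).
    """
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    clustering = nx.clustering(g)
    neigh_conn = nx.average_neighbor_degree(g)
    betweenness: dict[str, float] = {}
    avg_path: dict[str, float | None] = {}
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        n = len(comp)
        if n >= 3:
            betweenness.update(nx.betweenness_centrality(sub, normalized=True))
        else:
            betweenness.update({v: 0.0 for v in comp})
        for v in comp:
            if n == 1:
                avg_path[v] = None
            else:
                dists = nx.single_source_shortest_path_length(sub, v)
                avg_path[v] = sum(dists.values()) / (n - 1)
    return {
        v: GeneTopologyProfile(
            gene=v,
            degree=g.degree(v),
            clustering=float(clustering[v]),
            betweenness=float(betweenness[v]),
            avg_path=avg_path[v],
            neighborhood=float(neigh_conn.get(v, 0.0)),
        )
        for v in g.nodes
    }


def disease_topology_vector(
    disease: str,
    genes: frozenset[str] | set[str],
    profiles: dict[str, GeneTopologyProfile],
) -> TopologyVector:
    """Average the per-gene profiles of a disease's genes present in the network.

    Genes absent from the profile map are logged and skipped; genes with an
    undefined average path length (isolated nodes) are excluded from the S
    component only.  Raises :class:`UndefinedVectorError` if no gene of the
    disease is in the network.
    """
    present = sorted(g for g in genes if g in profiles)
    absent = sorted(set(genes) - set(present))
    if absent:
        logger.info(
            "disease %s: %d/%d genes absent from PPI network", disease, len(absent), len(genes)
        )
    if not present:
        raise UndefinedVectorError(disease)
    profs = [profiles[g] for g in present]
    s_values = [p.avg_path for p in profs if p.avg_path is not None]
    if len(s_values) < len(profs):
        logger.warning(
            "disease %s: %d isolated gene(s) excluded from path-length average",
            disease,
            len(profs) - len(s_values),
        )
    if not s_values:
        raise UndefinedVectorError(disease)
    return TopologyVector(
        disease=disease,
        R=float(np.mean([p.degree for p in profs])),
        C=float(np.mean([p.clustering for p in profs])),
        B=float(np.mean([p.betweenness for p in profs])),
        S=float(np.mean(s_values)),
        H=float(np.mean([p.neighborhood for p in profs])),
        n_genes_in_network=len(present),
    )


def netsim_pair(t1: TopologyVector, t2: TopologyVector) -> float | None:
    """Pearson correlation of two 5-component topology vectors.

    Returns None when either vector is constant across its five components
    (zero variance makes the correlation undefined).
    """
    x, y = t1.as_array(), t2.as_array()
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return None
    return _pearson(x, y)


def netsim_matrix(
    dmap: DiseaseGeneMap,
    net: InteractionNetwork,
    standardize_properties: bool = False,
) -> SimilarityMatrix:
    """All-pairs network similarity matrix.

    Diseases with no genes in the network are dropped (logged); pairs with an
    undefined correlation are stored as NaN.  The diagonal is set to 1.

    ``standardize_properties`` optionally z-scores each of the five vector
    components across diseases before correlating (an extension; the default
    correlates the raw T vectors).
    """
    profiles = gene_topology(net)
    vectors: dict[str, TopologyVector] = {}
    for disease in dmap.diseases:
        try:
            vectors[disease] = disease_topology_vector(
                disease, dmap.genes(disease), profiles
            )
        except UndefinedVectorError:
            logger.warning("disease %s has no genes in the PPI network; dropped", disease)
    diseases = sorted(vectors)
    if len(diseases) < 2:
        raise ValueError("fewer than 2 diseases with defined topology vectors")
    arrays = {d: vectors[d].as_array() for d in diseases}
    if standardize_properties:
        stacked = np.vstack([arrays[d] for d in diseases])
        mu = stacked.mean(axis=0)
        sd = stacked.std(axis=0, ddof=0)
        sd[sd == 0.0] = 1.0
        arrays = {d: (arrays[d] - mu) / sd for d in diseases}
    n = len(diseases)
    values = np.eye(n)
    for i, j in itertools.combinations(range(n), 2):
        x, y = arrays[diseases[i]], arrays[diseases[j]]
        if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
            score = np.nan
        else:
            score = _pearson(x, y)
        values[i, j] = values[j, i] = score
    return SimilarityMatrix(diseases, values, "netsim")
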