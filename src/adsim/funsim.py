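"""Functional similarity between disease gene sets (best-match average).

Edge weights of the functional gene network (log-likelihood scores, LLS)
are first min–max normalised over the whole network:

    LLS_N(gi, gj) = (LLS(gi, gj) - LLS_min) / (LLS_max - LLS_min)

The gene-level functional similarity is 1 for identical genes, LLS_N for
connected genes and 0 otherwise.  A gene's similarity to a gene set is its
best match within the set, and the disease-level score is the symmetric
best-match average over both gene sets:

    FunSim(d1, d2) = ( sum_{g in G1} F_G2(g) + sum_{g in G2} F_G1(g) ) / (m + n)

Genes absent from the functional network are retained in the sets: they
contribute a best match of 0 unless shared with the other set, which keeps
missing annotation from silently inflating similarity.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .data_io import DiseaseGeneMap, SimilarityMatrix, WeightedFunctionalNetwork, _pair


class DegenerateScaleError(ValueError):
    """All LLS weights equal: min–max normalisation has a zero denominator."""


@dataclass
class NormalizedFunctionalNetwork:
    """Functional network with edge weights min–max normalised to [0, 1]."""

    edges: dict[tuple[str, str], float]

    def weight(self, g1: str, g2: str) -> float | None:
        return self.edges.get(_pair(g1, g2))


def normalize_lls(w: WeightedFunctionalNetwork) -> NormalizedFunctionalNetwork:
    """Min–max normalise LLS weights using the network-wide extrema."""
    if not w.edges:
        raise ValueError("cannot normalise an empty functional network")
    span = w.lls_max - w.lls_min
    if span == 0.0:
        raise DegenerateScaleError(
            f"all LLS weights equal ({w.lls_min}); normalisation undefined"
        )
    return NormalizedFunctionalNetwork(
        {pair: (lls - w.lls_min) / span for pair, lls in w.edges.items()}
    )


def gene_pair_funsim(g1: str, g2: str, net: NormalizedFunctionalNetwork) -> float:
    """Gene-level functional similarity: 1 if identical, LLS_N if linked, else 0."""
    if g1 == g2:
        return 1.0
    w = net.weight(g1, g2)
    return 0.0 if w is None else w


def gene_to_set(g: str, genes: frozenset[str] | set[str], net: NormalizedFunctionalNetwork) -> float:
    """Best-match similarity of gene ``g`` against a non-empty gene set."""
    if not genes:
        raise ValueError("gene set must be non-empty")
    return max(gene_pair_funsim(g, gi, net) for gi in genes)


def funsim_pair(
    g1: frozenset[str] | set[str],
    g2: frozenset[str] | set[str],
    net: NormalizedFunctionalNetwork,
) -> float:
    """Symmetric best-match-average functional similarity of two gene sets."""
    if not g1 or not g2:
        raise ValueError("gene sets must be non-empty")
    s1, s2 = set(g1), set(g2)  # duplicates collapsed before m and n are counted
    total = sum(gene_to_set(g, s2, net) for g in s1)
    total += sum(gene_to_set(g, s1, net) for g in s2)
    return total / (len(s1) + len(s2))


def funsim_matrix(
    dmap: DiseaseGeneMap, net: NormalizedFunctionalNetwork
) -> SimilarityMatrix:
    """All-pairs functional similarity matrix; symmetric, unit diagonal."""
    diseases = dmap.diseases
    if len(diseases) < 2:
        raise ValueError("need at least 2 diseases")
    n = len(diseases)
    values = np.eye(n)
    for i, j in itertools.combinations(range(n), 2):
        score = funsim_pair(dmap.genes(diseases[i]), dmap.genes(diseases[j]), net)
        values[i, j] = values[j, i] = score
    return SimilarityMatrix(diseases, values, "funsim")
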