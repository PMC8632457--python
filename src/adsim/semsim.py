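"""Resnik semantic similarity over a disease-ontology DAG.

Direct gene annotations are propagated up the IS_A hierarchy (true-path
rule: every gene annotated to a term is counted for all of its ancestors),
after which each term's information content is

    IC(t) = -log(n_t / N)

with n_t the number of distinct genes reaching the term and N the number of
distinct genes annotated anywhere in the ontology.  The semantic similarity
of two terms is the IC of their most informative common ancestor (MICA),
where ancestor sets include the terms themselves so that
SemSim(t, t) = IC(t).

The log base is configurable (default natural log); under the default
max-IC normalisation the base cancels.
"""

from __future__ import annotations

import itertools
import logging
import math

import networkx as nx
import numpy as np

from .data_io import DiseaseGeneMap, OntologyGraph, SimilarityMatrix, TermMapping

logger = logging.getLogger("adsim")


class AnnotatedOntology:
    """Ontology with propagated annotations, IC values and ancestor closures.

    IC is anti-monotone along IS_A edges (a parent's gene set contains each
    child's), and IC(root) = 0 whenever every annotated gene reaches the
    root.  Terms with no (propagated) annotation have undefined IC and are
    skipped during MICA search.
    """

    def __init__(self, base: OntologyGraph, ic_log_base: float | None = None):
        self.base = base
        self.ic_log_base = ic_log_base  # None -> natural log
        dag = base.to_digraph()  # child -> parent
        if not base.direct_annotations or not any(base.direct_annotations.values()):
            raise ValueError("ontology has no annotated term")

        # propagate annotations leaf-to-root: each term's set is the union of
        # its direct annotations and those of all its descendants
        self.propagated: dict[str, frozenset[str]] = {}
        for term in nx.topological_sort(dag):  # children before parents
            genes: set[str] = set(base.direct_annotations.get(term, ()))
            for child in dag.predecessors(term):
                genes |= self.propagated[child]
            self.propagated[term] = frozenset(genes)

        all_genes: set[str] = set()
        for gs in self.propagated.values():
            all_genes |= gs
        self.n_total_genes = len(all_genes)

        self.ic: dict[str, float] = {}
        for term, genes in self.propagated.items():
            if genes:
                frac = len(genes) / self.n_total_genes
                ic = -math.log(frac)
                if ic_log_base is not None:
                    ic /= math.log(ic_log_base)
                self.ic[term] = ic

        # ancestor closure (including self) and depth (longest path from root)
        self._ancestors: dict[str, frozenset[str]] = {}
        self._depth: dict[str, int] = {}
        for term in reversed(list(nx.topological_sort(dag))):  # parents first
            anc: set[str] = {term}
            parents = list(dag.successors(term))
            for p in parents:
                anc |= self._ancestors[p]
            self._ancestors[term] = frozenset(anc)
            self._depth[term] = (
                0 if not parents else 1 + max(self._depth[p] for p in parents)
            )

    def ancestors(self, term: str) -> frozenset[str]:
        """Ancestor set of ``term``, including the term itself."""
        if term not in self._ancestors:
            raise KeyError(f"term {term!r} not in ontology")
        return self._ancestors[term]

    def depth(self, term: str) -> int:
        return self._depth[term]


def propagate_annotations(
    o: OntologyGraph, ic_log_base: float | None = None
) -> AnnotatedOntology:
    """Propagate annotations up the DAG and compute per-term IC."""
    return AnnotatedOntology(o, ic_log_base=ic_log_base)


def mica(t1: str, t2: str, a: AnnotatedOntology) -> str:
    """Most informative common ancestor of two terms.

    Only ancestors with defined IC compete; ties are broken by greater DAG
    depth, then lexicographically by term id.
    """
    common = a.ancestors(t1) & a.ancestors(t2)
    candidates = [t for t in common if t in a.ic]
    if not candidates:
        raise ValueError(f"no common ancestor of {t1!r} and {t2!r} has defined IC")
    return min(candidates, key=lambda t: (-a.ic[t], -a.depth(t), t))


def semsim_pair(t1: str, t2: str, a: AnnotatedOntology) -> float:
    """Resnik similarity: IC of the most informative common ancestor."""
    return a.ic[mica(t1, t2, a)]


def semsim_matrix(
    dmap: DiseaseGeneMap,
    mapping: TermMapping,
    a: AnnotatedOntology,
    normalize: bool = True,
) -> SimilarityMatrix:
    """All-pairs semantic similarity matrix over mapped diseases.

    Diseases without a term mapping (or mapped to a term absent from the
    ontology) are skipped with a logged report.  With ``normalize`` (the
    default) every entry — including the diagonal, which is IC(term) in raw
    mode — is divided by the maximum IC over the mapped terms, so entries
    lie in [0, 1] and are scale-compatible with the other measures.
    """
    mapped: dict[str, str] = {}
    skipped: list[str] = []
    for disease in dmap.diseases:
        term = mapping.term(disease)
        if term is None or term not in a.base.terms or term not in a.ic:
            skipped.append(disease)
        else:
            mapped[disease] = term
    if skipped:
        logger.warning("semsim: skipped unmapped/unannotated diseases: %s", skipped)
    diseases = sorted(mapped)
    if len(diseases) < 2:
        raise ValueError("fewer than 2 diseases with mapped ontology terms")
    n = len(diseases)
    values = np.zeros((n, n))
    for i in range(n):
        values[i, i] = a.ic[mapped[diseases[i]]]
    for i, j in itertools.combinations(range(n), 2):
        score = semsim_pair(mapped[diseases[i]], mapped[diseases[j]], a)
        values[i, j] = values[j, i] = score
    if normalize:
        max_ic = max(a.ic[mapped[d]] for d in diseases)
        if max_ic > 0:
            values = values / max_ic
        else:  # all mapped terms carry every gene; similarity is uniformly 1
            values = np.ones_like(values)
    return SimilarityMatrix(diseases, values, "semsim")
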