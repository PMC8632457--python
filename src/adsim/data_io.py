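"""Readers, writers and shared domain types for the disease-similarity pipeline.

All downstream stages consume the containers defined here:

* :class:`DiseaseGeneMap` — disease term -> set of associated gene symbols.
* :class:`InteractionNetwork` — undirected, unweighted protein–protein
  interaction network.
* :class:`WeightedFunctionalNetwork` — undirected gene network whose edges
  carry raw log-likelihood scores (LLS), as in HumanNet.
* :class:`OntologyGraph` — rooted DAG of disease terms (IS_A edges only)
  with direct term -> gene annotations.
* :class:`TermMapping` — mapping from the disease identifiers used in the
  gene table (MeSH-style labels) onto ontology term ids.
* :class:`SimilarityMatrix` — a symmetric disease × disease score matrix
  tagged with the measure it holds.

File formats are deliberately plain: 2/3-column TSV edge lists, 2-column TSV
tables, GMT-style gene-set lines, OBO 1.2 ontologies and square TSV matrices.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import obonet
import pandas as pd

logger = logging.getLogger("adsim")

SYMMETRY_TOL = 1e-12
#: measure tags a SimilarityMatrix may carry
MEASURE_TAGS = ("netsim", "funsim", "semsim", "integrated")


class ParseError(ValueError):
    """A malformed record in an input file; carries the offending line number."""


class StructuralError(ValueError):
    """Input violates a structural requirement (cycles, ambiguous root, ...)."""


def normalize_gene(symbol: str) -> str:
    """Case-normalise a gene symbol: strip surrounding whitespace, uppercase.

    No alias resolution is attempted; set intersections are therefore exact
    on the normalised symbols.
    """
    return symbol.strip().upper()


def _pair(a: str, b: str) -> tuple[str, str]:
    """Canonical unordered representation of an edge."""
    return (a, b) if a <= b else (b, a)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DiseaseGeneMap:
    """Disease identifier -> set of gene symbols.

    Gene symbols are uppercased so intersections between diseases are
    well-defined; every stored gene set is non-empty.
    """

    entries: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        for disease, genes in self.entries.items():
            if not genes:
                raise ValueError(f"disease {disease!r} has an empty gene set")

    @classmethod
    def from_raw(cls, raw: Mapping[str, Iterable[str]]) -> "DiseaseGeneMap":
        return cls(
            {d: frozenset(normalize_gene(g) for g in gs) for d, gs in raw.items()}
        )

    @property
    def diseases(self) -> list[str]:
        return sorted(self.entries)

    def genes(self, disease: str) -> frozenset[str]:
        return self.entries[disease]

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.entries.values():
            out |= genes
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class InteractionNetwork:
    """Undirected PPI network; no self-loops, no duplicate edges."""

    graph: nx.Graph

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValueError(f"self-loops not allowed: {loops[:3]}")

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "InteractionNetwork":
        g = nx.Graph()
        g.add_edges_from((a, b) for a, b in edges if a != b)
        return cls(g)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {_pair(a, b) for a, b in self.graph.edges}

    def __contains__(self, gene: str) -> bool:
        return gene in self.graph


@dataclass
class WeightedFunctionalNetwork:
    """Undirected functional gene network with raw LLS edge weights.

    ``lls_min`` / ``lls_max`` are cached over the whole network; min–max
    normalisation (the first step of the functional-similarity measure) uses
    these global extrema.
    """

    edges: dict[tuple[str, str], float]
    lls_min: float = field(init=False)
    lls_max: float = field(init=False)

    def __post_init__(self) -> None:
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop not allowed: ({a},{b})")
            if (a, b) != _pair(a, b):
                raise ValueError(f"edge key not in canonical order: ({a},{b})")
        if self.edges:
            vals = list(self.edges.values())
            self.lls_min = min(vals)
            self.lls_max = max(vals)
        else:
            self.lls_min = math.nan
            self.lls_max = math.nan

    @classmethod
    def from_edges(
        cls, triples: Iterable[tuple[str, str, float]]
    ) -> "WeightedFunctionalNetwork":
        edges: dict[tuple[str, str], float] = {}
        for a, b, w in triples:
            if a == b:
                continue
            edges[_pair(a, b)] = float(w)
        return cls(edges)

    def weight(self, g1: str, g2: str) -> float | None:
        return self.edges.get(_pair(g1, g2))

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class OntologyGraph:
    """Rooted DAG of disease terms connected by IS_A edges.

    ``isa_edges`` point child -> parent.  The IS_A graph must be acyclic and
    every term must reach the root.  ``direct_annotations`` holds the genes
    annotated directly to each term, before any propagation.
    """

    terms: frozenset[str]
    isa_edges: frozenset[tuple[str, str]]
    direct_annotations: dict[str, frozenset[str]]
    root: str

    def __post_init__(self) -> None:
        if self.root not in self.terms:
            raise StructuralError(f"root {self.root!r} not among terms")
        for child, parent in self.isa_edges:
            if child not in self.terms or parent not in self.terms:
                raise StructuralError(f"isa edge ({child},{parent}) leaves term set")
        extra = set(self.direct_annotations) - set(self.terms)
        if extra:
            raise StructuralError(f"annotations on unknown terms: {sorted(extra)[:3]}")
        dag = self.to_digraph()
        if not nx.is_directed_acyclic_graph(dag):
            cycle = nx.find_cycle(dag)
            raise StructuralError(f"IS_A graph contains a cycle: {cycle}")
        for t in self.terms:
            if t != self.root and not nx.has_path(dag, t, self.root):
                raise StructuralError(f"term {t!r} does not reach root {self.root!r}")

    def to_digraph(self) -> nx.DiGraph:
        """child -> parent digraph over all terms."""
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        g.add_edges_from(self.isa_edges)
        return g

    def parents(self, term: str) -> set[str]:
        return {p for c, p in self.isa_edges if c == term}


@dataclass
class TermMapping:
    """Disease id (MeSH-style label) -> ontology term id.

    Injective on the diseases actually scored; diseases present in the gene
    table but absent here are recorded by callers, never silently dropped.
    """

    pairs: dict[str, str]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for disease, term in self.pairs.items():
            if term in seen:
                raise ValueError(
                    f"mapping not injective: {disease!r} and {seen[term]!r} "
                    f"both map to {term!r}"
                )
            seen[term] = disease

    def term(self, disease: str) -> str | None:
        return self.pairs.get(disease)


@dataclass
class SimilarityMatrix:
    """Symmetric disease × disease matrix for one similarity measure.

    ``values`` may contain NaN for pairs whose score is undefined (e.g. a
    degenerate network-similarity correlation); such pairs are excluded from
    downstream ranking rather than imputed.
    """

    diseases: list[str]
    values: np.ndarray
    tag: str

    def __post_init__(self) -> None:
        if self.tag not in MEASURE_TAGS:
            raise ValueError(f"unknown measure tag {self.tag!r}")
        v = np.asarray(self.values, dtype=float)
        n = len(self.diseases)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} != ({n},{n})")
        asym = np.nanmax(np.abs(v - v.T)) if n else 0.0
        if asym > SYMMETRY_TOL:
            raise ValueError(f"matrix asymmetric beyond tolerance: {asym:g}")
        self.values = v

    def loc(self, d1: str, d2: str) -> float:
        i, j = self.diseases.index(d1), self.diseases.index(d2)
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.diseases, columns=self.diseases)

    def is_complete(self) -> bool:
        return not np.isnan(self.values).any()


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_disease_gene_table(path: str | Path, fmt: str = "tsv") -> DiseaseGeneMap:
    """Read a disease -> gene association table.

    Parameters
    ----------
    path:
        Input file.
    fmt:
        ``"tsv"`` — one ``disease<TAB>gene`` pair per line;
        ``"gmt"`` — one disease per line: ``disease<TAB>description<TAB>gene...``
        (the GMT gene-set convention; the description field may be empty).

    Duplicate (disease, gene) rows are collapsed and symbols uppercased.
    """
    path = Path(path)
    raw: dict[str, set[str]] = {}
    lines = path.read_text().splitlines()
    if not any(line.strip() for line in lines):
        raise ParseError(f"{path}: empty input file")
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if fmt == "tsv":
            if len(fields) != 2 or not fields[0].strip() or not fields[1].strip():
                raise ParseError(f"{path}:{lineno}: malformed disease-gene row: {line!r}")
            disease, genes = fields[0].strip(), [fields[1]]
        elif fmt == "gmt":
            if len(fields) < 3 or not fields[0].strip():
                raise ParseError(f"{path}:{lineno}: malformed GMT record: {line!r}")
            disease, genes = fields[0].strip(), [g for g in fields[2:] if g.strip()]
            if not genes:
                raise ParseError(f"{path}:{lineno}: GMT record lists no genes")
        else:
            raise ValueError(f"unknown format {fmt!r}")
        raw.setdefault(disease, set()).update(normalize_gene(g) for g in genes)
    return DiseaseGeneMap({d: frozenset(gs) for d, gs in raw.items()})


def read_edge_list(
    path: str | Path, weighted: bool = False
) -> InteractionNetwork | WeightedFunctionalNetwork:
    """Read an undirected TSV edge list.

    Two columns per row for an unweighted PPI network, three (the third a
    numeric LLS weight) for a functional network.  Reversed duplicate rows
    are merged; self-loop rows are skipped with a logged warning (PPI dumps
    commonly contain them and they carry no information for any similarity
    measure here).  For duplicate weighted edges the last weight wins.
    """
    path = Path(path)
    want = 3 if weighted else 2
    pairs: list[tuple[str, str]] = []
    triples: list[tuple[str, str, float]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != want or any(not f.strip() for f in fields[:2]):
            raise ParseError(
                f"{path}:{lineno}: expected {want} columns, got {len(fields)}: {line!r}"
            )
        a, b = normalize_gene(fields[0]), normalize_gene(fields[1])
        if a == b:
            logger.warning("%s:%d: skipping self-loop edge (%s,%s)", path, lineno, a, b)
            continue
        if weighted:
            try:
                w = float(fields[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: non-numeric weight {fields[2]!r}"
                ) from exc
            triples.append((a, b, w))
        else:
            pairs.append((a, b))
    if weighted:
        return WeightedFunctionalNetwork.from_edges(triples)
    return InteractionNetwork.from_edges(pairs)


def read_obo(
    path: str | Path,
    annotations: Mapping[str, Iterable[str]] | None = None,
    root: str | None = None,
) -> OntologyGraph:
    """Read an OBO 1.2 ontology, keeping IS_A relationships only.

    Obsolete terms are excluded.  The root is detected as the unique term
    with no parent; if the parentless term is not unique, pass ``root``
    explicitly.  ``annotations`` attaches direct term -> gene annotations
    (gene symbols are normalised); they may also be attached later.
    """
    path = Path(path)
    graph = obonet.read_obo(str(path))  # skips obsolete terms, child->parent edges
    terms = set(graph.nodes)
    isa = {
        (child, parent)
        for child, parent, key in graph.edges(keys=True)
        if key == "is_a" and child in terms and parent in terms
    }
    isa_dag = nx.DiGraph()
    isa_dag.add_nodes_from(terms)
    isa_dag.add_edges_from(isa)
    if not nx.is_directed_acyclic_graph(isa_dag):
        cycle = nx.find_cycle(isa_dag)
        raise StructuralError(f"{path}: IS_A cycle detected: {cycle}")
    if root is None:
        roots = [t for t in terms if isa_dag.out_degree(t) == 0]
        if len(roots) != 1:
            raise StructuralError(
                f"{path}: root not unique ({sorted(roots)[:5]}); supply root explicitly"
            )
        root = roots[0]
    direct: dict[str, frozenset[str]] = {}
    if annotations:
        for term, genes in annotations.items():
            if term in terms:
                direct[term] = frozenset(normalize_gene(g) for g in genes)
    return OntologyGraph(
        terms=frozenset(terms),
        isa_edges=frozenset(isa),
        direct_annotations=direct,
        root=root,
    )


def read_annotation_table(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a two-column ``term<TAB>gene`` annotation table."""
    path = Path(path)
    raw: dict[str, set[str]] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 2 or not fields[0].strip() or not fields[1].strip():
            raise ParseError(f"{path}:{lineno}: malformed annotation row: {line!r}")
        raw.setdefault(fields[0].strip(), set()).add(normalize_gene(fields[1]))
    return {t: frozenset(gs) for t, gs in raw.items()}


def read_term_mapping(path: str | Path) -> TermMapping:
    """Read a two-column ``disease<TAB>ontology-term`` mapping table."""
    path = Path(path)
    pairs: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 2 or not fields[0].strip() or not fields[1].strip():
            raise ParseError(f"{path}:{lineno}: malformed mapping row: {line!r}")
        pairs[fields[0].strip()] = fields[1].strip()
    return TermMapping(pairs)


def read_similarity_matrix(path: str | Path, tag: str) -> SimilarityMatrix:
    """Read a square TSV similarity matrix written by `write_similarity_matrix`."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    if list(frame.index) != list(frame.columns):
        raise ParseError(f"{path}: row and column labels differ")
    return SimilarityMatrix(list(frame.index), frame.to_numpy(dtype=float), tag)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_similarity_matrix(m: SimilarityMatrix, path: str | Path) -> None:
    """Write a square TSV with disease-id header row/column, full precision.

    Values are written with enough significant digits (repr precision) to
    round-trip through `read_similarity_matrix` within 1e-9.  Refuses to
    write a matrix whose asymmetry exceeds the tolerance (re-checked here in
    case values were mutated after construction).
    """
    asym = np.nanmax(np.abs(m.values - m.values.T)) if len(m.diseases) else 0.0
    if asym > SYMMETRY_TOL:
        raise ValueError(f"refusing to write asymmetric matrix (max asym {asym:g})")
    frame = m.to_frame()
    frame.to_csv(path, sep="\t", float_format="%.12g", index_label="disease")


def write_disease_gene_table(dmap: DiseaseGeneMap, path: str | Path) -> None:
    """Write a disease–gene map as a two-column TSV (sorted, deterministic)."""
    with open(path, "w") as fh:
        for disease in dmap.diseases:
            for gene in sorted(dmap.genes(disease)):
                fh.write(f"{disease}\t{gene}\n")


def write_edge_list(
    net: InteractionNetwork | WeightedFunctionalNetwork, path: str | Path
) -> None:
    """Write a network as a TSV edge list (2 or 3 columns, sorted)."""
    with open(path, "w") as fh:
        if isinstance(net, WeightedFunctionalNetwork):
            for (a, b), w in sorted(net.edges.items()):
                fh.write(f"{a}\t{b}\t{w:.12g}\n")
        else:
            for a, b in sorted(net.edges):
                fh.write(f"{a}\t{b}\n")


def write_obo(onto: OntologyGraph, path: str | Path) -> None:
    """Write an ontology as minimal OBO 1.2 (id/name/is_a stanzas)."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: disease-ontology\n")
        for term in sorted(onto.terms):
            fh.write(f"\n[Term]\nid: {term}\nname: {term}\n")
            for parent in sorted(onto.parents(term)):
                fh.write(f"is_a: {parent}\n")


def write_annotation_table(
    annotations: Mapping[str, frozenset[str]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for term in sorted(annotations):
            for gene in sorted(annotations[term]):
                fh.write(f"{term}\t{gene}\n")


def write_term_mapping(mapping: TermMapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        for disease in sorted(mapping.pairs):
            fh.write(f"{disease}\t{mapping.pairs[disease]}\n")
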