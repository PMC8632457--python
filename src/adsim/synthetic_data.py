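"""Synthetic input bundle with planted disease-cluster structure.

The generator emulates the five external inputs of the pipeline at desk
scale: a scale-free PPI network (preferential attachment), an LLS-weighted
functional network, a rooted tree-shaped disease ontology with gene
annotations, a disease -> ontology-term mapping, and a disease–gene map
with planted clusters of similar diseases.

The cluster signal is injected in all three measurement channels, because
candidate selection requires agreement of all three:

* shared genes — each planted cluster owns a disjoint gene pool and its
  member diseases draw ``ceil(within_cluster_share * genes_per_disease)``
  genes from that pool (network + shared-gene signal);
* functional edge density — gene pairs inside a cluster pool are linked
  with probability ``func_edge_prob_within``, all other pairs with the much
  smaller ``func_edge_prob_between`` (functional signal);
* ontology placement — cluster members are annotated to distinct leaves of
  a common depth-1 subtree of the balanced ontology tree (semantic signal).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .data_io import (
    DiseaseGeneMap,
    InteractionNetwork,
    OntologyGraph,
    TermMapping,
    WeightedFunctionalNetwork,
    read_annotation_table,
    read_disease_gene_table,
    read_edge_list,
    read_obo,
    read_term_mapping,
    write_annotation_table,
    write_disease_gene_table,
    write_edge_list,
    write_obo,
    write_term_mapping,
)


class ConfigError(ValueError):
    """Invalid synthetic-bundle configuration."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; the defaults define the benchmark conditions.

    Diseases are assigned to planted clusters round-robin (disease ``i``
    belongs to cluster ``i mod n_planted_clusters``), so ``n_diseases`` need
    not be divisible by ``n_planted_clusters``.
    """

    n_genes: int = 500
    ppi_attach: int = 3
    n_diseases: int = 12
    n_planted_clusters: int = 3
    genes_per_disease: int = 15
    within_cluster_share: float = 0.8
    lls_range: tuple[float, float] = (1.0, 4.0)
    func_edge_prob_within: float = 0.4
    func_edge_prob_between: float = 0.005
    ontology_depth: int = 4
    ontology_branching: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.within_cluster_share <= 1.0:
            raise ConfigError("within_cluster_share must lie in [0,1]")
        for p in (self.func_edge_prob_within, self.func_edge_prob_between):
            if not 0.0 <= p <= 1.0:
                raise ConfigError("edge probabilities must lie in [0,1]")
        if self.lls_range[0] >= self.lls_range[1]:
            raise ConfigError("lls_range low must be < high")
        if self.genes_per_disease > self.n_genes:
            raise ConfigError("genes_per_disease exceeds n_genes")
        if self.n_planted_clusters < 1 or self.n_diseases < self.n_planted_clusters:
            raise ConfigError("need 1 <= n_planted_clusters <= n_diseases")
        if self.n_planted_clusters * self.genes_per_disease > self.n_genes:
            raise ConfigError("cluster gene pools do not fit into the gene universe")
        if self.n_planted_clusters > self.ontology_branching:
            raise ConfigError(
                "each planted cluster needs its own depth-1 ontology subtree: "
                "n_planted_clusters must be <= ontology_branching"
            )
        members = math.ceil(self.n_diseases / self.n_planted_clusters)
        leaves_per_subtree = self.ontology_branching ** (self.ontology_depth - 1)
        if members > leaves_per_subtree:
            raise ConfigError("not enough ontology leaves per subtree for cluster members")


@dataclass
class SyntheticBundle:
    """A complete, internally consistent input bundle plus ground truth."""

    ppi: InteractionNetwork
    func: WeightedFunctionalNetwork
    ontology: OntologyGraph
    mapping: TermMapping
    diseases: DiseaseGeneMap
    truth: dict[str, int]
    config: SyntheticConfig | None = None
    cluster_pools: dict[int, frozenset[str]] = field(default_factory=dict)


def _gene_names(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n)]


def _disease_names(n: int) -> list[str]:
    return [f"DIS{i:02d}" for i in range(n)]


def _balanced_ontology_terms(
    branching: int, depth: int
) -> tuple[str, list[tuple[str, str]], list[list[str]]]:
    """Balanced tree as (root, child->parent edges, leaves grouped by depth-1 subtree)."""
    root = "T:R"
    edges: list[tuple[str, str]] = []
    subtree_leaves: list[list[str]] = []
    for s in range(branching):
        top = f"T:R.{s}"
        edges.append((top, root))
        level = [top]
        for _ in range(depth - 1):
            nxt = []
            for parent in level:
                for c in range(branching):
                    child = f"{parent}.{c}"
                    edges.append((child, parent))
                    nxt.append(child)
            level = nxt
        subtree_leaves.append(level)
    return root, edges, subtree_leaves


def generate_bundle(cfg: SyntheticConfig) -> SyntheticBundle:
    """Deterministically generate a bundle from the configuration seed."""
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_names(cfg.n_genes)
    diseases = _disease_names(cfg.n_diseases)

    # scale-free PPI over the whole gene universe
    ba_seed = int(rng.integers(2**31))
    ba = nx.barabasi_albert_graph(cfg.n_genes, cfg.ppi_attach, seed=ba_seed)
    ppi = InteractionNetwork.from_edges(
        (genes[a], genes[b]) for a, b in ba.edges
    )

    # disjoint per-cluster gene pools
    pool_genes = rng.choice(
        cfg.n_genes, size=cfg.n_planted_clusters * cfg.genes_per_disease, replace=False
    )
    pools: dict[int, frozenset[str]] = {}
    pool_id = np.full(cfg.n_genes, -1, dtype=int)
    for c in range(cfg.n_planted_clusters):
        idx = pool_genes[c * cfg.genes_per_disease : (c + 1) * cfg.genes_per_disease]
        pools[c] = frozenset(genes[i] for i in idx)
        pool_id[idx] = c

    # disease gene sets: within-cluster share from the pool, rest uniform
    truth = {d: i % cfg.n_planted_clusters for i, d in enumerate(diseases)}
    n_within = math.ceil(cfg.within_cluster_share * cfg.genes_per_disease)
    entries: dict[str, frozenset[str]] = {}
    for d in diseases:
        pool = sorted(pools[truth[d]])
        chosen = {
            str(g) for g in np.array(pool)[rng.choice(len(pool), size=n_within, replace=False)]
        }
        while len(chosen) < cfg.genes_per_disease:
            g = genes[int(rng.integers(cfg.n_genes))]
            chosen.add(g)
        entries[d] = frozenset(chosen)
    dmap = DiseaseGeneMap(entries)

    # functional network: dense inside cluster pools, sparse elsewhere
    iu, ju = np.triu_indices(cfg.n_genes, k=1)
    same_pool = (pool_id[iu] >= 0) & (pool_id[iu] == pool_id[ju])
    probs = np.where(same_pool, cfg.func_edge_prob_within, cfg.func_edge_prob_between)
    keep = rng.random(len(iu)) < probs
    low, high = cfg.lls_range
    weights = rng.uniform(low, high, size=int(keep.sum()))
    func = WeightedFunctionalNetwork.from_edges(
        (genes[int(a)], genes[int(b)], float(w))
        for a, b, w in zip(iu[keep], ju[keep], weights)
    )

    # ontology: balanced tree; cluster members on leaves of a common subtree
    root, isa_edges, subtree_leaves = _balanced_ontology_terms(
        cfg.ontology_branching, cfg.ontology_depth
    )
    terms = {root} | {c for c, _ in isa_edges}
    mapping_pairs: dict[str, str] = {}
    annotations: dict[str, frozenset[str]] = {}
    next_leaf = [0] * cfg.n_planted_clusters
    for d in diseases:
        c = truth[d]
        leaf = subtree_leaves[c][next_leaf[c]]
        next_leaf[c] += 1
        mapping_pairs[d] = leaf
        annotations[leaf] = dmap.genes(d)
    ontology = OntologyGraph(
        terms=frozenset(terms),
        isa_edges=frozenset(isa_edges),
        direct_annotations=annotations,
        root=root,
    )
    return SyntheticBundle(
        ppi=ppi,
        func=func,
        ontology=ontology,
        mapping=TermMapping(mapping_pairs),
        diseases=dmap,
        truth=truth,
        config=cfg,
        cluster_pools=pools,
    )


def perturb_bundle(
    b: SyntheticBundle, gene_swap_fraction: float, seed: int
) -> SyntheticBundle:
    """Replace a fraction of each disease's genes with random PPI genes.

    Deterministic given ``seed``; the networks, ontology structure and truth
    labels are kept, and each perturbed disease's ontology annotation is
    updated to its new gene set so the bundle stays internally consistent.
    """
    if not 0.0 <= gene_swap_fraction <= 1.0:
        raise ValueError("gene_swap_fraction must lie in [0,1]")
    if gene_swap_fraction == 0.0:
        return b
    rng = np.random.default_rng(seed)
    universe = sorted(b.ppi.nodes)
    new_entries: dict[str, frozenset[str]] = {}
    for d in sorted(b.diseases.entries):
        current = sorted(b.diseases.genes(d))
        n_swap = int(round(gene_swap_fraction * len(current)))
        drop = {
            str(g)
            for g in np.array(current)[rng.choice(len(current), size=n_swap, replace=False)]
        }
        kept = set(current) - drop
        while len(kept) < len(current):
            kept.add(universe[int(rng.integers(len(universe)))])
        new_entries[d] = frozenset(kept)
    new_dmap = DiseaseGeneMap(new_entries)
    new_annotations = dict(b.ontology.direct_annotations)
    for d, term in b.mapping.pairs.items():
        if term in new_annotations:
            new_annotations[term] = new_dmap.genes(d)
    new_onto = OntologyGraph(
        terms=b.ontology.terms,
        isa_edges=b.ontology.isa_edges,
        direct_annotations=new_annotations,
        root=b.ontology.root,
    )
    return SyntheticBundle(
        ppi=b.ppi,
        func=b.func,
        ontology=new_onto,
        mapping=b.mapping,
        diseases=new_dmap,
        truth=dict(b.truth),
        config=b.config,
        cluster_pools=dict(b.cluster_pools),
    )


# ---------------------------------------------------------------------------
# Round-tripping through the on-disk formats
# ---------------------------------------------------------------------------

BUNDLE_FILES = {
    "ppi": "ppi_edges.tsv",
    "func": "functional_edges.tsv",
    "obo": "ontology.obo",
    "annotations": "term_annotations.tsv",
    "mapping": "term_mapping.tsv",
    "diseases": "disease_genes.tsv",
    "truth": "truth_labels.tsv",
}


def write_bundle(b: SyntheticBundle, directory) -> None:
    """Write the bundle in exactly the formats the readers accept."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_edge_list(b.ppi, directory / BUNDLE_FILES["ppi"])
    write_edge_list(b.func, directory / BUNDLE_FILES["func"])
    write_obo(b.ontology, directory / BUNDLE_FILES["obo"])
    write_annotation_table(
        b.ontology.direct_annotations, directory / BUNDLE_FILES["annotations"]
    )
    write_term_mapping(b.mapping, directory / BUNDLE_FILES["mapping"])
    write_disease_gene_table(b.diseases, directory / BUNDLE_FILES["diseases"])
    with open(directory / BUNDLE_FILES["truth"], "w") as fh:
        for d in sorted(b.truth):
            fh.write(f"{d}\t{b.truth[d]}\n")


def read_bundle(directory) -> SyntheticBundle:
    """Read a bundle written by :func:`write_bundle` (truth file optional)."""
    from pathlib import Path

    directory = Path(directory)
    ppi = read_edge_list(directory / BUNDLE_FILES["ppi"], weighted=False)
    func = read_edge_list(directory / BUNDLE_FILES["func"], weighted=True)
    annotations = read_annotation_table(directory / BUNDLE_FILES["annotations"])
    ontology = read_obo(directory / BUNDLE_FILES["obo"], annotations=annotations)
    mapping = read_term_mapping(directory / BUNDLE_FILES["mapping"])
    diseases = read_disease_gene_table(directory / BUNDLE_FILES["diseases"], fmt="tsv")
    truth: dict[str, int] = {}
    truth_path = directory / BUNDLE_FILES["truth"]
    if truth_path.exists():
        for line in truth_path.read_text().splitlines():
            if line.strip():
                d, label = line.split("\t")
                truth[d] = int(label)
    return SyntheticBundle(
        ppi=ppi,
        func=func,
        ontology=ontology,
        mapping=mapping,
        diseases=diseases,
        truth=truth,
    )


def default_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """The frozen benchmark configuration, optionally with field overrides."""
    return replace(SyntheticConfig(seed=seed), **overrides)
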