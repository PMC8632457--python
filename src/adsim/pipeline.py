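"""End-to-end orchestration: ingest -> three matrices -> integration ->
candidate pairs -> disease–gene network -> significant clusters.

A single :class:`PipelineConfig` (loadable from YAML) drives the whole run.
Inputs are either the five external files or a synthetic bundle generated
in-process from a seed.  All outputs are plain text with deterministic
ordering, so re-running an identical configuration reproduces byte-identical
artifacts; run metadata records every tunable setting and the SHA-256 of
each input file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import ad_network, clustering, funsim, integration, netsim, semsim
from .data_io import (
    SimilarityMatrix,
    read_annotation_table,
    read_disease_gene_table,
    read_edge_list,
    read_obo,
    read_term_mapping,
    write_similarity_matrix,
)
from .synthetic_data import SyntheticBundle, SyntheticConfig, generate_bundle

logger = logging.getLogger("adsim")


@dataclass
class PipelineConfig:
    """Full pipeline configuration.

    Either the five input paths are set, or ``synthetic`` holds a
    :class:`SyntheticConfig` and the inputs are generated in-process.
    Defaults follow the study parameters: top_k=50 candidate intersection,
    min_degree=3 relevant-gene filter, cluster_threshold=0.3.
    """

    ppi_path: str | None = None
    functional_path: str | None = None
    obo_path: str | None = None
    annotations_path: str | None = None
    mapping_path: str | None = None
    disease_genes_path: str | None = None
    disease_genes_fmt: str = "tsv"
    synthetic: SyntheticConfig | None = None

    top_k: int = 50
    min_degree: int = 3
    cluster_threshold: float = 0.3
    linkage: str = "average"
    cluster_extraction: str = "clades"
    semsim_normalize: bool = True
    ic_log_base: float | None = None  # None -> natural log
    netsim_standardize: bool = False
    clamp_negative_netsim: bool = True
    output_dir: str = "adsim_output"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        syn = raw.pop("synthetic", None)
        cfg = cls(**raw)
        if syn is not None:
            if "lls_range" in syn:
                syn["lls_range"] = tuple(syn["lls_range"])
            cfg.synthetic = SyntheticConfig(**syn)
        return cfg

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        if self.synthetic is not None:
            out["synthetic"] = dataclasses.asdict(self.synthetic)
            out["synthetic"]["lls_range"] = list(self.synthetic.lls_range)
        return out


@dataclass
class PipelineResult:
    """In-memory results of a full run (everything also written to disk)."""

    netsim: SimilarityMatrix
    funsim: SimilarityMatrix
    semsim: SimilarityMatrix
    integrated: SimilarityMatrix
    candidates: integration.CandidatePairSet
    shared_gene_table: "object"
    network: ad_network.DiseaseGeneNetwork
    relevant_genes: "object"
    dendrogram: clustering.DendrogramResult
    clusters: clustering.ClusterReport
    bundle: SyntheticBundle | None = None
    output_dir: Path | None = None
    metadata: dict = field(default_factory=dict)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_inputs(cfg: PipelineConfig):
    if cfg.synthetic is not None:
        bundle = generate_bundle(cfg.synthetic)
        return bundle, {}
    required = {
        "ppi_path": cfg.ppi_path,
        "functional_path": cfg.functional_path,
        "obo_path": cfg.obo_path,
        "annotations_path": cfg.annotations_path,
        "mapping_path": cfg.mapping_path,
        "disease_genes_path": cfg.disease_genes_path,
    }
    missing = [k for k, v in required.items() if v is None]
    if missing:
        raise ValueError(f"config lacks synthetic block and input paths: {missing}")
    checksums = {k: _sha256(Path(v)) for k, v in required.items()}
    ppi = read_edge_list(cfg.ppi_path, weighted=False)
    func = read_edge_list(cfg.functional_path, weighted=True)
    annotations = read_annotation_table(cfg.annotations_path)
    onto = read_obo(cfg.obo_path, annotations=annotations)
    mapping = read_term_mapping(cfg.mapping_path)
    dmap = read_disease_gene_table(cfg.disease_genes_path, fmt=cfg.disease_genes_fmt)
    bundle = SyntheticBundle(
        ppi=ppi, func=func, ontology=onto, mapping=mapping, diseases=dmap, truth={}
    )
    return bundle, checksums


def run_pipeline(cfg: PipelineConfig, write: bool = True) -> PipelineResult:
    """Execute every stage and (optionally) write all artifacts.

    Stage failures propagate with the stage name prefixed so a broken run
    names the stage and the offending entities.
    """
    bundle, checksums = _load_inputs(cfg)
    dmap = bundle.diseases

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    ns = stage(
        "netsim",
        netsim.netsim_matrix,
        dmap,
        bundle.ppi,
        standardize_properties=cfg.netsim_standardize,
    )
    normalized = stage("funsim", funsim.normalize_lls, bundle.func)
    fs = stage("funsim", funsim.funsim_matrix, dmap, normalized)
    annotated = stage(
        "semsim", semsim.propagate_annotations, bundle.ontology, cfg.ic_log_base
    )
    ss = stage(
        "semsim",
        semsim.semsim_matrix,
        dmap,
        bundle.mapping,
        annotated,
        normalize=cfg.semsim_normalize,
    )
    integ = stage(
        "integrate",
        integration.integrated_matrix,
        ns,
        fs,
        ss,
        clamp_negative=cfg.clamp_negative_netsim,
    )
    candidates = stage(
        "candidates",
        integration.top_k_intersection,
        integration.rank_pairs(ns),
        integration.rank_pairs(fs),
        integration.rank_pairs(ss),
        k=cfg.top_k,
    )
    shared_table = stage("candidates", integration.shared_gene_ranking, candidates, dmap)
    net = stage("network", ad_network.build_network, candidates, dmap)
    genes_table = stage(
        "network", ad_network.relevant_genes, net, min_degree=cfg.min_degree
    )
    dend = stage("cluster", clustering.hierarchical_cluster, integ, linkage=cfg.linkage)
    report = stage(
        "cluster",
        clustering.significant_clusters,
        dend,
        integ,
        threshold=cfg.cluster_threshold,
        extraction=cfg.cluster_extraction,
    )
    report = stage("cluster", clustering.cluster_shared_genes, report, dmap)

    metadata = {
        "config": cfg.to_dict(),
        "input_checksums": checksums,
        "n_diseases_scored": len(integ.diseases),
        "n_candidate_pairs": len(candidates.pairs),
        "venn": candidates.venn,
        "n_relevant_genes": int(len(genes_table)),
        "n_significant_clusters": len(report.clusters),
        "clusters": [sorted(c) for c in report.clusters],
        "cluster_shared_genes": [sorted(g) for g in report.shared_genes],
    }

    result = PipelineResult(
        netsim=ns,
        funsim=fs,
        semsim=ss,
        integrated=integ,
        candidates=candidates,
        shared_gene_table=shared_table,
        network=net,
        relevant_genes=genes_table,
        dendrogram=dend,
        clusters=report,
        bundle=bundle if cfg.synthetic is not None else None,
        metadata=metadata,
    )
    if write:
        result.output_dir = _write_outputs(cfg, result)
    return result


def _write_outputs(cfg: PipelineConfig, res: PipelineResult) -> Path:
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    for m in (res.netsim, res.funsim, res.semsim, res.integrated):
        write_similarity_matrix(m, out / f"{m.tag}.tsv")
    res.shared_gene_table.to_csv(out / "candidate_pairs.tsv", sep="\t", index=False)
    integration.top_pairs_report(res.integrated, n_top=10).to_csv(
        out / "top_integrated_pairs.tsv", sep="\t", index=False, float_format="%.9f"
    )
    with open(out / "venn_counts.json", "w") as fh:
        json.dump(res.candidates.venn, fh, indent=2, sort_keys=True)
        fh.write("\n")
    ad_network.export_network(
        res.network, out / "network_edges.tsv", out / "network_nodes.tsv"
    )
    res.relevant_genes.to_csv(out / "relevant_genes.tsv", sep="\t", index=False)
    clustering.write_cluster_report(res.clusters, out / "clusters.tsv")
    (out / "dendrogram.nwk").write_text(res.dendrogram.to_newick() + "\n")
    with open(out / "run_metadata.json", "w") as fh:
        json.dump(res.metadata, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("pipeline outputs written to %s", out)
    return out
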