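"""Integration of the three similarity measures and candidate-pair selection.

The integrated similarity of a disease pair is the geometric mean (cube
root of the product) of its network, functional and semantic similarity:

    IntegratedSim(d1, d2) = (NetSim * FunSim * SemSim) ** (1/3)

A negative network similarity is clamped to 0 by default (a negative
"similarity" has no meaning for the downstream threshold and clustering
logic; clamping is monotone).  Candidate pairs are selected as the
intersection of the top-k pairs under each of the three measures
(k defaults to 50) and then ranked by their number of shared genes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import DiseaseGeneMap, SimilarityMatrix

Pair = tuple[str, str]


def _pair_key(d1: str, d2: str) -> Pair:
    return (d1, d2) if d1 <= d2 else (d2, d1)


@dataclass
class RankedPairList:
    """Unordered disease pairs sorted by descending score.

    Ties are broken lexicographically by the pair's sorted disease ids so
    the ranking is deterministic.
    """

    pairs: list[tuple[str, str, float]]
    tag: str

    def top(self, k: int) -> set[Pair]:
        if k > len(self.pairs):
            raise ValueError(f"k={k} exceeds list length {len(self.pairs)}")
        return {(a, b) for a, b, _ in self.pairs[:k]}


@dataclass
class CandidatePairSet:
    """Pairs present in the top-k of all three measures, plus Venn counts."""

    pairs: set[Pair]
    venn: dict[str, int] = field(default_factory=dict)
    k: int = 0


def integrated_similarity(
    ns: float, fs: float, ss: float, clamp_negative: bool = True
) -> float:
    """Cube root of the product of the three similarity components.

    NaN in any component propagates (the pair is undefined and excluded
    downstream).  With ``clamp_negative`` (default) a negative network
    similarity yields 0; otherwise the real (signed) cube root is returned.
    """
    if math.isnan(ns) or math.isnan(fs) or math.isnan(ss):
        return math.nan
    if clamp_negative and ns < 0:
        ns = 0.0
    product = ns * fs * ss
    return math.copysign(abs(product) ** (1.0 / 3.0), product)


def rank_pairs(m: SimilarityMatrix) -> RankedPairList:
    """Sort all defined off-diagonal pairs by descending score."""
    entries: list[tuple[str, str, float]] = []
    n = len(m.diseases)
    for i, j in itertools.combinations(range(n), 2):
        v = m.values[i, j]
        if not math.isnan(v):
            a, b = _pair_key(m.diseases[i], m.diseases[j])
            entries.append((a, b, float(v)))
    if not entries:
        raise ValueError("no defined off-diagonal entries to rank")
    entries.sort(key=lambda t: (-t[2], t[0], t[1]))
    return RankedPairList(entries, m.tag)


def top_k_intersection(
    netsim_list: RankedPairList,
    funsim_list: RankedPairList,
    semsim_list: RankedPairList,
    k: int = 50,
) -> CandidatePairSet:
    """Pairs in the top-k of all three rankings, with all 7 Venn region counts."""
    a = netsim_list.top(k)
    b = funsim_list.top(k)
    c = semsim_list.top(k)
    venn = {
        "netsim_only": len(a - b - c),
        "funsim_only": len(b - a - c),
        "semsim_only": len(c - a - b),
        "netsim_funsim": len((a & b) - c),
        "netsim_semsim": len((a & c) - b),
        "funsim_semsim": len((b & c) - a),
        "all_three": len(a & b & c),
    }
    return CandidatePairSet(pairs=a & b & c, venn=venn, k=k)


def shared_gene_ranking(
    pairs: CandidatePairSet | set[Pair], dmap: DiseaseGeneMap
) -> pd.DataFrame:
    """Rank candidate pairs by the size of their gene-set intersection.

    Returns a DataFrame with columns (disease_1, disease_2, n_shared_genes,
    shared_genes), sorted by descending count with lexicographic tie-break.
    """
    pair_set = pairs.pairs if isinstance(pairs, CandidatePairSet) else pairs
    rows = []
    for d1, d2 in sorted(pair_set):
        for d in (d1, d2):
            if d not in dmap.entries:
                raise KeyError(f"disease {d!r} not in disease-gene map")
        shared = dmap.genes(d1) & dmap.genes(d2)
        rows.append(
            {
                "disease_1": d1,
                "disease_2": d2,
                "n_shared_genes": len(shared),
                "shared_genes": ",".join(sorted(shared)),
            }
        )
    frame = pd.DataFrame(
        rows, columns=["disease_1", "disease_2", "n_shared_genes", "shared_genes"]
    )
    return frame.sort_values(
        by=["n_shared_genes", "disease_1", "disease_2"],
        ascending=[False, True, True],
        ignore_index=True,
    )


def integrated_matrix(
    ns: SimilarityMatrix,
    fs: SimilarityMatrix,
    ss: SimilarityMatrix,
    clamp_negative: bool = True,
) -> SimilarityMatrix:
    """Element-wise integrated similarity over the shared disease universe.

    The three matrices are aligned by disease id; diseases missing from any
    one of them raise an alignment error listing the symmetric difference.
    The diagonal is set to 1.
    """
    sets = [set(m.diseases) for m in (ns, fs, ss)]
    union = sets[0] | sets[1] | sets[2]
    inter = sets[0] & sets[1] & sets[2]
    if union != inter:
        raise ValueError(
            f"disease universes differ; not shared by all three: {sorted(union - inter)}"
        )
    diseases = sorted(inter)
    frames = [m.to_frame().loc[diseases, diseases].to_numpy() for m in (ns, fs, ss)]
    n = len(diseases)
    values = np.ones((n, n))
    for i, j in itertools.combinations(range(n), 2):
        v = integrated_similarity(
            frames[0][i, j], frames[1][i, j], frames[2][i, j], clamp_negative
        )
        values[i, j] = values[j, i] = v
    return SimilarityMatrix(diseases, values, "integrated")


def top_pairs_report(m: SimilarityMatrix, n_top: int = 10) -> pd.DataFrame:
    """Top-n pairs by score: (rank, disease_1, disease_2, score) table."""
    ranked = rank_pairs(m)
    rows = [
        {"rank": i + 1, "disease_1": a, "disease_2": b, "score": s}
        for i, (a, b, s) in enumerate(ranked.pairs[:n_top])
    ]
    return pd.DataFrame(rows, columns=["rank", "disease_1", "disease_2", "score"])
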