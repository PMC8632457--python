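"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from first principles on plain dict/set
adjacency structures — deliberately avoiding networkx/scipy graph calls and
the package's own code paths — so agreement with the package is a genuine
dual-route check.
"""

from __future__ import annotations

import itertools
import math


# -- graph topology -----------------------------------------------------------


def adjacency(edges: set[tuple[str, str]]) -> dict[str, set[str]]:
    adj: dict[str, set[str]] = {}
    for a, b in edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    return adj


def floyd_warshall(nodes: list[str], adj: dict[str, set[str]]) -> dict[tuple[str, str], float]:
    dist = {(u, v): math.inf for u in nodes for v in nodes}
    for u in nodes:
        dist[(u, u)] = 0.0
        for v in adj.get(u, ()):
            dist[(u, v)] = 1.0
    for k in nodes:
        for i in nodes:
            for j in nodes:
                if dist[(i, k)] + dist[(k, j)] < dist[(i, j)]:
                    dist[(i, j)] = dist[(i, k)] + dist[(k, j)]
    return dist


def shortest_path_counts(
    nodes: list[str], adj: dict[str, set[str]], dist: dict[tuple[str, str], float]
) -> dict[tuple[str, str], int]:
    """Number of shortest paths between every ordered pair (DP over distance)."""
    sigma: dict[tuple[str, str], int] = {}
    order = sorted(
        ((u, v) for u in nodes for v in nodes if dist[(u, v)] < math.inf),
        key=lambda p: dist[p],
    )
    for u, v in order:
        if u == v:
            sigma[(u, v)] = 1
        elif dist[(u, v)] == 1.0:
            sigma[(u, v)] = 1
        else:
            sigma[(u, v)] = sum(
                sigma[(u, w)]
                for w in adj[v]
                if dist[(u, w)] == dist[(u, v)] - 1.0
            )
    return sigma


def brute_topology(edges: set[tuple[str, str]], nodes: list[str] | None = None) -> dict[str, dict]:
    """Degree, clustering, normalised betweenness, mean path length and
    neighborhood connectivity for every node, by exhaustive enumeration."""
    adj = adjacency(edges)
    if nodes is None:
        nodes = sorted(adj)
    dist = floyd_warshall(nodes, adj)
    sigma = shortest_path_counts(nodes, adj, dist)
    out: dict[str, dict] = {}
    for v in nodes:
        neigh = adj.get(v, set())
        deg = len(neigh)
        # clustering: closed triples among neighbours
        if deg < 2:
            cc = 0.0
        else:
            links = sum(
                1 for a, b in itertools.combinations(sorted(neigh), 2) if b in adj.get(a, set())
            )
            cc = 2.0 * links / (deg * (deg - 1))
        comp = [u for u in nodes if dist[(v, u)] < math.inf]
        n = len(comp)
        # betweenness within the component, normalised by 2/((n-1)(n-2))
        bt = 0.0
        if n > 2:
            for s, t in itertools.combinations(comp, 2):
                if s == v or t == v or sigma[(s, t)] == 0:
                    continue
                if dist[(s, v)] + dist[(v, t)] == dist[(s, t)]:
                    bt += sigma[(s, v)] * sigma[(v, t)] / sigma[(s, t)]
            bt *= 2.0 / ((n - 1) * (n - 2))
        sp = (
            sum(dist[(v, u)] for u in comp if u != v) / (n - 1) if n > 1 else None
        )
        nc = sum(len(adj[u]) for u in neigh) / deg if deg else 0.0
        out[v] = {
            "degree": deg,
            "clustering": cc,
            "betweenness": bt,
            "avg_path": sp,
            "neighborhood": nc,
        }
    return out


def brute_pearson(x, y) -> float:
    """Explicit covariance / sigma formula."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    sx = math.sqrt(sum((a - mx) ** 2 for a in x) / n)
    sy = math.sqrt(sum((b - my) ** 2 for b in y) / n)
    return cov / (sx * sy)


# -- functional similarity ----------------------------------------------------


def brute_funsim_pair(g1: set[str], g2: set[str], weights: dict) -> float:
    """Literal best-match-average: materialise the full gene-level similarity
    matrix, then average the row/column maxima."""
    sim: dict[tuple[str, str], float] = {}
    for a in g1 | g2:
        for b in g1 | g2:
            if a == b:
                sim[(a, b)] = 1.0
            else:
                key = (a, b) if a <= b else (b, a)
                sim[(a, b)] = weights.get(key, 0.0)
    total = sum(max(sim[(a, b)] for b in g2) for a in g1)
    total += sum(max(sim[(b, a)] for a in g1) for b in g2)
    return total / (len(g1) + len(g2))


# -- ontology semantics -------------------------------------------------------


def brute_ancestors(term: str, parents: dict[str, set[str]]) -> set[str]:
    """Ancestor closure including the term itself, by repeated expansion."""
    anc = {term}
    frontier = {term}
    while frontier:
        nxt = set()
        for t in frontier:
            nxt |= parents.get(t, set())
        nxt -= anc
        anc |= nxt
        frontier = nxt
    return anc


def brute_depth(term: str, parents: dict[str, set[str]]) -> int:
    ps = parents.get(term, set())
    if not ps:
        return 0
    return 1 + max(brute_depth(p, parents) for p in ps)


def brute_ic(
    terms: list[str], parents: dict[str, set[str]], direct: dict[str, set[str]], base=None
) -> dict[str, float]:
    """IC from propagated counts: a term's genes are the union of the direct
    annotations of every term that has it as an ancestor."""
    propagated = {
        t: set().union(
            *(genes for s, genes in direct.items() if t in brute_ancestors(s, parents)),
            set(),
        )
        for t in terms
    }
    all_genes = set().union(*propagated.values(), set())
    out = {}
    for t, genes in propagated.items():
        if genes:
            ic = -math.log(len(genes) / len(all_genes))
            if base is not None:
                ic /= math.log(base)
            out[t] = ic
    return out


def brute_mica(
    t1: str, t2: str, parents: dict[str, set[str]], ic: dict[str, float]
) -> str:
    common = brute_ancestors(t1, parents) & brute_ancestors(t2, parents)
    candidates = [t for t in common if t in ic]
    return min(candidates, key=lambda t: (-ic[t], -brute_depth(t, parents), t))


# -- clustering ---------------------------------------------------------------


def brute_row_distance(values, i: int, j: int) -> float:
    """Coordinate-by-coordinate Euclidean sum over full similarity rows."""
    total = 0.0
    for k in range(len(values)):
        total += (values[i][k] - values[j][k]) ** 2
    return math.sqrt(total)
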