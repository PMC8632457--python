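import random
from pathlib import Path

import pytest

from adsim.synthetic_data import SyntheticConfig, generate_bundle

DATA_DIR = Path(__file__).parent / "data"
FIXTURE_SEED = 1
FIXTURE_TOP_K = 10


@pytest.fixture(scope="session")
def fixture_bundle_dir() -> Path:
    return DATA_DIR / "fixture_bundle"


@pytest.fixture(scope="session")
def fixture_expected_dir() -> Path:
    return DATA_DIR / "fixture_expected"


@pytest.fixture(scope="session")
def default_bundle():
    """The frozen benchmark bundle (generated in-process, seed 1)."""
    return generate_bundle(SyntheticConfig(seed=FIXTURE_SEED))


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """A reduced configuration for fast end-to-end tests."""
    return SyntheticConfig(
        n_genes=150,
        n_diseases=9,
        n_planted_clusters=3,
        genes_per_disease=10,
        seed=7,
    )


def random_connected_graph(rng: random.Random, max_nodes: int = 7) -> set[tuple[str, str]]:
    """Random connected labelled graph with 2..max_nodes nodes (edge set)."""
    n = rng.randint(2, max_nodes)
    nodes = [f"n{i}" for i in range(n)]
    edges: set[tuple[str, str]] = set()
    for i in range(1, n):  # random spanning tree keeps it connected
        j = rng.randrange(i)
        a, b = sorted((nodes[i], nodes[j]))
        edges.add((a, b))
    for a, b in ((x, y) for x, y in __import__("itertools").combinations(nodes, 2)):
        if rng.random() < 0.3:
            edges.add((a, b))
    return edges


def random_dag(rng: random.Random, max_terms: int = 10):
    """Random rooted DAG: (terms, child->parent map, direct annotations)."""
    n = rng.randint(2, max_terms)
    terms = [f"t{i}" for i in range(n)]
    parents: dict[str, set[str]] = {terms[0]: set()}
    for i in range(1, n):
        k = rng.randint(1, min(2, i))
        parents[terms[i]] = set(rng.sample(terms[:i], k))
    genes = [f"g{i}" for i in range(rng.randint(1, 8))]
    direct: dict[str, set[str]] = {}
    for t in terms:
        if rng.random() < 0.6:
            picked = {g for g in genes if rng.random() < 0.5}
            if picked:
                direct[t] = picked
    if not direct:  # ensure at least one annotated term
        direct[terms[-1]] = {genes[0]}
    return terms, parents, direct
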