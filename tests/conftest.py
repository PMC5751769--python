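import networkx as nx
import numpy as np
import pytest

from gfsn import FixtureSpec, SimilarityMatrix


def random_graph(rng: np.random.Generator, n_max: int = 30, p: float = 0.25) -> nx.Graph:
    """A seeded Erdos-Renyi graph with string node labels and unit weights."""
    n = int(rng.integers(4, n_max + 1))
    g = nx.fast_gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31 - 1)))
    g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in range(n)})
    nx.set_edge_attributes(g, 1.0, "weight")
    return g


def random_weighted_graph(rng: np.random.Generator, n_max: int = 30, p: float = 0.25) -> nx.Graph:
    g = random_graph(rng, n_max, p)
    for u, v in g.edges:
        g[u][v]["weight"] = float(rng.uniform(0.05, 1.0))
    return g


def random_similarity(rng: np.random.Generator, genes: list[str]) -> SimilarityMatrix:
    n = len(genes)
    vals = rng.uniform(0, 1, size=(n, n))
    vals = (vals + vals.T) / 2
    np.fill_diagonal(vals, 1.0)
    return SimilarityMatrix(genes, vals)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)


@pytest.fixture
def small_spec() -> FixtureSpec:
    return FixtureSpec(n_genes=60, seed=11)


@pytest.fixture
def path_graph() -> nx.Graph:
    g = nx.Graph()
    g.add_edge("a", "b", weight=1.0)
    g.add_edge("b", "c", weight=1.0)
    return g
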