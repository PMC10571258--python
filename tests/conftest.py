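import itertools

import numpy as np
import pytest

from speakeasy2 import Partition, WeightedGraph, preprocess_graph


def clique_edges(nodes: range, weight: float = 1.0):
    return [(i, j, weight) for i, j in itertools.combinations(nodes, 2)]


@pytest.fixture
def two_cliques():
    """Two disconnected 10-cliques; planted truth is unambiguous."""
    ids = [f"a{i}" for i in range(10)] + [f"b{i}" for i in range(10)]
    edges = clique_edges(range(10)) + clique_edges(range(10, 20))
    g = preprocess_graph(WeightedGraph.from_edges(ids, edges))
    truth = Partition(tuple(ids), np.array([0] * 10 + [1] * 10))
    return g, truth


@pytest.fixture
def two_six_cliques():
    """Two disconnected 6-cliques (the bubble/merge toy)."""
    ids = [f"v{i}" for i in range(12)]
    edges = clique_edges(range(6)) + clique_edges(range(6, 12))
    return preprocess_graph(WeightedGraph.from_edges(ids, edges))


@pytest.fixture
def butterfly():
    """Two triangles sharing node 'c2': the canonical overlap toy."""
    ids = ["c0", "c1", "c2", "c3", "c4"]
    edges = [(0, 1, 1.0), (0, 2, 1.0), (1, 2, 1.0), (2, 3, 1.0), (2, 4, 1.0), (3, 4, 1.0)]
    return WeightedGraph.from_edges(ids, edges)


@pytest.fixture
def star_graph():
    """Hub c linked to x, y, z with unit weights."""
    ids = ["c", "x", "y", "z"]
    edges = [(0, 1, 1.0), (0, 2, 1.0), (0, 3, 1.0)]
    return WeightedGraph.from_edges(ids, edges)


@pytest.fixture
def signed_blocks():
    """Two 10-node blocks, positive within, negative between."""
    rng = np.random.default_rng(7)
    n = 20
    ids = [f"s{i}" for i in range(n)]
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            same = (i < 10) == (j < 10)
            if same and rng.random() < 0.6:
                edges.append((i, j, 1.0))
            elif not same and rng.random() < 0.4:
                edges.append((i, j, -1.0))
    g = preprocess_graph(WeightedGraph.from_edges(ids, edges))
    truth = Partition(tuple(ids), np.array([0] * 10 + [1] * 10))
    return g, truth


def random_graph(rng: np.random.Generator, n: int, p: float = 0.5, weighted: bool = True):
    """Small random graph for oracle comparisons."""
    ids = [f"r{i}" for i in range(n)]
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                w = rng.uniform(0.1, 1.0) if weighted else 1.0
                edges.append((i, j, w))
    if not edges:
        edges = [(0, 1, 1.0)]
    return WeightedGraph.from_edges(ids, edges)
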