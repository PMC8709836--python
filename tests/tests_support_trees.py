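"""Shared test helper: additive distance matrices from random binary
trees, built independently of the neighbor-joining implementation."""

import itertools

import networkx as nx
import numpy as np
from skbio.stats.distance import DistanceMatrix


def random_additive_matrix(rng: np.random.Generator, n: int) -> DistanceMatrix:
    """Path-length matrix of a random binary tree with positive edges."""
    edges = {("L0", "L1"): float(rng.uniform(0.2, 1.0))}
    inner = 0
    for k in range(2, n):
        (u, v), w = list(edges.items())[int(rng.integers(0, len(edges)))]
        del edges[(u, v)]
        mid = f"I{inner}"
        inner += 1
        edges[(u, mid)] = w / 2
        edges[(mid, v)] = w / 2
        edges[(mid, f"L{k}")] = float(rng.uniform(0.1, 0.8))
    g = nx.Graph()
    for (u, v), w in edges.items():
        g.add_edge(u, v, weight=w)
    leaves = [f"L{i}" for i in range(n)]
    data = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = nx.shortest_path_length(g, leaves[i], leaves[j], weight="weight")
        data[i, j] = data[j, i] = d
    return DistanceMatrix(data, ids=leaves)
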