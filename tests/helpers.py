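"""Shared test utilities: random-network builders and independent oracles.

The oracles here deliberately avoid the package's own code paths:
exhaustive spanning-tree enumeration via Pruefer sequences, BFS
component counting through networkx, exhaustive set-partition search
for modularity, closed-form OLS via normal equations.
"""

from __future__ import annotations

import itertools

import numpy as np
import networkx as nx

from topodmn import WeightedNetwork


def random_weight_matrix(m: int, rng: np.random.Generator) -> np.ndarray:
    """Symmetric matrix with zero diagonal and off-diagonals in (0, 2)."""
    W = rng.uniform(0.05, 1.95, size=(m, m))
    W = (W + W.T) / 2
    np.fill_diagonal(W, 0.0)
    return W


def random_network(m: int, rng: np.random.Generator, scope="both") -> WeightedNetwork:
    labels = [f"n{i}" for i in range(m)]
    return WeightedNetwork(random_weight_matrix(m, rng), labels, scope=scope)


def network_from(W: np.ndarray) -> WeightedNetwork:
    W = np.asarray(W, dtype=float)
    return WeightedNetwork(W, [f"n{i}" for i in range(W.shape[0])])


def pruefer_to_edges(seq: tuple[int, ...], m: int) -> list[tuple[int, int]]:
    """Decode a Pruefer sequence into the edge list of a labeled tree."""
    degree = [1] * m
    for node in seq:
        degree[node] += 1
    edges = []
    seq = list(seq)
    for node in seq:
        leaf = min(i for i in range(m) if degree[i] == 1)
        edges.append((leaf, node))
        degree[leaf] -= 1
        degree[node] -= 1
    u, v = (i for i in range(m) if degree[i] == 1)
    edges.append((u, v))
    return edges


def exhaustive_mst_weight(W: np.ndarray) -> float:
    """Minimum total weight over every labeled spanning tree (m <= 7)."""
    m = W.shape[0]
    if m == 2:
        return float(W[0, 1])
    best = np.inf
    for seq in itertools.product(range(m), repeat=m - 2):
        total = sum(W[i, j] for i, j in pruefer_to_edges(seq, m))
        best = min(best, total)
    return float(best)


def bfs_component_count(W: np.ndarray, lam: float) -> int:
    """Components of the graph with edges of weight <= lam, via networkx BFS."""
    m = W.shape[0]
    G = nx.Graph()
    G.add_nodes_from(range(m))
    for i in range(m):
        for j in range(i + 1, m):
            if W[i, j] <= lam:
                G.add_edge(i, j)
    return nx.number_connected_components(G)


def set_partitions(items: list[int]):
    """All set partitions of *items* (Bell-number many)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partition in set_partitions(rest):
        for i in range(len(partition)):
            yield partition[:i] + [[first] + partition[i]] + partition[i + 1 :]
        yield [[first]] + partition


def exhaustive_best_modularity(S: np.ndarray) -> float:
    """Max Newman Q over every partition (m <= 8)."""
    m = S.shape[0]
    total = S.sum()
    k = S.sum(axis=1)
    best = -np.inf
    for partition in set_partitions(list(range(m))):
        q = 0.0
        for block in partition:
            idx = np.asarray(block)
            q += S[np.ix_(idx, idx)].sum() / total - (k[idx].sum() / total) ** 2
        best = max(best, q)
    return float(best)


def ols_slope_normal_equations(xs, ys) -> float:
    """OLS slope from the 2x2 normal equations, solved explicitly."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    n = xs.size
    A = np.array([[n, xs.sum()], [xs.sum(), (xs * xs).sum()]])
    b = np.array([ys.sum(), (xs * ys).sum()])
    intercept, slope = np.linalg.solve(A, b)
    return float(slope)
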