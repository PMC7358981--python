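"""Classical weighted graph-theoretic measures of the network.

Path-based measures (characteristic path length, global efficiency,
network radius) treat the dissimilarity weights directly as edge
lengths — the ``1 - r`` weight is already a distance-like quantity, so
no inverse transform is applied. Community and centrality measures
(modularity, eigenvector centrality) instead need affinities; they run
on ``s_ij = max(0, 1 - W_ij)``, i.e. the Pearson correlation with
negatives zeroed, the standard conversion for weighted functional
networks and the one that keeps the adjacency non-negative so the
Perron-Frobenius centrality vector exists.
"""

from __future__ import annotations

import numpy as np
import networkx as nx

from .connectivity import WeightedNetwork

__all__ = [
    "affinity_matrix",
    "shortest_paths",
    "characteristic_path_length",
    "global_efficiency",
    "network_radius",
    "modularity",
    "modularity_q",
    "eigenvector_centrality",
    "eigenvector_centrality_score",
]


def affinity_matrix(net: WeightedNetwork) -> np.ndarray:
    """Non-negative affinities ``max(0, 1 - W)`` with zero diagonal."""
    S = np.maximum(0.0, 1.0 - net.weights)
    np.fill_diagonal(S, 0.0)
    return S


def shortest_paths(net: WeightedNetwork) -> np.ndarray:
    """All-pairs shortest-path distances with W entries as edge lengths.

    Vectorized Floyd-Warshall on the dense matrix; a zero off-diagonal
    weight is a genuine zero-length edge, not a missing one.
    """
    W = net.weights
    if W.min() < 0:
        raise ValueError("edge lengths must be non-negative")
    D = W.copy()
    m = D.shape[0]
    for k in range(m):
        np.minimum(D, D[:, k, None] + D[None, k, :], out=D)
    return D


def characteristic_path_length(net: WeightedNetwork, D: np.ndarray | None = None) -> float:
    """Mean shortest-path length over all ordered pairs i != j."""
    if net.n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    if D is None:
        D = shortest_paths(net)
    m = D.shape[0]
    return float(D.sum() / (m * (m - 1)))


def global_efficiency(net: WeightedNetwork, D: np.ndarray | None = None) -> float:
    """Mean inverse shortest-path length over all ordered pairs i != j."""
    if net.n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    if D is None:
        D = shortest_paths(net)
    m = D.shape[0]
    off = ~np.eye(m, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = 1.0 / D[off]
    return float(inv.mean())


def network_radius(net: WeightedNetwork, D: np.ndarray | None = None) -> float:
    """Minimum nodal eccentricity; eccentricity is the largest distance
    from a node to any other node."""
    if net.n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    if D is None:
        D = shortest_paths(net)
    ecc = D.max(axis=1)
    return float(ecc.min())


def modularity_q(S: np.ndarray, labels: np.ndarray) -> float:
    """Newman modularity Q of a partition on a weighted adjacency matrix."""
    total = S.sum()
    if total == 0:
        raise ValueError("all-zero affinity matrix has no modularity")
    k = S.sum(axis=1)
    q = 0.0
    for c in np.unique(labels):
        mask = labels == c
        q += S[np.ix_(mask, mask)].sum() / total - (k[mask].sum() / total) ** 2
    return float(q)


def modularity(
    net: WeightedNetwork,
    seed: int = 0,
    n_restarts: int = 10,
    resolution: float = 1.0,
    return_partition: bool = False,
):
    """Best-of-restarts Louvain modularity on the affinity graph.

    Louvain's node sweep order is randomized, so the partition search is
    repeated ``n_restarts`` times with seeds ``seed .. seed+n_restarts-1``
    and the partition with the highest Q is kept; with a fixed *seed*
    the result is deterministic.
    """
    S = affinity_matrix(net)
    if S.sum() == 0:
        raise ValueError("all-zero affinity matrix has no modularity")
    G = nx.from_numpy_array(S)
    best_q, best_labels = -np.inf, None
    for k in range(n_restarts):
        communities = nx.community.louvain_communities(
            G, weight="weight", seed=seed + k, resolution=resolution
        )
        labels = np.empty(net.n_nodes, dtype=int)
        for c, members in enumerate(communities):
            labels[list(members)] = c
        q = modularity_q(S, labels)
        if q > best_q:
            best_q, best_labels = q, labels
    if return_partition:
        return best_q, best_labels
    return best_q


def eigenvector_centrality(
    net: WeightedNetwork, tol: float = 1e-13, max_iter: int = 10_000
) -> np.ndarray:
    """Leading-eigenvector centralities of the affinity matrix.

    Power iteration on ``S + I`` (same eigenvectors as S; the shift
    makes the Perron eigenvalue strictly dominant so the iteration
    cannot oscillate). Returned vector is non-negative with unit
    Euclidean norm.
    """
    S = affinity_matrix(net)
    m = S.shape[0]
    A = S + np.eye(m)
    v = np.full(m, 1.0 / np.sqrt(m))
    for _ in range(max_iter):
        nxt = A @ v
        nxt /= np.linalg.norm(nxt)
        if np.abs(nxt - v).max() < tol:
            return nxt
        v = nxt
    raise RuntimeError(f"power iteration did not converge in {max_iter} steps")


def eigenvector_centrality_score(net: WeightedNetwork) -> float:
    """Subject-level scalar: mean nodal eigenvector centrality."""
    return float(eigenvector_centrality(net).mean())
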