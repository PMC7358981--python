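"""Zeroth-homology graph filtration of a weighted network.

Thresholding a complete weighted graph at an increasing value ``lam``
yields a nested family of graphs. For zeroth homology the only events
are component merges, and these happen exactly at the weights of the
minimum spanning tree: the filtration values are ``0`` followed by the
m - 1 MST edge weights in ascending order, and the zeroth Betti number
(component count) steps from m down to 1 across them. The merge
sequence is identical to single-linkage agglomerative clustering.

Edge inclusion at a threshold is closed (weight <= lam), so the Betti
number drops exactly at the MST weights. Ties among MST weights are
kept as a multiset: the lambda list is non-decreasing and a tied value
merges several components at once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectivity import WeightedNetwork

__all__ = [
    "SpanningTree",
    "FiltrationProfile",
    "MergeEvent",
    "MergeDendrogram",
    "minimum_spanning_tree",
    "filtration_values",
    "betti0_at",
    "betti0_curve",
    "merge_dendrogram",
    "mean_network",
]


class _UnionFind:
    """Union-find with path compression; roots chosen as the smaller index."""

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        root = i
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[i] != root:
            self.parent[i], i = root, self.parent[i]
        return root

    def union(self, i: int, j: int) -> bool:
        ri, rj = self.find(i), self.find(j)
        if ri == rj:
            return False
        if rj < ri:
            ri, rj = rj, ri
        self.parent[rj] = ri
        return True

    def n_components(self) -> int:
        return sum(1 for i, p in enumerate(self.parent) if i == p)


@dataclass(frozen=True)
class SpanningTree:
    """An MST as a list of ``(i, j, weight)`` edges over node positions."""

    edges: tuple[tuple[int, int, float], ...]
    n_nodes: int

    @property
    def total_weight(self) -> float:
        return float(sum(w for _, _, w in self.edges))

    @property
    def weights(self) -> np.ndarray:
        return np.array(sorted(w for _, _, w in self.edges), dtype=float)


@dataclass(frozen=True)
class FiltrationProfile:
    """The (lambda, beta0) step function of a network's filtration."""

    lambdas: np.ndarray
    betti0: np.ndarray

    def __post_init__(self) -> None:
        lam = np.asarray(self.lambdas, dtype=float)
        b = np.asarray(self.betti0, dtype=int)
        if lam.shape != b.shape or lam.ndim != 1:
            raise ValueError("lambdas and betti0 must be 1-D and equal length")
        if lam[0] != 0.0:
            raise ValueError("first filtration value must be 0")
        if np.any(np.diff(lam) < 0):
            raise ValueError("filtration values must be non-decreasing")
        if np.any(np.diff(b) > 0):
            raise ValueError("betti0 must be non-increasing")
        object.__setattr__(self, "lambdas", lam)
        object.__setattr__(self, "betti0", b)


@dataclass(frozen=True)
class MergeEvent:
    lam: float
    members_a: tuple[int, ...]
    members_b: tuple[int, ...]


@dataclass(frozen=True)
class MergeDendrogram:
    """Single-linkage merge history: m - 1 events in ascending lambda order."""

    events: tuple[MergeEvent, ...]
    n_nodes: int


def _sorted_edges(W: np.ndarray) -> list[tuple[float, int, int]]:
    m = W.shape[0]
    iu, ju = np.triu_indices(m, k=1)
    edges = sorted(zip(W[iu, ju].tolist(), iu.tolist(), ju.tolist()))
    return edges


def minimum_spanning_tree(net: WeightedNetwork) -> SpanningTree:
    """Kruskal MST of the complete weighted graph.

    Ties are broken by lexicographic (i, j) node-position order, making
    the returned tree deterministic; the total weight (and hence the
    filtration) is the same for every MST regardless of tie-breaking.
    """
    m = net.n_nodes
    if m < 2:
        raise ValueError("MST requires at least 2 nodes")
    uf = _UnionFind(m)
    chosen: list[tuple[int, int, float]] = []
    for w, i, j in _sorted_edges(net.weights):
        if uf.union(i, j):
            chosen.append((i, j, w))
            if len(chosen) == m - 1:
                break
    return SpanningTree(tuple(chosen), m)


def filtration_values(tree: SpanningTree) -> np.ndarray:
    """``[0]`` followed by the MST edge weights sorted ascending (length m)."""
    return np.concatenate(([0.0], tree.weights))


def betti0_at(net: WeightedNetwork, lam: float) -> int:
    """Number of connected components at threshold *lam* (closed: w <= lam)."""
    if lam < 0:
        raise ValueError("threshold must be non-negative")
    W = net.weights
    uf = _UnionFind(net.n_nodes)
    iu, ju = np.triu_indices(net.n_nodes, k=1)
    for i, j in zip(iu[W[iu, ju] <= lam].tolist(), ju[W[iu, ju] <= lam].tolist()):
        uf.union(i, j)
    return uf.n_components()


def betti0_curve(net: WeightedNetwork) -> FiltrationProfile:
    """Evaluate beta0 at each filtration value of the MST.

    beta0 only changes at MST weights, so these m points determine the
    whole step function: beta0 starts at m (for generic all-positive
    weights) and ends at 1.
    """
    tree = minimum_spanning_tree(net)
    lams = filtration_values(tree)
    betti = np.array([betti0_at(net, lam) for lam in lams], dtype=int)
    return FiltrationProfile(lams, betti)


def merge_dendrogram(net: WeightedNetwork) -> MergeDendrogram:
    """Replay the MST construction as single-linkage merge events."""
    m = net.n_nodes
    tree = minimum_spanning_tree(net)
    members: dict[int, list[int]] = {i: [i] for i in range(m)}
    uf = _UnionFind(m)
    events = []
    for i, j, w in sorted(tree.edges, key=lambda e: (e[2], e[0], e[1])):
        ri, rj = uf.find(i), uf.find(j)
        a, b = sorted(members[ri]), sorted(members[rj])
        if b < a:
            a, b = b, a
        events.append(MergeEvent(w, tuple(a), tuple(b)))
        uf.union(i, j)
        root = uf.find(i)
        members[root] = a + b
    return MergeDendrogram(tuple(events), m)


def mean_network(nets: list[WeightedNetwork]) -> WeightedNetwork:
    """Element-wise mean of several subjects' weight matrices.

    Used to summarise a group as a single network; all inputs must share
    node labels and scope.
    """
    if not nets:
        raise ValueError("need at least one network")
    labels = nets[0].node_labels
    scope = nets[0].scope
    for net in nets[1:]:
        if net.node_labels != labels:
            raise ValueError("networks have mismatched node labels")
    W = np.mean([net.weights for net in nets], axis=0)
    return WeightedNetwork(W, labels, subject_id="group-mean", scope=scope)


def write_profile(profile: FiltrationProfile, path) -> None:
    """Export a (lambda, betti0) table as TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("lambda\tbetti0\n")
        for lam, b in zip(profile.lambdas, profile.betti0):
            fh.write(f"{float(lam)!r}\t{int(b)}\n")


def write_dendrogram(dendro: MergeDendrogram, path) -> None:
    """Export merge events as TSV: lambda, members_a, members_b."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("lambda\tmembers_a\tmembers_b\n")
        for ev in dendro.events:
            a = ",".join(map(str, ev.members_a))
            b = ",".join(map(str, ev.members_b))
            fh.write(f"{float(ev.lam)!r}\t{a}\t{b}\n")
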