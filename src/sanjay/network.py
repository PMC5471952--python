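"""Thresholded cell networks, entropy-based threshold selection, communities.

Cells become nodes of an undirected graph (a thresholded flow cytometry
network): two cells are joined when their Manhattan distance is at most a
threshold T.  Sweeping T from 0 to the data diameter moves the graph from N
isolated nodes to a clique; the selected T maximizes the Shannon entropy of a
topological summary (by default the degree distribution), giving the most
informative network.  Communities are then found by Walktrap-style random-walk
agglomeration with the merge sequence cut at maximal modularity.
"""

from __future__ import annotations

import dataclasses

import igraph as ig
import numpy as np
from scipy.spatial.distance import pdist, squareform

from .io import HDPointCloud

__all__ = [
    "TFCN",
    "CommunityPartition",
    "manhattan_distance",
    "pairwise_distances",
    "build_tfcn",
    "degree_entropy",
    "component_size_entropy",
    "select_threshold",
    "detect_communities",
]


def manhattan_distance(u, v) -> float:
    """Sum of absolute coordinate differences between two equal-length vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    return float(np.abs(u - v).sum())


def pairwise_distances(values: np.ndarray, metric: str = "manhattan") -> np.ndarray:
    """Square matrix of pairwise distances under the named metric."""
    scipy_name = {"manhattan": "cityblock", "euclidean": "euclidean"}[metric]
    return squareform(pdist(np.asarray(values, dtype=float), metric=scipy_name))


@dataclasses.dataclass(frozen=True)
class TFCN:
    """Thresholded flow cytometry network over cell indices 0..N-1."""

    n_nodes: int
    edges: np.ndarray  # (n_edges, 2) int array, u < v, no self-loops
    threshold: float
    cloud: HDPointCloud | None = None

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        if len(self.edges):
            np.add.at(deg, self.edges[:, 0], 1)
            np.add.at(deg, self.edges[:, 1], 1)
        return deg

    def edge_set(self) -> set[tuple[int, int]]:
        return {(int(u), int(v)) for u, v in self.edges}

    def to_igraph(self) -> ig.Graph:
        return ig.Graph(n=self.n_nodes, edges=[tuple(e) for e in self.edges])


@dataclasses.dataclass(frozen=True)
class CommunityPartition:
    """Assignment of every node to exactly one community, ids 1..n."""

    labels: np.ndarray

    def __post_init__(self):
        labels = np.asarray(self.labels, dtype=np.int64)
        ids = np.unique(labels)
        if len(labels) == 0 or not np.array_equal(ids, np.arange(1, len(ids) + 1)):
            raise ValueError("labels must cover ids 1..n with every node labelled")
        object.__setattr__(self, "labels", labels)

    @property
    def n_communities(self) -> int:
        return int(self.labels.max())

    def members(self, community_id: int) -> np.ndarray:
        return np.flatnonzero(self.labels == community_id)


def build_tfcn(cloud: HDPointCloud, threshold: float, metric: str = "manhattan") -> TFCN:
    """Connect every pair of cells within (closed) distance ``threshold``."""
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    D = pairwise_distances(cloud.values, metric)
    iu, ju = np.triu_indices(cloud.n_cells, k=1)
    keep = D[iu, ju] <= threshold
    edges = np.column_stack([iu[keep], ju[keep]]).astype(np.int64)
    return TFCN(cloud.n_cells, edges, float(threshold), cloud)


def _distribution_entropy(values: np.ndarray) -> float:
    _, counts = np.unique(values, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def degree_entropy(net: TFCN) -> float:
    """Shannon entropy (nats) of the empirical degree distribution.

    Zero iff all nodes share one degree (clique, empty graph, any
    degree-regular graph).
    """
    return _distribution_entropy(net.degrees())


def component_size_entropy(net: TFCN) -> float:
    """Entropy of the distribution of connected-component sizes over nodes."""
    comp = net.to_igraph().connected_components()
    sizes = np.asarray(comp.sizes())
    membership_sizes = sizes[np.asarray(comp.membership)]
    return _distribution_entropy(membership_sizes)


def _candidate_grid(D: np.ndarray, n_candidates: int = 64) -> np.ndarray:
    iu, ju = np.triu_indices(D.shape[0], k=1)
    dists = np.unique(D[iu, ju])
    if len(dists) <= n_candidates:
        return dists
    qs = np.linspace(0, 1, n_candidates)
    return np.unique(np.quantile(dists, qs))


def select_threshold(
    cloud: HDPointCloud,
    candidates=None,
    metric: str = "manhattan",
    property: str = "degree",
) -> float:
    """Pick the threshold maximizing the entropy of the network's topology.

    Parameters
    ----------
    candidates : sequence of float or None
        Thresholds to scan; ``None`` uses a 64-point quantile grid of the
        distinct pairwise distances.
    property : {"degree", "components"}
        Topological summary whose distribution entropy is maximized.

    Ties are broken toward the smallest threshold.
    """
    D = pairwise_distances(cloud.values, metric)
    if candidates is None:
        candidates = _candidate_grid(D)
    candidates = np.sort(np.asarray(list(candidates), dtype=float))
    if candidates.size == 0:
        raise ValueError("candidate threshold set is empty")

    if property == "degree":
        # Vectorized sweep: degree of node i at threshold T is the count of
        # other cells within T.
        best_T, best_H = None, -1.0
        for T in candidates:
            deg = (D <= T).sum(axis=1) - 1
            H = _distribution_entropy(deg)
            if H > best_H + 1e-12:
                best_T, best_H = float(T), H
        return best_T
    if property == "components":
        best_T, best_H = None, -1.0
        for T in candidates:
            net = build_tfcn(cloud, float(T), metric)
            H = component_size_entropy(net)
            if H > best_H + 1e-12:
                best_T, best_H = float(T), H
        return best_T
    raise ValueError(f"unknown property {property!r}")


def detect_communities(net: TFCN, walk_length: int = 4, seed: int = 0) -> CommunityPartition:
    """Partition the network by random-walk (Walktrap) agglomeration.

    Short random walks get trapped in densely connected groups; nodes with
    similar walk profiles are merged agglomeratively and the merge sequence is
    cut at the modularity maximum.  Detection runs per connected component, so
    communities never straddle components and isolated nodes become
    singletons.  The procedure is deterministic (walk profiles are computed
    exactly); ``seed`` is accepted for interface uniformity.
    """
    if walk_length < 1:
        raise ValueError(f"walk_length must be >= 1, got {walk_length}")
    del seed  # deterministic: exact transition probabilities, no sampling
    g = net.to_igraph()
    labels = np.zeros(net.n_nodes, dtype=np.int64)
    next_id = 1
    for comp in g.connected_components():
        nodes = np.asarray(comp)
        sub = g.subgraph(nodes)
        if sub.ecount() == 0 or len(nodes) == 1:
            labels[nodes] = next_id
            next_id += 1
            continue
        clustering = sub.community_walktrap(steps=walk_length).as_clustering()
        membership = np.asarray(clustering.membership)
        for local_c in range(membership.max() + 1):
            labels[nodes[membership == local_c]] = next_id
            next_id += 1
    return CommunityPartition(labels)
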