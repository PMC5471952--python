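"""Structural representation: community centroids and k-means sub-centroids.

Each community is summarized by its centroid O_i (overall position) plus the
centroids of its k-means split into 3 parts for a 2D target (4 parts for 3D),
which preserve the community's internal geometry.  The ordered list
O_1, E_1^1..E_1^3, O_2, ... of these structural points (d = 4n of them for 2D,
5n for 3D, n = number of communities) stands in for all cells during
synthesis.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from sklearn.cluster import KMeans

from ._utils import substream_seed
from .io import HDPointCloud
from .network import CommunityPartition, pairwise_distances

__all__ = [
    "StructuralPoints",
    "DistanceMatrix",
    "centroid",
    "k_component_centroids",
    "build_structural_points",
    "pairwise_distance_matrix",
]


@dataclasses.dataclass(frozen=True)
class StructuralPoints:
    """Ordered structural points Q_1..Q_d with their roles.

    ``roles[j]`` is ``"O"`` for a community centroid and ``"E"`` for a
    component (k-means) centroid; ``community[j]`` is the 1-based community id
    each point summarizes.
    """

    points: np.ndarray  # (d, m)
    roles: tuple[str, ...]
    community: tuple[int, ...]
    n_communities: int

    @property
    def d(self) -> int:
        return self.points.shape[0]


@dataclasses.dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric, zero-diagonal pairwise distance matrix with its metric tag."""

    values: np.ndarray
    metric: str = "manhattan"

    def __post_init__(self):
        V = np.asarray(self.values, dtype=float)
        if V.ndim != 2 or V.shape[0] != V.shape[1]:
            raise ValueError(f"distance matrix must be square, got {V.shape}")
        if not np.allclose(V, V.T) or np.any(np.diag(V) != 0) or np.any(V < 0):
            raise ValueError("distance matrix must be symmetric, non-negative, zero-diagonal")
        object.__setattr__(self, "values", V)

    @property
    def d(self) -> int:
        return self.values.shape[0]


def centroid(points) -> np.ndarray:
    """Coordinate-wise arithmetic mean of a non-empty set of vectors."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[0] == 0:
        raise ValueError("centroid needs a non-empty 2D point set")
    return points.mean(axis=0)


def k_component_centroids(points, k: int, seed: int = 0) -> np.ndarray:
    """k-means cluster means of a point set, sorted lexicographically.

    When fewer than k points are available the result is padded with copies
    of the set's centroid (with a warning), keeping downstream point counts
    fixed.
    """
    points = np.asarray(points, dtype=float)
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if points.shape[0] < k:
        warnings.warn(
            f"community of {points.shape[0]} points < k={k}: padding with centroid copies",
            stacklevel=2,
        )
        pad = np.repeat(centroid(points)[None, :], k - points.shape[0], axis=0)
        out = np.vstack([points, pad])
    elif k == 1:
        out = centroid(points)[None, :]
    else:
        km = KMeans(
            n_clusters=k,
            init="k-means++",
            n_init=10,
            max_iter=300,
            random_state=seed % (2**31),
        ).fit(points)
        out = km.cluster_centers_
    order = np.lexsort(out.T[::-1])  # sort rows lexicographically
    return out[order]


def build_structural_points(
    cloud: HDPointCloud,
    partition: CommunityPartition,
    target_dim: int = 2,
    seed: int = 0,
) -> StructuralPoints:
    """Assemble O_i plus 3-centroids (2D) or 4-centroids (3D) per community."""
    if target_dim not in (2, 3):
        raise ValueError(f"target_dim must be 2 or 3, got {target_dim}")
    if len(partition.labels) != cloud.n_cells:
        raise ValueError("partition does not cover the point cloud")
    k = target_dim + 1
    rows, roles, comm = [], [], []
    for cid in range(1, partition.n_communities + 1):
        members = cloud.values[partition.members(cid)]
        rows.append(centroid(members))
        roles.append("O")
        comm.append(cid)
        sub = k_component_centroids(
            members, k, seed=substream_seed(seed, f"kmeans-c{cid}")
        )
        rows.extend(sub)
        roles.extend(["E"] * k)
        comm.extend([cid] * k)
    return StructuralPoints(
        np.asarray(rows), tuple(roles), tuple(comm), partition.n_communities
    )


def pairwise_distance_matrix(sp: StructuralPoints, metric: str = "manhattan") -> DistanceMatrix:
    """Pairwise distances between the structural points under ``metric``."""
    if sp.d < 2:
        raise ValueError("need at least two structural points")
    return DistanceMatrix(pairwise_distances(sp.points, metric), metric)
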