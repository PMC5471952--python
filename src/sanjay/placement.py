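"""Placing every cell from its distances to embedded community anchors.

A point in the plane is pinned down by its distances to three non-collinear
anchors (four non-coplanar anchors in 3D).  Each cell is therefore positioned
by multilateration against its own community's embedded component centroids:
its high-dimensional distances to those centroids (scaled onto the grid) are
matched in the low-dimensional space by solving the linearized system of
squared-distance differences in the least-squares sense — exact when the
distances are consistent, and the residual-minimizing position when the
synthesized anchors carry band-limited distortion.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.spatial.distance import cdist

from .io import HDPointCloud
from .network import CommunityPartition
from .structure import StructuralPoints
from .synthesis import GridEmbedding

__all__ = ["LowDimPointSet", "trilaterate", "project_all_points"]

_METRIC = {"manhattan": "cityblock", "euclidean": "euclidean"}


@dataclasses.dataclass(frozen=True)
class LowDimPointSet:
    """Low-dimensional coordinates with their provenance and grid scale.

    ``coords`` are in grid units; divide by ``scale`` for data units.
    """

    coords: np.ndarray  # (N, k) float
    provenance: str  # "structural" | "placed"
    scale: float = 1.0

    def __post_init__(self):
        C = np.asarray(self.coords, dtype=float)
        if C.ndim != 2 or C.shape[1] not in (2, 3) or not np.all(np.isfinite(C)):
            raise ValueError("coords must be a finite N x k array with k in {2, 3}")
        object.__setattr__(self, "coords", C)

    @property
    def data_units(self) -> np.ndarray:
        return self.coords / self.scale


def trilaterate(anchors: np.ndarray, dists: np.ndarray) -> np.ndarray:
    """Position a point in k dims from distances to k+1 (or more) anchors.

    Solves the linear system obtained by subtracting the first
    squared-distance equation from the others; least squares, exact for
    consistent inputs.  Raises on affinely dependent anchors (collinear in
    2D, coplanar in 3D) or negative distances.
    """
    anchors = np.asarray(anchors, dtype=float)
    dists = np.asarray(dists, dtype=float)
    n, k = anchors.shape
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} anchors in {k}D, got {n}")
    if np.any(dists < 0):
        raise ValueError("distances must be non-negative")
    A = 2.0 * (anchors[1:] - anchors[0])
    if np.linalg.matrix_rank(A, tol=1e-9 * max(1.0, np.abs(A).max())) < k:
        raise ValueError("anchors are affinely dependent (collinear/coplanar)")
    rhs = (
        dists[0] ** 2
        - dists[1:] ** 2
        + (anchors[1:] ** 2).sum(axis=1)
        - (anchors[0] ** 2).sum()
    )
    x, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    return x


def _solve_many(anchors: np.ndarray, dist_block: np.ndarray) -> np.ndarray:
    """Vectorized multilateration of many points against one anchor set."""
    A = 2.0 * (anchors[1:] - anchors[0])
    rhs = (
        dist_block[:, [0]] ** 2
        - dist_block[:, 1:] ** 2
        + (anchors[1:] ** 2).sum(axis=1)[None, :]
        - (anchors[0] ** 2).sum()
    )
    sol, *_ = np.linalg.lstsq(A, rhs.T, rcond=None)
    return sol.T


def project_all_points(
    cloud: HDPointCloud,
    partition: CommunityPartition,
    sp: StructuralPoints,
    ge: GridEmbedding,
    metric: str = "manhattan",
) -> LowDimPointSet:
    """Extend the structural embedding to all N cells.

    Every cell's distances to its community's component centroids are
    computed in the original space with ``metric``, scaled onto the grid, and
    multilaterated against those centroids' synthesized positions.  When the
    embedded anchors of a community are affinely dependent, the community
    centroid is added as an extra anchor; if that still fails, the cells fall
    back to the community centroid's position (with a warning).

    Note that multilateration matches *Euclidean* low-dimensional distances;
    feeding Manhattan high-dimensional distances (the default, matching the
    thresholded-network construction) is a deliberate modeling mismatch that
    is surfaced in run reports.
    """
    k = ge.coords.shape[1]
    emb = ge.coords.astype(float)
    coords = np.zeros((cloud.n_cells, k), dtype=float)
    roles = np.asarray(sp.roles)
    comm = np.asarray(sp.community)
    for cid in range(1, sp.n_communities + 1):
        members = partition.members(cid)
        e_idx = np.flatnonzero((comm == cid) & (roles == "E"))
        o_idx = np.flatnonzero((comm == cid) & (roles == "O"))
        anchors = emb[e_idx]
        anchor_high = sp.points[e_idx]
        dists = cdist(cloud.values[members], anchor_high, metric=_METRIC[metric]) * ge.scale
        try:
            coords[members] = _place_community(anchors, dists)
        except ValueError:
            anchors2 = np.vstack([anchors, emb[o_idx]])
            high2 = np.vstack([anchor_high, sp.points[o_idx]])
            dists2 = cdist(cloud.values[members], high2, metric=_METRIC[metric]) * ge.scale
            try:
                coords[members] = _place_community(anchors2, dists2)
            except ValueError:
                warnings.warn(
                    f"community {cid}: embedded anchors degenerate; placing its "
                    "cells at the community centroid's position",
                    stacklevel=2,
                )
                coords[members] = emb[o_idx[0]]
    return LowDimPointSet(coords, provenance="placed", scale=ge.scale)


def _place_community(anchors: np.ndarray, dists: np.ndarray) -> np.ndarray:
    k = anchors.shape[1]
    A = 2.0 * (anchors[1:] - anchors[0])
    if np.linalg.matrix_rank(A, tol=1e-9 * max(1.0, np.abs(A).max())) < k:
        raise ValueError("degenerate anchors")
    return _solve_many(anchors, dists)
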