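"""Synthetic flow-cytometry-like data and exhaustive synthesis oracles.

Real cytometry samples show a handful of well-separated cell populations per
channel panel; the generator emulates this with a Gaussian mixture in
channel space, clipped at zero (the instrument floor), optionally including
a rare population at a small mixture weight.  Defaults are sized to the
regime the method targets: 12 channels with population means in the
hundreds, so pairwise Manhattan distances land in the low thousands.

The brute-force oracle enumerates *every* placement of a small point set on
a tiny grid and reports the true minimum of the maximum additive distortion,
providing an independent lower bound for the synthesizer.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from ._utils import substream
from .io import HDPointCloud
from .network import pairwise_distances
from .structure import DistanceMatrix

__all__ = [
    "PopulationSpec",
    "generate_flow_like_cloud",
    "sample_benchmark_instance",
    "brute_force_min_max_distortion",
]


@dataclasses.dataclass(frozen=True)
class PopulationSpec:
    """Mixture description of the simulated cell populations.

    Parameters
    ----------
    means : (n_populations, m) array
        Population mean intensities per channel.
    spreads : (n_populations,) or (n_populations, m) array
        Per-population standard deviations (> 0).
    weights : (n_populations,) array or None
        Mixture proportions (default uniform); must sum to 1.
    rare_fraction : float or None
        If set (< 0.05), the last population's weight is forced to this
        value and the rest renormalized — a rare phenotype of the kind
        per-cell analysis is meant not to lose.
    """

    means: np.ndarray
    spreads: np.ndarray
    weights: np.ndarray | None = None
    rare_fraction: float | None = None

    def __post_init__(self):
        means = np.atleast_2d(np.asarray(self.means, dtype=float))
        n_pop, m = means.shape
        spreads = np.asarray(self.spreads, dtype=float)
        if spreads.ndim == 0:
            spreads = np.full(n_pop, float(spreads))
        if spreads.ndim == 1:
            spreads = np.repeat(spreads[:, None], m, axis=1)
        if spreads.shape != (n_pop, m) or np.any(spreads <= 0):
            raise ValueError("spreads must be positive and match the means' shape")
        if self.weights is None:
            weights = np.full(n_pop, 1.0 / n_pop)
        else:
            weights = np.asarray(self.weights, dtype=float)
        if self.rare_fraction is not None:
            if not 0 < self.rare_fraction < 0.05:
                raise ValueError("rare_fraction must be in (0, 0.05)")
            weights = weights.copy()
            weights[-1] = 0.0
            weights = weights / weights.sum() * (1 - self.rare_fraction)
            weights[-1] = self.rare_fraction
        if weights.shape != (n_pop,) or abs(weights.sum() - 1.0) > 1e-9 or np.any(weights < 0):
            raise ValueError("weights must be non-negative and sum to 1")
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "spreads", spreads)
        object.__setattr__(self, "weights", weights)

    @property
    def n_populations(self) -> int:
        return self.means.shape[0]

    @property
    def n_channels(self) -> int:
        return self.means.shape[1]


def default_spec(
    n_populations: int = 3, m: int = 12, seed: int = 0, rare_fraction: float | None = None
) -> PopulationSpec:
    """Population layout used throughout: means uniform in [200, 900] per
    channel, per-channel sd 40 — separated blobs at cytometry-like scale."""
    rng = substream(seed, "popspec")
    means = rng.uniform(200.0, 900.0, size=(n_populations, m))
    return PopulationSpec(means, np.full(n_populations, 40.0), rare_fraction=rare_fraction)


def generate_flow_like_cloud(
    n_cells: int,
    m: int | None = None,
    spec: PopulationSpec | None = None,
    seed: int = 0,
) -> tuple[HDPointCloud, np.ndarray]:
    """Draw a Gaussian-mixture point cloud clipped at zero intensity.

    Returns the cloud and the ground-truth population label of every cell
    (0-based), for recovery tests.
    """
    if spec is None:
        spec = default_spec(m=12 if m is None else m, seed=seed)
    if m is not None and m != spec.n_channels:
        raise ValueError(f"m={m} conflicts with spec's {spec.n_channels} channels")
    if n_cells < spec.n_populations:
        raise ValueError("need at least one cell per population")
    rng = substream(seed, "cells")
    labels = rng.choice(spec.n_populations, size=n_cells, p=spec.weights)
    noise = rng.standard_normal((n_cells, spec.n_channels))
    values = np.clip(spec.means[labels] + noise * spec.spreads[labels], 0.0, None)
    names = tuple(f"FL{i + 1}" for i in range(spec.n_channels))
    return HDPointCloud(values, names), labels


def sample_benchmark_instance(
    seed: int, metric: str = "manhattan"
) -> tuple[HDPointCloud, DistanceMatrix]:
    """One benchmark unit: 10 cells x 12 channels from a 3-population mixture,
    with its pairwise distance matrix."""
    spec = default_spec(n_populations=3, m=12, seed=seed)
    cloud, _ = generate_flow_like_cloud(10, spec=spec, seed=seed)
    D = DistanceMatrix(pairwise_distances(cloud.values, metric), metric)
    return cloud, D


def brute_force_min_max_distortion(
    D_int: np.ndarray, b: int, k: int = 2
) -> tuple[np.ndarray, float]:
    """Exhaustively find the grid placement minimizing max additive distortion.

    Enumerates all ``(2**(b*k))**d`` placements of the d points on the b-bit
    grid and returns an optimal configuration together with
    ``min over placements of max over pairs |dist(R_i, R_j) - D_int[i, j]|``
    (Euclidean grid distance).  A true global optimum — usable as a lower
    bound on any synthesizer's distortion — so the instance size is strictly
    capped.
    """
    D_int = np.asarray(D_int, dtype=float)
    d = D_int.shape[0]
    if k != 2 or b > 3 or d > 4 or d < 2:
        raise ValueError("oracle limited to k=2, b<=3, 2<=d<=4 (exhaustive search)")
    side = 2**b
    P = side * side
    xs, ys = np.divmod(np.arange(P), side)
    pts = np.column_stack([xs, ys]).astype(float)
    diff = pts[:, None, :] - pts[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2)).astype(np.float32)  # (P, P)

    err = None
    for i in range(d):
        for j in range(i + 1, d):
            pair = np.abs(dist - D_int[i, j])  # (P, P), rows=point i, cols=point j
            contrib = pair.reshape([P if ax in (i, j) else 1 for ax in range(d)])
            err = contrib if err is None else np.maximum(err, contrib)
    flat = np.argmin(err)
    idx = np.unravel_index(flat, err.shape)
    config = pts[list(idx)].astype(np.int64)
    # recompute the optimum in float64 (the search array is float32 for memory)
    diff = config[:, None, :] - config[None, :, :]
    dd = np.sqrt((diff.astype(np.float64) ** 2).sum(axis=2))
    iu = np.triu_indices(d, k=1)
    best = float(np.abs(dd - D_int)[iu].max())
    return config, best
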