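"""Distortion metrics, classical MDS and random-projection baselines.

Distortion of a pair under a projection is the absolute change of its
distance, ``|d(x', y') - d(x, y)|``; a projection is summarized by the
maximum and the mean of this quantity over all C(N, 2) pairs.  The two
baselines the synthesizer is compared against are Torgerson classical
scaling (eigendecomposition of the double-centered squared-distance matrix)
and Gaussian random projection (a scaled i.i.d. normal matrix, whose
expected squared-distance preservation is the Johnson-Lindenstrauss
property).

The published benchmark distortion tables (30 twelve-channel datasets,
10-point subsamples) ship with the package as CSV fixtures; their ratio
columns and headline summaries are reproduced by :func:`ratio_summary` with
ratios truncated to the printed precision.
"""

from __future__ import annotations

import dataclasses
from importlib import resources

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from ._utils import substream, truncate
from .io import HDPointCloud, RunConfig, subsample_points
from .network import pairwise_distances
from .structure import DistanceMatrix
from .synthesis import find_min_epsilon, synthesize_embedding

__all__ = [
    "DistortionReport",
    "distortion_summary",
    "classical_mds",
    "random_projection",
    "ratio_summary",
    "compare_methods",
    "load_printed_table",
]

_SCIPY_METRIC = {"manhattan": "cityblock", "euclidean": "euclidean"}


@dataclasses.dataclass(frozen=True)
class DistortionReport:
    """Per-pair distortions of one projection plus max/mean summaries."""

    pairs: np.ndarray  # columns: i, j, d_high, d_low, |d_low - d_high|
    max_distortion: float
    avg_distortion: float
    metric: str
    method: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.pairs, columns=["i", "j", "d_high", "d_low", "distortion"]
        )


def distortion_summary(
    high: HDPointCloud | np.ndarray | DistanceMatrix,
    low: np.ndarray,
    metric: str = "manhattan",
    method: str = "sanjay",
) -> DistortionReport:
    """Per-pair |d_low - d_high| with max and mean over all unordered pairs.

    ``low`` must already be in data units (grid outputs divided by their
    scale).  ``metric`` applies to the original space; projected points are
    compared with the plane's own (Euclidean) distance, matching the norm
    the synthesis constraints preserve.
    """
    if isinstance(high, HDPointCloud):
        high = high.values
    if isinstance(high, DistanceMatrix):
        n = high.d
        iu, ju = np.triu_indices(n, k=1)
        d_high = high.values[iu, ju]
    else:
        high = np.asarray(high, dtype=float)
        n = high.shape[0]
        iu, ju = np.triu_indices(n, k=1)
        d_high = pdist(high, metric=_SCIPY_METRIC[metric])
    low = np.asarray(low, dtype=float)
    if low.shape[0] != n:
        raise ValueError(f"point count mismatch: {n} high vs {low.shape[0]} low")
    if n < 2:
        raise ValueError("need at least two points")
    d_low = pdist(low, metric="euclidean")
    dist = np.abs(d_low - d_high)
    pairs = np.column_stack([iu, ju, d_high, d_low, dist])
    return DistortionReport(
        pairs, float(dist.max()), float(dist.mean()), metric, method
    )


def classical_mds(D: DistanceMatrix | np.ndarray, k: int = 2) -> np.ndarray:
    """Torgerson classical scaling of a distance matrix into k dimensions.

    Double-centers -1/2 D^2, takes the top-k non-negative eigenpairs and
    scales eigenvectors by the square roots of their eigenvalues.
    Deterministic up to sign; signs are fixed by making each axis's
    largest-magnitude loading positive.  Axes beyond the matrix's embedding
    rank come out as zeros.
    """
    Dv = D.values if isinstance(D, DistanceMatrix) else np.asarray(D, dtype=float)
    n = Dv.shape[0]
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} points for {k} dimensions")
    if Dv.max() <= 0:
        raise ValueError("distance matrix has no positive entries")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (Dv**2) @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:k]
    coords = np.zeros((n, k))
    for axis, ei in enumerate(order):
        lam = w[ei]
        if lam <= 0:
            continue  # not embeddable on this axis; leave zeros
        v = V[:, ei]
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        coords[:, axis] = np.sqrt(lam) * v
    return coords


def random_projection(
    cloud: HDPointCloud | np.ndarray, k: int = 2, seed: int = 0
) -> np.ndarray:
    """Project onto k dims with an i.i.d. N(0, 1/k) matrix (seeded).

    With entries scaled by 1/sqrt(k), squared Euclidean distances are
    preserved in expectation over the draw of the matrix.
    """
    X = cloud.values if isinstance(cloud, HDPointCloud) else np.asarray(cloud, dtype=float)
    m = X.shape[1]
    if not k < m:
        raise ValueError(f"target dimension k={k} must be below the input's {m}")
    rng = substream(seed, "rp")
    R = rng.standard_normal((m, k)) / np.sqrt(k)
    return X @ R


def ratio_summary(
    baseline: np.ndarray, sanjay: np.ndarray, decimals: int = 3, summary_decimals: int = 2
) -> dict:
    """Element-wise baseline/sanjay ratios with mean/min/max summaries.

    Per-row ratios and the summaries are truncated (not rounded) to the
    printed precisions of the published tables: 3 decimals per row, 2 for
    the summary statistics.
    """
    baseline = np.asarray(baseline, dtype=float)
    sanjay = np.asarray(sanjay, dtype=float)
    if baseline.shape != sanjay.shape:
        raise ValueError("ratio_summary needs equally long lists")
    if np.any(sanjay <= 0):
        raise ValueError("denominator values must be positive")
    ratios = np.array([truncate(r, decimals) for r in baseline / sanjay])
    return {
        "ratios": ratios,
        "mean": truncate(float(ratios.mean()), summary_decimals),
        "min": truncate(float(ratios.min()), summary_decimals),
        "max": truncate(float(ratios.max()), summary_decimals),
    }


def load_printed_table(n: int) -> pd.DataFrame:
    """Published benchmark distortion table (1-4) shipped as a CSV fixture."""
    names = {
        1: "table1_max_distortion_mds_vs_sanjay.csv",
        2: "table2_avg_distortion_mds_vs_sanjay.csv",
        3: "table3_max_distortion_rp_vs_sanjay.csv",
        4: "table4_avg_distortion_rp_vs_sanjay.csv",
    }
    if n not in names:
        raise ValueError("table number must be 1..4")
    with resources.files("sanjay.data").joinpath(names[n]).open("r") as fh:
        return pd.read_csv(fh)


def compare_methods(
    cloud: HDPointCloud,
    cfg: RunConfig | None = None,
    methods: tuple[str, ...] = ("sanjay", "mds", "rp"),
    dataset_id: int | str = 1,
) -> pd.DataFrame:
    """Max/avg distortion of each method on one subsampled dataset.

    Subsamples ``cfg.sample_size`` cells (default 10, the benchmark unit),
    runs each requested method on the same subsample, and reports one row
    per method with max/avg distortion in data units plus the
    baseline/synthesizer distortion ratio where applicable.
    """
    cfg = cfg or RunConfig()
    n = cfg.sample_size or 10
    sub = subsample_points(cloud, min(n, cloud.n_cells), cfg.seed)
    D = DistanceMatrix(pairwise_distances(sub.values, cfg.metric), cfg.metric)
    k = cfg.target_dim

    reports: dict[str, DistortionReport] = {}
    epsilons: dict[str, float] = {}
    for method in methods:
        if method == "sanjay":
            if cfg.epsilon == "auto":
                eps, emb = find_min_epsilon(D, cfg)
            else:
                emb = synthesize_embedding(D, cfg)
                eps = cfg.epsilon
            low = emb.data_units
            epsilons[method] = eps
        elif method == "mds":
            low = classical_mds(D, k)
        elif method == "rp":
            low = random_projection(sub, k, cfg.seed)
        else:
            raise ValueError(f"unknown method {method!r}")
        reports[method] = distortion_summary(D, low, cfg.metric, method)

    rows = []
    for method, rep in reports.items():
        ratio = np.nan
        if method != "sanjay" and "sanjay" in reports:
            ratio = truncate(
                rep.max_distortion / reports["sanjay"].max_distortion, 3
            )
        rows.append(
            {
                "dataset_id": dataset_id,
                "method": method,
                "max_distortion": rep.max_distortion,
                "avg_distortion": rep.avg_distortion,
                "ratio_vs_sanjay": ratio,
                "epsilon": epsilons.get(method, np.nan),
            }
        )
    return pd.DataFrame(rows)
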