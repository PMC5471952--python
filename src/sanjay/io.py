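"""Event-data containers, file reading/writing and run configuration.

The central container is :class:`HDPointCloud`: an events x channels matrix of
fluorescence intensities with channel names, read from FCS 3.0/3.1 or from
delimited text (CSV/TSV with a header row, one row per cell).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from ._utils import substream
from .fcs import read_fcs

__all__ = [
    "HDPointCloud",
    "RunConfig",
    "read_events",
    "subsample_points",
    "write_embedding",
    "read_embedding",
    "write_report",
]


@dataclasses.dataclass(frozen=True)
class HDPointCloud:
    """N cells x m channels of fluorescence intensities.

    Parameters
    ----------
    values : ndarray of shape (N, m)
        Finite intensities, one row per event, in arbitrary fluorescence units.
    channel_names : tuple of str
        One name per channel.
    """

    values: np.ndarray
    channel_names: tuple[str, ...]

    def __post_init__(self):
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 2:
            raise ValueError(f"values must be 2D, got shape {values.shape}")
        if values.shape[0] < 1 or values.shape[1] < 1:
            raise ValueError(f"need at least one event and one channel, got {values.shape}")
        if not np.all(np.isfinite(values)):
            raise ValueError("values contain non-finite entries")
        names = tuple(str(c) for c in self.channel_names)
        if len(names) != values.shape[1]:
            raise ValueError(
                f"{len(names)} channel names for {values.shape[1]} channels"
            )
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "channel_names", names)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


@dataclasses.dataclass
class RunConfig:
    """Configuration of one embedding run.

    Parameters
    ----------
    target_dim : {2, 3}
        Dimension of the synthesized embedding.
    bits : int
        Width b of the unsigned coordinates on the synthesis grid
        (coordinates live in ``[0, 2**bits - 1]``).
    block : int
        Number l of high-order bits fixed per refinement iteration; must
        divide ``bits``.
    epsilon : "auto" or float
        Multiplicative tolerance of the squared-distance band.  ``"auto"``
        searches for the smallest feasible value by bisection.
    metric : {"manhattan", "euclidean"}
        Distance used in the original space (and for distortion reporting).
    threshold : "auto" or float
        Edge threshold T of the cell network; ``"auto"`` maximizes degree
        entropy over a quantile grid of pairwise distances.
    seed : int
        Master seed; all substreams derive from it.
    solver_timeout : float
        Budget in seconds for each refinement step's decision search.
    sample_size : int or None
        If set, subsample this many cells before embedding.
    transform : callable or None
        Optional user-supplied intensity transform applied to the raw
        matrix right after reading (e.g. log/logicle); default leaves
        values raw.
    """

    target_dim: int = 2
    bits: int = 10
    block: int = 2
    epsilon: str | float = "auto"
    metric: str = "manhattan"
    threshold: str | float = "auto"
    seed: int = 0
    solver_timeout: float = 60.0
    sample_size: int | None = None
    transform: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self):
        if self.target_dim not in (2, 3):
            raise ValueError(f"target_dim must be 2 or 3, got {self.target_dim}")
        if self.bits < 2:
            raise ValueError(f"bits must be >= 2, got {self.bits}")
        if not (1 <= self.block <= self.bits) or self.bits % self.block != 0:
            raise ValueError(
                f"block must divide bits (got block={self.block}, bits={self.bits})"
            )
        if self.epsilon != "auto":
            self.epsilon = float(self.epsilon)
            if not self.epsilon > 0:
                raise ValueError("fixed epsilon must be > 0")
        if self.metric not in ("manhattan", "euclidean"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.threshold != "auto":
            self.threshold = float(self.threshold)
            if self.threshold < 0:
                raise ValueError("fixed threshold must be >= 0")


def read_events(path: str | Path, format: str | None = None) -> HDPointCloud:
    """Read cytometry events from an FCS or delimited-text file.

    Parameters
    ----------
    path : path
    format : {"fcs", "csv", "tsv"} or None
        ``None`` infers from the file suffix.

    Returns
    -------
    HDPointCloud with one row per event; channel names preserved, no rows
    silently dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {".fcs": "fcs", ".tsv": "tsv"}.get(path.suffix.lower(), "csv")
    if format == "fcs":
        values, names = read_fcs(path)
        return HDPointCloud(values, tuple(names))
    if format not in ("csv", "tsv"):
        raise ValueError(f"unknown format {format!r}")
    sep = "," if format == "csv" else "\t"
    df = pd.read_csv(path, sep=sep, header=0)
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no event rows")
    bad = df.columns[[not pd.api.types.is_numeric_dtype(t) for t in df.dtypes]]
    if len(bad):
        col = bad[0]
        row = int(pd.to_numeric(df[col], errors="coerce").isna().idxmax())
        raise ValueError(f"{path}: non-numeric value at row {row}, column {col!r}")
    return HDPointCloud(df.to_numpy(dtype=np.float64), tuple(map(str, df.columns)))


def subsample_points(cloud: HDPointCloud, n: int, seed: int) -> HDPointCloud:
    """Choose n distinct rows uniformly without replacement (seeded)."""
    if not 1 <= n <= cloud.n_cells:
        raise ValueError(f"n must be in [1, {cloud.n_cells}], got {n}")
    rng = substream(seed, "subsample")
    idx = np.sort(rng.choice(cloud.n_cells, size=n, replace=False))
    return HDPointCloud(cloud.values[idx], cloud.channel_names)


def write_embedding(
    coords: np.ndarray,
    roles: Sequence[str],
    path: str | Path,
) -> None:
    """Write a low-dimensional coordinate table as CSV (x,y[,z],role)."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] == 0:
        raise ValueError("coordinate table must be non-empty and 2D")
    k = coords.shape[1]
    cols = ["x", "y", "z"][:k]
    df = pd.DataFrame(coords, columns=cols)
    df["role"] = list(roles)
    df.to_csv(path, index=False)


def read_embedding(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Inverse of :func:`write_embedding`."""
    df = pd.read_csv(path)
    roles = df.pop("role").tolist()
    return df.to_numpy(dtype=float), roles


def write_report(report: dict, path: str | Path) -> None:
    """Write a run report (config, scale, distortions) as JSON text."""

    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        if dataclasses.is_dataclass(o):
            return {
                k: v for k, v in dataclasses.asdict(o).items() if not callable(v)
            }
        return str(o)

    Path(path).write_text(json.dumps(report, indent=2, default=_default) + "\n")
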