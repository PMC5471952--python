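"""Small shared helpers: seeded substreams and printed-precision truncation."""

from __future__ import annotations

import math
import zlib

import numpy as np

__all__ = ["substream", "substream_seed", "truncate"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a named, reproducible random substream derived from one master seed.

    All randomness in the package (subsampling, k-means, random projections,
    synthetic data) fans out from a single integer seed through named
    substreams, so one flag reproduces a whole run while the streams stay
    statistically independent of each other.
    """
    tag = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]))


def substream_seed(seed: int, name: str) -> int:
    """A plain integer seed (< 2**31) for APIs that take one (e.g. KMeans)."""
    return int(substream(seed, name).integers(2**31))


def truncate(x: float, decimals: int) -> float:
    """Truncate (not round) toward zero at the given number of decimals."""
    q = 10.0**decimals
    return math.trunc(x * q) / q
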