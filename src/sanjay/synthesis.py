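"""Grid-embedding synthesis by iterative bit-vector refinement.

The synthesizer places d points on an unsigned b-bit integer grid in k = 2 or
3 dimensions so that every pairwise squared grid distance lies within a
multiplicative band ``(1 - eps) * D^2 <= ||R_i - R_j||^2 <= (1 + eps) * D^2``
of the target distances D (scaled onto the grid).  Coordinates are built
``l`` high-order bits at a time: after fixing ``s`` bits, each point is only
known to lie in an axis-aligned sub-square of side ``2^(b-s)``, and interval
arithmetic gives the exact minimum/maximum squared distance achievable
between two such sub-squares.  Each iteration is a decision problem over the
unknown l-bit blocks: pick one block per point per axis such that every
pair's achievable-distance interval still intersects its band.  After b/l
iterations the sub-squares are single grid cells and the band holds exactly.

The per-iteration decision problem is solved by a complete backtracking
search with interval pruning (points assigned one at a time, candidate blocks
ordered by how well their sub-square midpoints fit the target distances); the
equivalent SMT-LIB 2 QF_BV encoding is available from
:func:`encode_refinement_smt2` for use with any external bit-vector solver.
"""

from __future__ import annotations

import dataclasses
import itertools
import math

import numpy as np

from .io import RunConfig
from .structure import DistanceMatrix

__all__ = [
    "SynthesisInfeasible",
    "SolverBudgetExceeded",
    "PartialGridCoordinate",
    "IntervalBound",
    "GridEmbedding",
    "scale_distances_to_grid",
    "band_thresholds",
    "subsquare_distance_bounds",
    "solve_refinement_step",
    "synthesize_embedding",
    "find_min_epsilon",
    "encode_refinement_smt2",
]


class SynthesisInfeasible(Exception):
    """No grid placement satisfies the distance band at this epsilon."""

    def __init__(self, message: str, bits_fixed: int = 0):
        super().__init__(message)
        self.bits_fixed = bits_fixed


class SolverBudgetExceeded(Exception):
    """The refinement-step search exhausted its node budget."""

    def __init__(self, message: str, bits_fixed: int = 0):
        super().__init__(message)
        self.bits_fixed = bits_fixed


@dataclasses.dataclass(frozen=True)
class PartialGridCoordinate:
    """A point whose k coordinates have ``s`` of ``b`` high-order bits fixed."""

    prefixes: tuple[int, ...]  # one prefix per axis, each < 2**s
    s: int
    b: int

    def __post_init__(self):
        if not 0 <= self.s <= self.b:
            raise ValueError(f"need 0 <= s <= b, got s={self.s}, b={self.b}")
        if any(not 0 <= p < 2**self.s for p in self.prefixes):
            raise ValueError("prefix value out of range for s bits")

    @property
    def r(self) -> int:
        return self.b - self.s

    def intervals(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array(self.prefixes, dtype=np.int64) << self.r
        return lo, lo + ((1 << self.r) - 1)


@dataclasses.dataclass(frozen=True)
class IntervalBound:
    """Min/max achievable squared distance over all free-bit completions."""

    lo: int
    hi: int

    def __post_init__(self):
        if not 0 <= self.lo <= self.hi:
            raise ValueError(f"need 0 <= lo <= hi, got {self.lo}, {self.hi}")


@dataclasses.dataclass(frozen=True)
class GridEmbedding:
    """Synthesized integer grid coordinates plus the scale back to data units.

    ``coords / scale`` recovers coordinates in the original intensity units.
    """

    coords: np.ndarray  # (d, k) int64, each in [0, 2**bits - 1]
    bits: int
    scale: float
    epsilon_used: float
    iterations: int

    @property
    def data_units(self) -> np.ndarray:
        return self.coords / self.scale


def scale_distances_to_grid(D: np.ndarray | DistanceMatrix, bits: int) -> tuple[np.ndarray, float]:
    """Map real distances onto the b-bit grid: the largest becomes 2**b - 1.

    Returns the rounded integer matrix and the scale factor (grid units per
    data unit); ``D_int / scale`` is within half a grid unit of ``D``.
    """
    if isinstance(D, DistanceMatrix):
        D = D.values
    D = np.asarray(D, dtype=float)
    if bits < 2:
        raise ValueError(f"bits must be >= 2, got {bits}")
    dmax = D.max()
    if dmax <= 0:
        raise ValueError("distance matrix has no positive entries; nothing to scale")
    scale = (2**bits - 1) / dmax
    D_int = np.round(D * scale).astype(np.int64)
    np.fill_diagonal(D_int, 0)
    return D_int, scale


def band_thresholds(D_int: np.ndarray, epsilon: float) -> tuple[np.ndarray, np.ndarray]:
    """Integer band on squared grid distances: L = ceil((1-eps)D^2), U = floor((1+eps)D^2).

    Squared grid distances are integers, so the closed real band and this
    integer band accept exactly the same placements.
    """
    D2 = D_int.astype(np.int64) ** 2
    L = np.ceil((1.0 - epsilon) * D2 - 1e-9).astype(np.int64)
    U = np.floor((1.0 + epsilon) * D2 + 1e-9).astype(np.int64)
    return np.maximum(L, 0), U


def _pair_bounds(lo_i, hi_i, lo_j, hi_j) -> tuple[np.int64, np.int64]:
    """Exact min/max squared Euclidean distance between two boxes (per-axis arrays)."""
    gap = np.maximum(0, np.maximum(lo_i - hi_j, lo_j - hi_i))
    reach = np.maximum(hi_i - lo_j, hi_j - lo_i)
    return np.int64((gap**2).sum()), np.int64((reach**2).sum())


def subsquare_distance_bounds(p: PartialGridCoordinate, q: PartialGridCoordinate) -> IntervalBound:
    """Bracket the squared distance between two partially fixed points.

    The bounds are tight: both are attained by some completion of the free
    bits, because the squared distance separates over axes and each axis
    ranges over a full integer interval.
    """
    if (p.s, p.b) != (q.s, q.b) or len(p.prefixes) != len(q.prefixes):
        raise ValueError("points must share bit-width, fixed length and dimension")
    lo, hi = _pair_bounds(*p.intervals(), *q.intervals())
    return IntervalBound(int(lo), int(hi))


def _candidate_blocks(l: int, k: int) -> np.ndarray:
    """All (2**l)**k l-bit block tuples, shape (n_candidates, k)."""
    return np.array(list(itertools.product(range(2**l), repeat=k)), dtype=np.int64)


class _Budget:
    """Shared node counter for one synthesis run."""

    __slots__ = ("nodes", "limit")

    def __init__(self, limit: int):
        self.nodes = 0
        self.limit = limit

    def tick(self, s: int) -> None:
        self.nodes += 1
        if self.nodes > self.limit:
            raise SolverBudgetExceeded(
                f"search exceeded {self.limit} nodes (at s={s})", bits_fixed=s
            )


def _continuous_seed(D_int: np.ndarray, k: int, bits: int) -> np.ndarray:
    """A continuous k-dim layout approximating the integer target distances.

    Classical (Torgerson) scaling of the target matrix followed by SMACOF
    (Guttman-transform) stress refinement, reflected so the first point sits
    in the low half of every axis and translated into the grid box.  Used
    only to order candidate blocks during the decision search — it carries
    no correctness weight, the interval constraints do.
    """
    D = D_int.astype(float)
    d = D.shape[0]
    J = np.eye(d) - np.ones((d, d)) / d
    B = -0.5 * J @ (D**2) @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:k]
    X = V[:, order] * np.sqrt(np.maximum(w[order], 0.0))
    if X.shape[1] < k:
        X = np.hstack([X, np.zeros((d, k - X.shape[1]))])
    # SMACOF iterations pull the layout toward the exact targets
    for _ in range(100):
        diff = X[:, None, :] - X[None, :, :]
        dist = np.sqrt((diff**2).sum(axis=2))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dist > 0, D / dist, 0.0)
        Bm = -ratio
        np.fill_diagonal(Bm, ratio.sum(axis=1))
        X = Bm @ X / d
    hi = 2**bits - 1
    X = X * np.where(X[0] > X.mean(axis=0), -1.0, 1.0)  # reflect point 0 low
    X = X - X.min(axis=0)
    span = X.max()
    if span > hi:  # rare: stress refinement overshoots the box
        X = X * (hi / span)
    return X


def _iter_step_models(
    prefixes: np.ndarray,
    s: int,
    b: int,
    l: int,
    L: np.ndarray,
    U: np.ndarray,
    budget: _Budget,
    literal_eq2: bool = False,
    symmetry_break: bool = True,
    seed_coords: np.ndarray | None = None,
):
    """Yield every feasible l-bit block assignment of one refinement step.

    Models are produced in a deterministic heuristic order: points are
    assigned one at a time and each point's candidate blocks are sorted by
    proximity to a continuous seed layout (when provided) or by how closely
    their sub-square midpoints realize the band-center distances to the
    already-assigned points, so the first model is already a good geometric
    fit.  Pairs with a not-yet-assigned point are pruned with their pre-step
    intervals (a necessary condition), making the enumeration complete for
    the step.
    """
    prefixes = np.asarray(prefixes, dtype=np.int64)
    d, k = prefixes.shape
    r = b - s
    if not 1 <= l <= r:
        raise ValueError(f"need 1 <= l <= remaining bits, got l={l}, r={r}")
    r_new = r - l

    # Current (pre-step) boxes for still-unassigned points.
    cur_lo = prefixes << r
    cur_hi = cur_lo + ((1 << r) - 1)
    cands = _candidate_blocks(l, k)

    def feasible(losq, hisq, li, ui):
        if literal_eq2:
            return (hisq >= li) & (hisq <= ui)
        return (hisq >= li) & (losq <= ui)

    chosen = np.zeros((d, k), dtype=np.int64)
    new_lo = np.zeros((d, k), dtype=np.int64)
    new_hi = np.zeros((d, k), dtype=np.int64)

    def extend(i):
        base = (prefixes[i] << l) | cands  # (nc, k) extended prefixes
        lo = base << r_new
        return lo, lo + ((1 << r_new) - 1)

    def order_candidates(i, lo, hi):
        mid = (lo + hi) / 2.0  # (nc, k)
        if seed_coords is not None:
            score = ((mid - seed_coords[i]) ** 2).sum(axis=1)
            return np.argsort(score, kind="stable")
        if i == 0:
            return np.arange(len(cands))
        amid = (new_lo[:i] + new_hi[:i]) / 2.0  # (i, k)
        dist = np.sqrt(((mid[:, None, :] - amid[None, :, :]) ** 2).sum(axis=2))
        target = np.sqrt((L[i, :i] + U[i, :i]) / 2.0)  # band-center distance
        denom = np.maximum(target, 1.0)
        score = (((dist - target) / denom) ** 2).sum(axis=1)
        return np.argsort(score, kind="stable")

    def dfs(i):
        if i == d:
            yield chosen.copy()
            return
        lo_all, hi_all = extend(i)
        idx = order_candidates(i, lo_all, hi_all)
        if i == 0 and s == 0 and symmetry_break and l >= 1:
            top = cands >> (l - 1)
            idx = idx[(top[idx] == 0).all(axis=1)]
        for c in idx:
            budget.tick(s)
            lo_c, hi_c = lo_all[c], hi_all[c]
            ok = True
            if i > 0:  # versus already-extended points
                gap = np.maximum(0, np.maximum(lo_c - new_hi[:i], new_lo[:i] - hi_c))
                reach = np.maximum(hi_c - new_lo[:i], new_hi[:i] - lo_c)
                ok = bool(
                    feasible((gap**2).sum(axis=1), (reach**2).sum(axis=1), L[i, :i], U[i, :i]).all()
                )
            if ok and i < d - 1:  # versus not-yet-extended points (necessary condition)
                gap = np.maximum(0, np.maximum(lo_c - cur_hi[i + 1 :], cur_lo[i + 1 :] - hi_c))
                reach = np.maximum(hi_c - cur_lo[i + 1 :], cur_hi[i + 1 :] - lo_c)
                ok = bool(
                    feasible(
                        (gap**2).sum(axis=1),
                        (reach**2).sum(axis=1),
                        L[i, i + 1 :],
                        U[i, i + 1 :],
                    ).all()
                )
            if not ok:
                continue
            chosen[i] = cands[c]
            new_lo[i], new_hi[i] = lo_c, hi_c
            yield from dfs(i + 1)

    yield from dfs(0)


def solve_refinement_step(
    prefixes: np.ndarray,
    s: int,
    b: int,
    l: int,
    L: np.ndarray,
    U: np.ndarray,
    node_budget: int = 200_000,
    literal_eq2: bool = False,
    symmetry_break: bool = True,
) -> np.ndarray | None:
    """Decide one refinement iteration: fix the next l bits of every coordinate.

    Parameters
    ----------
    prefixes : (d, k) int array of already-fixed s-bit prefixes.
    L, U : (d, d) integer band on squared grid distances.
    literal_eq2 : bool
        If True, apply both band sides to the interval *maximum* (the
        optimistic reading); default intersects the band with the whole
        achievable interval, so the final iteration degenerates to the exact
        band.
    symmetry_break : bool
        On the first iteration, restrict point 0 to the low half of every
        axis (grid reflections make this lossless).

    Returns
    -------
    (d, k) array of l-bit blocks, or None if the step is unsatisfiable.
    Raises :class:`SolverBudgetExceeded` when more than ``node_budget``
    candidate extensions are examined.
    """
    budget = _Budget(node_budget)
    return next(
        _iter_step_models(prefixes, s, b, l, L, U, budget, literal_eq2, symmetry_break),
        None,
    )


def _squared_dists(coords: np.ndarray) -> np.ndarray:
    diff = coords[:, None, :] - coords[None, :, :]
    return (diff.astype(np.int64) ** 2).sum(axis=2)


def _polish(
    coords: np.ndarray, D_int: np.ndarray, L: np.ndarray, U: np.ndarray, bits: int, max_passes: int = 60
) -> np.ndarray:
    """Band-preserving local descent on additive distortion.

    Coordinate moves over geometrically spaced step sizes are accepted only
    when every pair of the moved point stays inside the integer band and the
    (max, sum-of-squares) additive-distortion objective strictly improves,
    so the band contract of the synthesis step is never weakened.  The first
    model found by the decision search is only guaranteed to sit inside the
    band; this descent moves it toward the band's interior optimum.
    """
    coords = coords.copy()
    d, k = coords.shape
    hi_cap = 2**bits - 1
    iu = np.triu_indices(d, k=1)
    steps = [s for s in (64, 32, 16, 8, 4, 2, 1) if s <= hi_cap]

    def objective(C):
        e = np.abs(np.sqrt(_squared_dists(C)) - D_int)[iu]
        return float(e.max(initial=0.0)), float((e**2).sum())

    best = objective(coords)
    mask = ~np.eye(d, dtype=bool)
    for _ in range(max_passes):
        improved = False
        for i in range(d):
            for ax in range(k):
                for step in steps:
                    for delta in (-step, step):
                        v = coords[i, ax] + delta
                        if not 0 <= v <= hi_cap:
                            continue
                        old = coords[i, ax]
                        coords[i, ax] = v
                        sq = ((coords - coords[i]) ** 2).sum(axis=1)
                        if np.all((sq[mask[i]] >= L[i, mask[i]]) & (sq[mask[i]] <= U[i, mask[i]])):
                            cand = objective(coords)
                            if cand < best:
                                best = cand
                                improved = True
                                continue
                        coords[i, ax] = old
        if not improved:
            break
    return coords


def synthesize_embedding(
    D: DistanceMatrix | np.ndarray,
    cfg: RunConfig | None = None,
    *,
    target_dim: int | None = None,
    bits: int | None = None,
    block: int | None = None,
    epsilon: float | None = None,
    node_budget: int = 200_000,
    literal_eq2: bool = False,
    symmetry_break: bool = True,
    polish: bool = True,
) -> GridEmbedding:
    """Synthesize a full b-bit grid embedding of a distance matrix.

    Runs ``bits / block`` refinement iterations, each a complete decision
    search for the next block of bits.  On success the returned coordinates
    satisfy the multiplicative squared-distance band for ``epsilon`` exactly
    (asserted post hoc).  Raises :class:`SynthesisInfeasible` when an
    iteration is unsatisfiable and :class:`SolverBudgetExceeded` when the
    search budget runs out (both carry the number of bits fixed so far).
    """
    if cfg is not None:
        target_dim = cfg.target_dim if target_dim is None else target_dim
        bits = cfg.bits if bits is None else bits
        block = cfg.block if block is None else block
        if epsilon is None:
            if cfg.epsilon == "auto":
                raise ValueError(
                    "epsilon='auto' is resolved by find_min_epsilon; pass a number here"
                )
            epsilon = cfg.epsilon
    target_dim = 2 if target_dim is None else target_dim
    bits = 10 if bits is None else bits
    block = 2 if block is None else block
    epsilon = 0.1 if epsilon is None else float(epsilon)
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    if bits % block != 0:
        raise ValueError(f"block ({block}) must divide bits ({bits})")

    Dv = D.values if isinstance(D, DistanceMatrix) else np.asarray(D, dtype=float)
    d = Dv.shape[0]
    if d < 2:
        raise ValueError("need at least two points to embed")
    D_int, scale = scale_distances_to_grid(Dv, bits)
    L, U = band_thresholds(D_int, epsilon)

    n_steps = bits // block
    budget = _Budget(node_budget)

    # Iterative refinement with chronological backtracking across iterations:
    # each level enumerates the feasible block models of one step; when a
    # later step runs out of models the previous level advances to its next
    # model.  The search is therefore complete for the whole b-bit problem
    # (up to the node budget), not just per iteration.
    seed_coords = _continuous_seed(D_int, target_dim, bits)

    def step_iter(prefix_level, s):
        return _iter_step_models(
            prefix_level, s, bits, block, L, U, budget, literal_eq2,
            symmetry_break, seed_coords,
        )

    prefix_stack = [np.zeros((d, target_dim), dtype=np.int64)]
    iter_stack = [step_iter(prefix_stack[0], 0)]
    deepest = 0
    coords = None
    while iter_stack:
        blocks = next(iter_stack[-1], None)
        if blocks is None:
            iter_stack.pop()
            prefix_stack.pop()
            continue
        new_prefix = (prefix_stack[-1] << block) | blocks
        if len(iter_stack) == n_steps:
            coords = new_prefix
            break
        prefix_stack.append(new_prefix)
        iter_stack.append(step_iter(new_prefix, (len(prefix_stack) - 1) * block))
        deepest = max(deepest, len(prefix_stack) - 1)
    if coords is None:
        raise SynthesisInfeasible(
            f"no grid placement satisfies the band at epsilon={epsilon} "
            f"(deepest iteration reached: {deepest} of {n_steps})",
            bits_fixed=deepest * block,
        )
    if polish:
        coords = _polish(coords, D_int, L, U, bits)
    sq = _squared_dists(coords)
    off = ~np.eye(d, dtype=bool)
    if not np.all((sq[off] >= L[off]) & (sq[off] <= U[off])):
        raise AssertionError("band contract violated by synthesized embedding")
    return GridEmbedding(coords, bits, scale, epsilon, n_steps)


def find_min_epsilon(
    D: DistanceMatrix | np.ndarray,
    cfg: RunConfig | None = None,
    tol: float = 0.01,
    epsilon_max: float = 1.0,
    **kwargs,
) -> tuple[float, GridEmbedding]:
    """Smallest feasible band tolerance by bisection over (0, epsilon_max].

    Small epsilon means a tight, high-quality projection but a hard decision
    problem; large epsilon is easy but loose.  Feasibility of the constraint
    band is monotone in epsilon, so bisection applies: the search keeps the
    smallest epsilon (within ``tol``) whose synthesis succeeds and returns
    that embedding.  A step that exhausts its search budget counts as
    infeasible at that epsilon.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")

    def attempt(eps: float) -> GridEmbedding | None:
        try:
            return synthesize_embedding(D, cfg, epsilon=eps, **kwargs)
        except (SynthesisInfeasible, SolverBudgetExceeded):
            return None

    best = attempt(epsilon_max)
    if best is None:
        raise RuntimeError(
            f"synthesis infeasible even at epsilon={epsilon_max}: the distance "
            "matrix may violate the triangle inequality or the grid is too coarse"
        )
    lo, hi = 0.0, epsilon_max
    while hi - lo > tol:
        mid = (lo + hi) / 2
        emb = attempt(mid)
        if emb is not None:
            hi, best = mid, emb
        else:
            lo = mid
    return hi, best


def _bv(value: int, width: int) -> str:
    return f"(_ bv{int(value)} {width})"


def encode_refinement_smt2(
    prefixes: np.ndarray,
    s: int,
    b: int,
    l: int,
    L: np.ndarray,
    U: np.ndarray,
    literal_eq2: bool = False,
) -> str:
    """Emit one refinement iteration as an SMT-LIB 2 QF_BV query.

    The unknowns are the next l-bit block of every coordinate
    (``A_<point>_<axis>``); a model of the query is exactly a valid result of
    :func:`solve_refinement_step` (same integer thresholds, same interval
    semantics), so any conformant bit-vector solver can be used as a drop-in
    backend.
    """
    prefixes = np.asarray(prefixes, dtype=np.int64)
    d, k = prefixes.shape
    r = b - s
    r_new = r - l
    W = 2 * b + 4  # wide enough for sums of k squared b-bit differences

    lines = ["(set-logic QF_BV)"]
    for i in range(d):
        for ax in range(k):
            lines.append(f"(declare-const A_{i}_{ax} (_ BitVec {l}))")

    def ext(term: str, width: int) -> str:
        return f"((_ zero_extend {W - width}) {term})"

    def lo_term(i: int, ax: int) -> str:
        parts = []
        if s > 0:
            parts.append(_bv(int(prefixes[i, ax]), s))
        parts.append(f"A_{i}_{ax}")
        if r_new > 0:
            parts.append(_bv(0, r_new))
        core = parts[0] if len(parts) == 1 else "(concat " + " ".join(parts) + ")"
        return ext(core, b)

    offset = _bv((1 << r_new) - 1, W)
    for i in range(d):
        for j in range(i + 1, d):
            axis_min, axis_max = [], []
            for ax in range(k):
                li, lj = lo_term(i, ax), lo_term(j, ax)
                hi_ = f"(bvadd {li} {offset})"
                hj = f"(bvadd {lj} {offset})"
                gap = (
                    f"(ite (bvuge {li} {hj}) (bvsub {li} {hj}) "
                    f"(ite (bvuge {lj} {hi_}) (bvsub {lj} {hi_}) {_bv(0, W)}))"
                )
                # midpoint comparison picks which one-sided reach is larger
                reach = (
                    f"(ite (bvuge (bvadd {li} {hi_}) (bvadd {lj} {hj})) "
                    f"(bvsub {hi_} {lj}) (bvsub {hj} {li}))"
                )
                axis_min.append(f"(bvmul {gap} {gap})")
                axis_max.append(f"(bvmul {reach} {reach})")

            def total(terms):
                out = terms[0]
                for t in terms[1:]:
                    out = f"(bvadd {out} {t})"
                return out

            losq, hisq = total(axis_min), total(axis_max)
            lower = f"(bvuge {hisq} {_bv(int(L[i, j]), W)})"
            upper_arg = hisq if literal_eq2 else losq
            upper = f"(bvule {upper_arg} {_bv(int(U[i, j]), W)})"
            lines.append(f"(assert {lower})")
            lines.append(f"(assert {upper})")
    lines.append("(check-sat)")
    lines.append("(get-model)")
    return "\n".join(lines) + "\n"
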