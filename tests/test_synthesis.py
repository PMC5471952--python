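import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sanjay import (
    IntervalBound,
    PartialGridCoordinate,
    SynthesisInfeasible,
    encode_refinement_smt2,
    find_min_epsilon,
    scale_distances_to_grid,
    solve_refinement_step,
    subsquare_distance_bounds,
    synthesize_embedding,
)
from sanjay.synthesis import band_thresholds


def squared_dists(coords):
    diff = np.asarray(coords)[:, None, :] - np.asarray(coords)[None, :, :]
    return (diff**2).sum(axis=2)


class TestScaleDistances:
    def test_max_maps_to_grid_edge(self):
        D = np.array([[0.0, 100.0], [100.0, 0.0]])
        D_int, scale = scale_distances_to_grid(D, 8)
        assert scale == pytest.approx(2.55)
        assert D_int.max() == 255

    def test_identity_when_already_grid_sized(self):
        D = np.array([[0.0, 255.0], [255.0, 0.0]])
        D_int, scale = scale_distances_to_grid(D, 8)
        assert scale == 1.0
        np.testing.assert_array_equal(D_int, np.round(D))

    def test_quantization_bound(self, rng):
        pts = rng.uniform(0, 500, size=(6, 3))
        diff = pts[:, None] - pts[None]
        D = np.sqrt((diff**2).sum(axis=2))
        D_int, scale = scale_distances_to_grid(D, 10)
        assert np.all(np.abs(D_int / scale - D) <= 0.5 / scale + 1e-9)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            scale_distances_to_grid(np.zeros((3, 3)), 8)


class TestSubsquareBounds:
    def test_fully_fixed_is_exact(self):
        p = PartialGridCoordinate((1, 2), s=3, b=3)
        q = PartialGridCoordinate((4, 6), s=3, b=3)
        bound = subsquare_distance_bounds(p, q)
        assert (bound.lo, bound.hi) == (25, 25)

    def test_1d_hand_example(self):
        # b=2, r=1: prefixes 0 vs 1 span {0,1} vs {2,3}
        p = PartialGridCoordinate((0,), s=1, b=2)
        q = PartialGridCoordinate((1,), s=1, b=2)
        bound = subsquare_distance_bounds(p, q)
        assert (bound.lo, bound.hi) == (1, 9)

    @given(st.integers(0, 2**31))
    @settings(max_examples=60, deadline=None)
    def test_brackets_every_completion_exactly(self, seed):
        """lo/hi equal the enumerated min/max over all free-bit completions."""
        rng = np.random.default_rng(seed)
        b = int(rng.integers(2, 5))
        r = int(rng.integers(1, min(3, b) + 1))
        s = b - r
        k = int(rng.integers(1, 3))
        pp = tuple(int(x) for x in rng.integers(0, 2**s, size=k)) if s else (0,) * k
        qp = tuple(int(x) for x in rng.integers(0, 2**s, size=k)) if s else (0,) * k
        p = PartialGridCoordinate(pp, s=s, b=b)
        q = PartialGridCoordinate(qp, s=s, b=b)
        bound = subsquare_distance_bounds(p, q)
        free = list(itertools.product(range(2**r), repeat=k))
        vals = []
        for fp in free:
            for fq in free:
                cp = [(pp[a] << r) | fp[a] for a in range(k)]
                cq = [(qp[a] << r) | fq[a] for a in range(k)]
                vals.append(sum((x - y) ** 2 for x, y in zip(cp, cq)))
        assert bound.lo == min(vals)
        assert bound.hi == max(vals)

    def test_width_mismatch_rejected(self):
        p = PartialGridCoordinate((0,), s=1, b=2)
        q = PartialGridCoordinate((0,), s=2, b=3)
        with pytest.raises(ValueError):
            subsquare_distance_bounds(p, q)

    def test_interval_bound_ordering_enforced(self):
        with pytest.raises(ValueError):
            IntervalBound(5, 3)


class TestSolveRefinementStep:
    def test_two_free_points_always_sat(self):
        D_int = np.array([[0, 40], [40, 0]])
        L, U = band_thresholds(D_int, 0.05)
        blocks = solve_refinement_step(
            np.zeros((2, 2), dtype=np.int64), 0, 6, 2, L, U
        )
        assert blocks is not None
        assert blocks.shape == (2, 2)

    def test_equilateral_blocks_satisfy_postcondition(self):
        D_int = np.full((3, 3), 40)
        np.fill_diagonal(D_int, 0)
        L, U = band_thresholds(D_int, 0.1)
        prefixes = np.zeros((3, 2), dtype=np.int64)
        blocks = solve_refinement_step(prefixes, 0, 6, 2, L, U)
        assert blocks is not None
        new = (prefixes << 2) | blocks
        for i in range(3):
            for j in range(i + 1, 3):
                bound = subsquare_distance_bounds(
                    PartialGridCoordinate(tuple(new[i]), 2, 6),
                    PartialGridCoordinate(tuple(new[j]), 2, 6),
                )
                assert bound.hi >= L[i, j] and bound.lo <= U[i, j]


class TestSynthesizeEmbedding:
    def test_triangle_violation_is_infeasible(self):
        D = np.array([[0.0, 10, 1], [10, 0, 1], [1, 1, 0]])
        with pytest.raises(SynthesisInfeasible):
            synthesize_embedding(D, bits=4, block=1, epsilon=0.01, polish=False)

    def test_pair_within_band(self):
        D = np.array([[0.0, 50.0], [50.0, 0.0]])
        emb = synthesize_embedding(D, bits=6, block=2, epsilon=0.05)
        sq = squared_dists(emb.coords)[0, 1]
        target = emb.scale * 50.0
        assert (1 - 0.05) * target**2 <= sq + 1 and sq <= (1 + 0.05) * target**2 + 1

    def test_planar_four_points_within_band(self, rng):
        pts = rng.uniform(0, 100, size=(4, 2))
        D = np.sqrt(squared_dists(pts))
        emb = synthesize_embedding(D, bits=8, block=2, epsilon=0.1)
        D_int, _ = scale_distances_to_grid(D, 8)
        L, U = band_thresholds(D_int, 0.1)
        sq = squared_dists(emb.coords)
        off = ~np.eye(4, dtype=bool)
        assert np.all(sq[off] >= L[off]) and np.all(sq[off] <= U[off])

    def test_success_at_eps_implies_success_at_2eps(self, rng):
        pts = rng.uniform(0, 100, size=(4, 2))
        D = np.sqrt(squared_dists(pts))
        eps = 0.15
        synthesize_embedding(D, bits=6, block=2, epsilon=eps)  # must succeed
        emb = synthesize_embedding(D, bits=6, block=2, epsilon=2 * eps)
        assert emb.epsilon_used == 2 * eps

    def test_duplicated_points_colocated(self):
        D = np.array(
            [[0.0, 0.0, 60.0], [0.0, 0.0, 60.0], [60.0, 60.0, 0.0]]
        )
        emb = synthesize_embedding(D, bits=6, block=2, epsilon=0.1)
        np.testing.assert_array_equal(emb.coords[0], emb.coords[1])


class TestFindMinEpsilon:
    def test_single_pair_near_exact(self):
        D = np.array([[0.0, 77.0], [77.0, 0.0]])
        eps, emb = find_min_epsilon(D, tol=0.01, bits=8, block=2)
        assert eps <= 0.02
        realized = np.sqrt(squared_dists(emb.coords)[0, 1])
        assert abs(realized - 255) <= 2  # max distance maps to the grid edge

    def test_equilateral_close_to_quantization_floor(self):
        D = np.full((3, 3), 5.0)
        np.fill_diagonal(D, 0.0)
        eps, emb = find_min_epsilon(D, tol=0.01, bits=3, block=1)
        got = np.sqrt(squared_dists(emb.coords))
        off = ~np.eye(3, dtype=bool)
        # equilateral triangles are not exactly grid-embeddable: within ~1 unit
        assert np.abs(got[off] - 7).max() <= 1.5

    def test_returned_embedding_matches_returned_epsilon(self, rng):
        pts = rng.uniform(0, 30, size=(5, 2))
        D = np.sqrt(squared_dists(pts))
        eps, emb = find_min_epsilon(D, tol=0.02, bits=6, block=2)
        assert emb.epsilon_used == eps


class TestSMTLIBEncoding:
    def test_wellformed_and_complete(self):
        D_int = np.array([[0, 40, 30], [40, 0, 20], [30, 20, 0]])
        L, U = band_thresholds(D_int, 0.1)
        text = encode_refinement_smt2(np.zeros((3, 2), dtype=np.int64), 0, 6, 2, L, U)
        assert text.count("(") == text.count(")")
        assert text.startswith("(set-logic QF_BV)")
        assert "(check-sat)" in text
        assert text.count("declare-const") == 3 * 2
        # both band thresholds appear as bit-vector constants
        assert f"bv{L[0, 1]}" in text and f"bv{U[0, 1]}" in text

    def test_assertion_count_covers_all_pairs(self):
        d = 4
        D_int = np.full((d, d), 20)
        np.fill_diagonal(D_int, 0)
        L, U = band_thresholds(D_int, 0.2)
        text = encode_refinement_smt2(np.zeros((d, 2), dtype=np.int64), 0, 4, 2, L, U)
        assert text.count("(assert ") == 2 * d * (d - 1) // 2
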