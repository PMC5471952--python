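import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sanjay import (
    HDPointCloud,
    build_tfcn,
    degree_entropy,
    detect_communities,
    manhattan_distance,
    select_threshold,
)
from sanjay.network import TFCN, component_size_entropy, pairwise_distances


class TestManhattanDistance:
    def test_identity_is_zero(self):
        assert manhattan_distance((0, 0, 0), (0, 0, 0)) == 0

    def test_hand_example(self):
        assert manhattan_distance((1, 2), (3, 1)) == 3

    @given(st.integers(0, 2**31))
    @settings(max_examples=50, deadline=None)
    def test_matches_elementwise_recomputation(self, seed):
        rng = np.random.default_rng(seed)
        u, v = rng.uniform(-100, 100, size=(2, 12))
        expected = sum(abs(a - b) for a, b in zip(u, v))
        assert manhattan_distance(u, v) == pytest.approx(expected)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            manhattan_distance((1, 2), (1, 2, 3))


class TestBuildTFCN:
    def test_above_diameter_gives_clique(self, rng):
        cloud = HDPointCloud(rng.uniform(0, 10, (6, 3)), ("a", "b", "c"))
        diam = pairwise_distances(cloud.values).max()
        net = build_tfcn(cloud, diam + 1)
        assert net.n_edges == 6 * 5 // 2

    def test_zero_threshold_isolates_distinct_points(self):
        cloud = HDPointCloud(np.arange(8, dtype=float).reshape(4, 2), ("a", "b"))
        assert build_tfcn(cloud, 0.0).n_edges == 0

    def test_1d_example(self):
        cloud = HDPointCloud(np.array([[0.0], [1.0], [5.0]]), ("x",))
        net = build_tfcn(cloud, 2.0)
        assert net.edge_set() == {(0, 1)}

    def test_closed_inequality(self):
        cloud = HDPointCloud(np.array([[0.0], [2.0]]), ("x",))
        assert build_tfcn(cloud, 2.0).n_edges == 1  # distance == T counts

    def test_edge_count_monotone_in_threshold(self, rng):
        cloud = HDPointCloud(rng.uniform(0, 50, (10, 4)), tuple("abcd"))
        counts = [build_tfcn(cloud, t).n_edges for t in np.linspace(0, 250, 12)]
        assert counts == sorted(counts)

    def test_negative_threshold_rejected(self, rng):
        cloud = HDPointCloud(rng.uniform(0, 1, (3, 2)), ("a", "b"))
        with pytest.raises(ValueError):
            build_tfcn(cloud, -0.1)


class TestDegreeEntropy:
    def test_regular_graphs_have_zero_entropy(self, rng):
        cloud = HDPointCloud(rng.uniform(0, 10, (5, 2)), ("a", "b"))
        clique = build_tfcn(cloud, 1e6)
        empty = build_tfcn(cloud, 0.0)
        assert degree_entropy(clique) == 0
        assert degree_entropy(empty) == 0

    def test_star_on_four_nodes(self):
        edges = np.array([[0, 1], [0, 2], [0, 3]])
        net = TFCN(4, edges, 1.0)
        expected = -(1 / 4) * math.log(1 / 4) - (3 / 4) * math.log(3 / 4)
        assert degree_entropy(net) == pytest.approx(expected)

    def test_entropy_nonnegative(self, rng):
        cloud = HDPointCloud(rng.uniform(0, 10, (9, 3)), ("a", "b", "c"))
        for t in np.linspace(0, 40, 9):
            assert degree_entropy(build_tfcn(cloud, t)) >= 0


class TestSelectThreshold:
    def test_matches_exhaustive_scan(self, two_blob_cloud):
        D = pairwise_distances(two_blob_cloud.values)
        iu = np.triu_indices(12, 1)
        cands = np.unique(D[iu])
        T = select_threshold(two_blob_cloud, cands)
        # independent argmax over the same grid
        best_H = max(degree_entropy(build_tfcn(two_blob_cloud, t)) for t in cands)
        assert degree_entropy(build_tfcn(two_blob_cloud, T)) == pytest.approx(best_H)

    def test_gap_and_clique_thresholds_never_selected(self, two_blob_cloud):
        """A threshold in the separating gap (both blobs complete, no cross
        edges) or at the diameter (clique) gives identical degrees, hence
        zero entropy; with within-blob candidates on offer the selection
        stays below the gap."""
        D = pairwise_distances(two_blob_cloud.values)
        iu = np.triu_indices(12, 1)
        within = np.unique(D[iu][D[iu] < 50])
        gap, diam = 100.0, float(D.max())
        assert degree_entropy(build_tfcn(two_blob_cloud, gap)) == 0
        assert degree_entropy(build_tfcn(two_blob_cloud, diam)) == 0
        T = select_threshold(two_blob_cloud, list(within) + [gap, diam])
        assert T < 50

    def test_duplicated_point_ties_break_small(self):
        cloud = HDPointCloud(np.ones((5, 2)), ("a", "b"))
        assert select_threshold(cloud, [0.0, 1.0, 2.0]) == 0.0

    def test_single_candidate_returned(self, two_blob_cloud):
        D = pairwise_distances(two_blob_cloud.values)
        diam = float(D.max())
        assert select_threshold(two_blob_cloud, [diam]) == diam

    def test_empty_candidates_rejected(self, two_blob_cloud):
        with pytest.raises(ValueError):
            select_threshold(two_blob_cloud, [])

    def test_component_entropy_mode_runs(self, two_blob_cloud):
        T = select_threshold(two_blob_cloud, property="components")
        assert T >= 0

    def test_component_entropy_zero_at_extremes(self, two_blob_cloud):
        assert component_size_entropy(build_tfcn(two_blob_cloud, 0.0)) == 0
        assert component_size_entropy(build_tfcn(two_blob_cloud, 1e6)) == 0


class TestDetectCommunities:
    def _clique_edges(self, nodes):
        return [(u, v) for i, u in enumerate(nodes) for v in nodes[i + 1 :]]

    def test_two_disjoint_cliques(self):
        edges = np.array(
            self._clique_edges(list(range(5))) + self._clique_edges(list(range(5, 10)))
        )
        part = detect_communities(TFCN(10, edges, 1.0))
        assert part.n_communities == 2
        assert len(set(part.labels[:5])) == 1
        assert len(set(part.labels[5:])) == 1

    def test_single_clique_single_community(self):
        edges = np.array(self._clique_edges(list(range(6))))
        assert detect_communities(TFCN(6, edges, 1.0)).n_communities == 1

    def test_isolated_nodes_become_singletons(self):
        edges = np.array(self._clique_edges([0, 1, 2]))
        part = detect_communities(TFCN(5, edges, 1.0))
        assert part.labels[3] != part.labels[4]
        assert part.n_communities == 3

    def test_deterministic(self, three_blob_cloud):
        cloud, _ = three_blob_cloud
        net = build_tfcn(cloud, 300.0)
        a = detect_communities(net, seed=1).labels
        b = detect_communities(net, seed=2).labels
        np.testing.assert_array_equal(a, b)

    def test_labels_partition_nodes(self, three_blob_cloud):
        cloud, _ = three_blob_cloud
        part = detect_communities(build_tfcn(cloud, 300.0))
        assert len(part.labels) == cloud.n_cells
        assert set(part.labels) == set(range(1, part.n_communities + 1))

    def test_three_dense_blobs_recovered(self, three_blob_cloud):
        """With a threshold in the separating gap the blobs are dense
        components and come back as exactly the generating labels."""
        cloud, labels = three_blob_cloud
        part = detect_communities(build_tfcn(cloud, 400.0))
        assert part.n_communities == 3
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(labels, part.labels) == 1.0

    def test_invalid_walk_length(self):
        with pytest.raises(ValueError):
            detect_communities(TFCN(2, np.array([[0, 1]]), 1.0), walk_length=0)
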