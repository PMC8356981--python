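"""Community detection: quality criteria, greedy optimiser, soft covers."""

import networkx as nx
import numpy as np
import pytest

from sbncomm import (
    AlgoSpec,
    detect,
    detect_soft_cover,
    greedy_multiscale_partition,
)
from sbncomm.detection import (
    DEFAULT_SCALES,
    HardPartition,
    criterion_value,
    detect_components,
)

from conftest import exhaustive_best_value, two_cliques


class TestCriterionValue:
    def test_single_community_newman_is_zero(self, small_fixture_graphs):
        for W in small_fixture_graphs:
            n = W.shape[0]
            assert criterion_value(W, np.ones(n, int), "newman") == pytest.approx(0.0)

    def test_rb_at_unit_resolution_equals_newman(self, small_fixture_graphs):
        rng = np.random.default_rng(0)
        for W in small_fixture_graphs:
            labels = rng.integers(1, 4, W.shape[0])
            assert criterion_value(W, labels, "rb", 1.0) == pytest.approx(
                criterion_value(W, labels, "newman")
            )

    def test_two_triangles_hand_oracle(self):
        # two K3 joined by a unit edge, m = 7: Q = 2 (3/7 - (7/14)^2)
        W = two_cliques(3, bridge=1.0)
        value = criterion_value(W, [1, 1, 1, 2, 2, 2], "newman")
        assert value == pytest.approx(6 / 7 - 1 / 2)

    def test_afg_matches_networkx_modularity_with_self_loops(self):
        rng = np.random.default_rng(3)
        W = np.triu((rng.random((12, 12)) < 0.4) * rng.uniform(0.2, 1, (12, 12)), 1)
        W = W + W.T
        labels = np.repeat([1, 2, 3], 4)
        for r in (0.3, -0.1, 0.0):
            G = nx.from_numpy_array(W)
            for i in range(12):
                G.add_edge(i, i, weight=r)
            comms = [set(np.flatnonzero(labels == c)) for c in (1, 2, 3)]
            expected = nx.community.modularity(G, comms, weight="weight")
            assert criterion_value(W, labels, "afg", r) == pytest.approx(expected, abs=1e-12)

    def test_stability_at_unit_time_equals_newman(self, small_fixture_graphs):
        W = small_fixture_graphs[0]
        labels = [1, 1, 1, 2, 2, 2]
        assert criterion_value(W, labels, "stability", 1.0) == pytest.approx(
            criterion_value(W, labels, "newman")
        )

    def test_unknown_criterion_rejected(self):
        with pytest.raises(ValueError):
            criterion_value(np.ones((3, 3)) - np.eye(3), [1, 1, 2], "leiden")


class TestGreedyOptimizer:
    def test_recovers_weakly_bridged_cliques(self):
        W = two_cliques(4, bridge=0.01)
        part, quality = greedy_multiscale_partition(W, "newman", seed=0)
        assert part.labels == [1, 1, 1, 1, 2, 2, 2, 2]
        assert quality.Q == pytest.approx(exhaustive_best_value(W), abs=1e-12)

    def test_afg_resistance_limits(self):
        W = two_cliques(3, bridge=1.0)
        part_fine, _ = greedy_multiscale_partition(W, "afg", scale=50.0, seed=0)
        assert part_fine.n_communities == W.shape[0]  # shattered
        part_coarse, _ = greedy_multiscale_partition(W, "afg", scale=-1.0, seed=0)
        assert part_coarse.n_communities == 1  # coarsened to one block

    @pytest.mark.parametrize("criterion", sorted(DEFAULT_SCALES))
    def test_returned_quality_is_self_consistent(self, planted_graph, criterion):
        G, _ = planted_graph
        part, quality = greedy_multiscale_partition(G, criterion, seed=3)
        recomputed = criterion_value(G, part, criterion, quality.scale)
        assert quality.Q == pytest.approx(recomputed, abs=1e-12)

    @pytest.mark.parametrize("criterion", sorted(DEFAULT_SCALES))
    def test_never_below_trivial_baselines(self, small_fixture_graphs, criterion):
        for W in small_fixture_graphs:
            n = W.shape[0]
            _, quality = greedy_multiscale_partition(W, criterion, seed=1)
            assert quality.Q >= criterion_value(W, np.ones(n, int), criterion) - 1e-12
            assert quality.Q >= criterion_value(W, np.arange(1, n + 1), criterion) - 1e-12

    def test_fixed_seed_is_deterministic(self, planted_graph):
        G, _ = planted_graph
        a, qa = greedy_multiscale_partition(G, "rb", seed=42)
        b, qb = greedy_multiscale_partition(G, "rb", seed=42)
        assert a.labels == b.labels and qa.Q == qb.Q

    def test_disconnected_input_rejected(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 1.0
        W[2, 3] = W[3, 2] = 1.0
        with pytest.raises(ValueError, match="connected"):
            greedy_multiscale_partition(W, "newman")

    def test_component_wise_detection_handles_disconnection(self):
        W = np.zeros((7, 7))
        blocks = two_cliques(3, bridge=0.0)
        W[:6, :6] = blocks  # two components plus an isolated node
        part = detect_components(W, AlgoSpec("newman"))
        assert part.n_nodes == 7
        assert len({part.labels[0], part.labels[3], part.labels[6]}) == 3


class TestSoftCover:
    def test_shared_node_gets_two_memberships(self):
        # two triangles sharing one node
        W = np.zeros((5, 5))
        for i, j in [(0, 1), (0, 2), (1, 2), (2, 3), (2, 4), (3, 4)]:
            W[i, j] = W[j, i] = 1.0
        cover = detect_soft_cover(W)
        sums = cover.membership.sum(axis=1)
        assert sums[2] == 2
        assert np.all(np.delete(sums, 2) == 1)

    def test_single_clique_is_one_community(self):
        W = np.ones((5, 5)) - np.eye(5)
        cover = detect_soft_cover(W)
        assert cover.n_communities == 1
        assert np.all(cover.membership == 1)

    def test_cover_property_every_node_belongs_somewhere(self, planted_graph):
        G, _ = planted_graph
        cover = detect_soft_cover(G)
        assert np.all(cover.membership.sum(axis=1) >= 1)

    def test_tiny_graph_single_community(self):
        W = np.zeros((2, 2))
        W[0, 1] = W[1, 0] = 1.0
        cover = detect_soft_cover(W)
        assert cover.membership.shape == (2, 1)


class TestPartitionContainers:
    def test_labels_canonicalized_contiguous(self):
        part = HardPartition([5, 5, 9, 2, 2])
        assert part.labels == [1, 1, 2, 3, 3]

    def test_dispatcher_routes_hard_and_soft(self, planted_graph):
        G, _ = planted_graph
        part, quality = detect(G, AlgoSpec("mscd_rb"))
        assert part.algorithm == "mscd_rb" and np.isfinite(quality.Q)
        cover = detect(G, AlgoSpec("soft_link"))
        assert cover.membership.shape[0] == G.n_nodes

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError):
            AlgoSpec("walktrap")
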