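"""Graph-construction schemes: efficiency, OMST, integration, thresholding."""

import numpy as np
import pytest

from sbncomm import (
    MetricStack,
    apply_scheme,
    generate_metric_stack,
    global_efficiency,
    integrate_metrics,
    omst_filter,
    threshold_to_sparsity,
)
from sbncomm.construction import SCHEME_NAMES
from sbncomm.matrices import METRIC_NAMES


class TestGlobalEfficiency:
    def test_complete_unit_graph_is_one(self):
        W = np.ones((4, 4)) - np.eye(4)
        assert global_efficiency(W) == pytest.approx(1.0)

    def test_edgeless_graph_is_zero(self):
        assert global_efficiency(np.zeros((4, 4))) == 0.0

    def test_three_node_path_hand_oracle(self):
        # pair distances {1, 1, 2} -> mean inverse = (1 + 1 + 1/2) / 3
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 1.0
        W[1, 2] = W[2, 1] = 1.0
        assert global_efficiency(W) == pytest.approx(5 / 6)

    def test_single_node_rejected(self):
        with pytest.raises(ValueError):
            global_efficiency(np.zeros((1, 1)))


class TestOmstFilter:
    def test_spanning_tree_input_is_identity(self):
        W = np.zeros((5, 5))
        for i, j, w in [(0, 1, 0.9), (1, 2, 0.8), (1, 3, 0.7), (3, 4, 0.6)]:
            W[i, j] = W[j, i] = w
        res = omst_filter(W)
        assert res.n_trees_used == 1
        assert np.allclose(res.filtered.weights, W)

    def test_matches_brute_force_over_tree_prefixes(self):
        # on K5 the candidate outputs are exactly the prefix unions of the
        # orthogonal-MST sequence; enumerate them independently
        rng = np.random.default_rng(5)
        W = np.triu(rng.uniform(0.2, 1.0, (5, 5)), 1)
        W = W + W.T
        res = omst_filter(W, max_trees=4)

        from scipy.sparse import csr_array
        from scipy.sparse.csgraph import connected_components, minimum_spanning_tree

        remaining = W.copy()
        accum = np.zeros_like(W)
        best_J, best_accum = -np.inf, None
        total = W.sum()
        while True:
            if connected_components(csr_array(remaining), directed=False)[0] > 1:
                break
            D = np.where(remaining > 0, 1.0 / remaining, 0.0)
            T = minimum_spanning_tree(csr_array(D)).toarray()
            ti, tj = np.nonzero(T)
            accum[ti, tj] = W[ti, tj]
            accum[tj, ti] = W[tj, ti]
            remaining[ti, tj] = remaining[tj, ti] = 0.0
            J = global_efficiency(accum) - accum.sum() / total
            if J > best_J:
                best_J, best_accum = J, accum.copy()
        assert np.allclose(res.filtered.weights, best_accum)

    def test_output_connected_with_bounded_edges(self, planted_graph):
        G, _ = planted_graph
        res = omst_filter(G, max_trees=4)
        n = G.n_nodes
        assert res.filtered.is_connected()
        assert n - 1 <= res.filtered.n_edges <= 4 * (n - 1)

    def test_selected_union_maximizes_cost_efficiency(self, planted_graph):
        G, _ = planted_graph
        res = omst_filter(G)
        best = max(J for _, J in res.cost_efficiency_curve)
        chosen = res.cost_efficiency_curve[res.n_trees_used - 1][1]
        assert chosen == pytest.approx(best)

    def test_disconnected_input_rejected(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 1.0
        W[2, 3] = W[3, 2] = 1.0
        with pytest.raises(ValueError, match="connected"):
            omst_filter(W)
        with pytest.raises(ValueError):
            omst_filter(np.ones((3, 3)) - np.eye(3), max_trees=0)


def _stack_from(base: np.ndarray, **overrides) -> MetricStack:
    mats = {m: base.copy() for m in METRIC_NAMES}
    mats.update(overrides)
    return MetricStack(mats)


class TestIntegrateMetrics:
    def test_two_identical_metrics_average_equally(self, planted_graph):
        G, _ = planted_graph
        stack = _stack_from(G.weights)
        out = integrate_metrics(stack, ["NS", "FA"])
        # equal weights -> output proportional to the rescaled input
        expected = integrate_metrics(stack, ["NS", "PS"])
        assert np.allclose(out.weights, expected.weights)
        iu = np.triu_indices(G.n_nodes, 1)
        mask = G.weights[iu] > 0
        assert np.corrcoef(out.weights[iu][mask], G.weights[iu][mask])[0, 1] == pytest.approx(1.0)

    def test_dissimilar_metric_upweighted(self, planted_graph):
        # M1 = M2 = base, M3 uncorrelated: alpha_3 > alpha_1 = alpha_2,
        # recovered from the output by least squares on the edges
        G, _ = planted_graph
        rng = np.random.default_rng(0)
        noise = np.triu(rng.uniform(0.1, 1.0, G.weights.shape), 1)
        noise = np.where(np.triu(G.weights, 1) > 0, noise, 0.0)
        noise = noise + noise.T
        stack = _stack_from(G.weights, TL=noise)
        out = integrate_metrics(stack, ["NS", "PS", "TL"])

        from sbncomm.construction import _rescale_unit

        iu = np.triu_indices(G.n_nodes, 1)
        mask = G.weights[iu] > 0
        X = np.column_stack(
            [_rescale_unit(stack[m], False)[iu][mask] for m in ("NS", "PS", "TL")]
        )
        alpha, *_ = np.linalg.lstsq(X, out.weights[iu][mask], rcond=None)
        assert alpha[0] == pytest.approx(alpha[1], abs=1e-9)
        assert alpha[2] > alpha[0]
        assert np.sum(alpha) == pytest.approx(1.0)

    def test_order_invariance(self, planted_graph):
        G, _ = planted_graph
        stack = generate_metric_stack(G, seed=3)
        a = integrate_metrics(stack, ["NS", "FA", "TL"])
        b = integrate_metrics(stack, ["TL", "NS", "FA"])
        assert np.allclose(a.weights, b.weights)

    def test_single_metric_rejected(self, planted_graph):
        G, _ = planted_graph
        with pytest.raises(ValueError):
            integrate_metrics(_stack_from(G.weights), ["NS"])

    def test_zero_variance_metric_warns(self, planted_graph):
        G, _ = planted_graph
        flat = np.where(G.weights > 0, 0.7, 0.0)
        stack = _stack_from(G.weights, FA=flat)
        with pytest.warns(UserWarning, match="zero"):
            integrate_metrics(stack, ["NS", "FA"])


class TestThresholdToSparsity:
    def test_current_sparsity_is_identity(self, planted_graph):
        G, _ = planted_graph
        out = threshold_to_sparsity(G, G.sparsity)
        assert np.allclose(out.weights, G.weights)

    def test_sort_and_cut_oracle(self):
        W = np.zeros((4, 4))
        vals = iter([6.0, 5.0, 4.0, 3.0, 2.0, 1.0])
        for i in range(4):
            for j in range(i + 1, 4):
                W[i, j] = W[j, i] = next(vals)
        out = threshold_to_sparsity(W, 3 / 6)
        kept = sorted(out.weights[np.triu_indices(4, 1)][out.weights[np.triu_indices(4, 1)] > 0])
        assert kept == [4.0, 5.0, 6.0]

    def test_equal_weights_tie_break_is_lexicographic(self):
        W = np.ones((4, 4)) - np.eye(4)
        out = threshold_to_sparsity(W, 0.5)
        iu, ju = np.nonzero(np.triu(out.weights, 1))
        assert list(zip(iu.tolist(), ju.tolist())) == [(0, 1), (0, 2), (0, 3)]

    def test_unreachable_target_names_deficit(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 1.0
        with pytest.raises(ValueError, match="deficit"):
            threshold_to_sparsity(W, 1.0)


@pytest.fixture(scope="module")
def stack(planted_graph):
    G, _ = planted_graph
    return generate_metric_stack(G, seed=11)


class TestApplyScheme:
    def test_ns_thresholded_schemes_share_topology(self, stack):
        D = apply_scheme("D", stack, reference_sparsity=0.2)
        E = apply_scheme("E", stack, reference_sparsity=0.2)
        F = apply_scheme("F", stack, reference_sparsity=0.2)
        assert np.array_equal(D.weights > 0, E.weights > 0)
        assert np.array_equal(D.weights > 0, F.weights > 0)
        assert not np.allclose(D.weights, E.weights)

    def test_omst_scheme_output_connected(self, stack):
        assert apply_scheme("C", stack).is_connected()

    def test_auto_sparsity_matches_nine_metric_scheme(self, stack):
        C = apply_scheme("C", stack)
        D = apply_scheme("D", stack, reference_sparsity="auto")
        assert D.n_edges == C.n_edges

    @pytest.mark.parametrize("scheme", list(SCHEME_NAMES) + list(SCHEME_NAMES.values()))
    def test_all_schemes_produce_normalized_graphs(self, stack, scheme):
        out = apply_scheme(scheme, stack, reference_sparsity=0.2)
        assert np.array_equal(out.weights, out.weights.T)
        assert np.all(np.diag(out.weights) == 0)
        assert out.weights.max() == pytest.approx(1.0)

    def test_unknown_scheme_rejected(self, stack):
        with pytest.raises(ValueError, match="unknown scheme"):
            apply_scheme("Z", stack)
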