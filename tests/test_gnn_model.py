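"""Network architecture: parameter accounting, convolution semantics,
community pooling, permutation symmetries and gradient correctness."""

import numpy as np
import pytest

from dockgraph import _autodiff as ad
from dockgraph._autodiff import Tensor
from dockgraph.gnn_model import (
    Batch,
    NetworkSpec,
    collate,
    community_pool,
    conv_forward,
    count_trainable_parameters,
    init_weights,
    network_forward,
    predict,
    prepare_graph,
)
from dockgraph.graph_builder import build_graph, select_interface_nodes
from dockgraph.synthetic_data import generate_complex


def random_graph(seed, d=8, n_res=10):
    rng = np.random.default_rng(seed)
    _, cplx, _ = generate_complex(n_res, seed=seed)
    nodes = select_interface_nodes(cplx)
    feats = rng.normal(size=(len(nodes), d)).astype(np.float32)
    return build_graph(cplx, feats, graph_id=f"r{seed}", target=0.5, nodes=nodes)


class TestParameterCount:
    @pytest.mark.parametrize("d,expected", [
        (1328, 52169),   # combined PSSM + embedding feature set
        (1306, 51465),   # embedding-only feature set
        (48, 11209), (26, 10505), (8, 9929),
    ])
    def test_enumerated_count_matches_closed_form(self, d, expected):
        spec = NetworkSpec(input_dim=d)
        assert count_trainable_parameters(spec) == expected
        assert spec.parameter_count_closed_form() == expected
        assert expected == 32 * d + 9673


class TestConvForward:
    def test_no_edges_gives_zero_outputs(self):
        x = Tensor(np.random.default_rng(0).normal(size=(4, 8)))
        w = init_weights(NetworkSpec(input_dim=8), seed=0)
        out = conv_forward(x, np.zeros(0, int), np.zeros(0, int), np.zeros((0, 1)),
                           w["internal.conv1.W"], w["internal.conv1.V"],
                           w["internal.conv1.att"], 4)
        assert np.array_equal(out.data, np.zeros((4, 16)))

    def test_self_loop_softmax_normalizes_to_one(self):
        # single node, single self-loop: attention weight must be exactly 1,
        # so the output is ReLU(z)
        x = Tensor(np.array([[1.0, -2.0, 0.5]]))
        W = Tensor(np.eye(3), requires_grad=True)
        V = Tensor(np.ones((1, 1)), requires_grad=True)
        att = Tensor(np.full((7, 1), 0.3), requires_grad=True)
        out = conv_forward(x, np.array([0]), np.array([0]), np.array([[0.5]]),
                           W, V, att, 1)
        np.testing.assert_allclose(out.data, np.maximum(x.data, 0))

    def test_permutation_equivariance(self):
        g = random_graph(21)
        p = prepare_graph(g)
        spec = NetworkSpec(input_dim=8)
        w = init_weights(spec, seed=1)
        src, dst, feat = p.edges["interface"]
        out = conv_forward(Tensor(p.x), src, dst, feat,
                           w["interface.conv1.W"], w["interface.conv1.V"],
                           w["interface.conv1.att"], len(p.x)).data
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(p.x))
        inv = np.argsort(perm)
        out_p = conv_forward(Tensor(p.x[perm]), inv[src], inv[dst], feat,
                             w["interface.conv1.W"], w["interface.conv1.V"],
                             w["interface.conv1.att"], len(p.x)).data
        np.testing.assert_allclose(out_p, out[perm], atol=1e-10)


class TestCommunityPool:
    def test_isolated_nodes_pool_to_identity(self):
        feats = np.arange(12.0).reshape(4, 3)
        chains = np.array(["A", "A", "B", "B"])
        pooled, edges, assign = community_pool(feats, np.zeros((0, 2), int), chains)
        assert np.array_equal(pooled, feats)
        assert len(np.unique(assign)) == 4

    def test_single_cluster_is_elementwise_max(self):
        feats = np.array([[1.0, 5.0], [3.0, 2.0], [2.0, 4.0]])
        chains = np.array(["A", "A", "A"])
        edges = np.array([[0, 1], [1, 2], [0, 2]])
        pooled, _, assign = community_pool(feats, edges, chains)
        if len(np.unique(assign)) == 1:  # Louvain may keep a triangle together
            np.testing.assert_allclose(pooled, [[3.0, 5.0]])
        for k in np.unique(assign):
            np.testing.assert_allclose(pooled[k], feats[assign == k].max(axis=0))

    def test_pooled_features_match_per_cluster_max(self, rng):
        g = random_graph(33, n_res=15)
        p = prepare_graph(g)
        feats = rng.normal(size=(g.n_nodes, 6))
        pooled, _, assign = community_pool(feats, g.internal_index, g.node_chains())
        for k in np.unique(assign):
            np.testing.assert_allclose(pooled[k], feats[assign == k].max(axis=0))

    def test_clusters_never_cross_chains(self):
        g = random_graph(34, n_res=15)
        p = prepare_graph(g)
        chains = g.node_chains()
        for k in np.unique(p.assign):
            assert len(set(chains[p.assign == k])) == 1


class TestNetworkForward:
    def test_permutation_invariance_of_graph_score(self):
        spec = NetworkSpec(input_dim=8)
        w = init_weights(spec, seed=3)
        g = random_graph(55, n_res=12)
        base = predict([g], w, spec)[0]
        # permute node order (and edge indices accordingly)
        rng = np.random.default_rng(1)
        perm = rng.permutation(g.n_nodes)
        inv = np.argsort(perm)
        import copy
        g2 = copy.deepcopy(g)
        g2.nodes = [g.nodes[i] for i in perm]
        g2.node_features = g.node_features[perm]
        for attr in ("internal_index", "interface_index"):
            idx = inv[getattr(g, attr)]
            setattr(g2, attr, np.sort(idx, axis=1))
        assert predict([g2], w, spec)[0] == pytest.approx(base, abs=1e-9)

    def test_zero_weights_score_constant_across_graphs(self):
        spec = NetworkSpec(input_dim=8)
        w = init_weights(spec, seed=0)
        for t in w.values():
            t.data = np.zeros_like(t.data)
        scores = predict([random_graph(s) for s in (60, 61, 62)], w, spec)
        assert np.allclose(scores, scores[0])

    def test_duplicated_graph_scores_identically_in_batch(self):
        spec = NetworkSpec(input_dim=8)
        w = init_weights(spec, seed=5)
        g = random_graph(70)
        s = predict([g, g], w, spec)
        assert s[0] == pytest.approx(s[1], abs=1e-12)

    def test_regression_inference_clamped_to_unit_interval(self):
        spec = NetworkSpec(input_dim=8)
        w = init_weights(spec, seed=7)
        w["head.fc2.b"].data[:] = 50.0  # force a huge raw output
        scores = predict([random_graph(71)], w, spec)
        assert 0.0 <= scores[0] <= 1.0

    def test_determinism_under_fixed_seed(self):
        spec = NetworkSpec(input_dim=8)
        g = random_graph(80)
        a = predict([g], init_weights(spec, seed=9), spec)
        b = predict([g], init_weights(spec, seed=9), spec)
        assert np.array_equal(a, b)


class TestGradients:
    def test_numerical_vs_analytic_gradient_on_toy_graph(self):
        """Central-difference check of the full forward+MSE pipeline."""
        spec = NetworkSpec(input_dim=6)
        g = random_graph(90, d=6, n_res=8)
        p = prepare_graph(g)
        batch = collate([p])
        weights = init_weights(spec, seed=11)
        target = np.array([0.7])

        def loss_value():
            return float(ad.mse_loss(
                network_forward(batch, weights, spec), target).data)

        loss = ad.mse_loss(network_forward(batch, weights, spec), target)
        loss.backward()

        rng = np.random.default_rng(0)
        checked = 0
        for name, w in weights.items():
            flat = w.data.reshape(-1)
            grad = (w.grad if w.grad is not None else np.zeros_like(w.data)).reshape(-1)
            for idx in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                h = 1e-6
                orig = flat[idx]
                flat[idx] = orig + h
                up = loss_value()
                flat[idx] = orig - h
                down = loss_value()
                flat[idx] = orig
                numeric = (up - down) / (2 * h)
                denom = max(abs(numeric), abs(grad[idx]), 1e-8)
                assert abs(numeric - grad[idx]) / denom < 1e-4, name
                checked += 1
        assert checked >= 30
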