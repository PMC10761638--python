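"""Similarity graph construction and GraphSAGE forward/backward."""

import numpy as np
import pytest

from radiogcn.graph import (LesionGraph, SageParams, attach_nodes, build_graph,
                            init_sage, sage_backward, sage_forward,
                            sage_forward_cached, similar_score)


def dense_oracle(X, A, params):
    """Independent node-by-node forward pass from the layer definitions."""
    n = X.shape[0]
    h = X.copy()
    for lay in params.layers:
        new = np.zeros((n, lay["b"].shape[0]))
        for i in range(n):
            wsum = np.abs(A[i]).sum()
            if wsum == 0:
                agg = np.zeros(h.shape[1])
            else:
                agg = sum(A[i, j] * h[j] for j in range(n)) / wsum
            z = lay["W_self"] @ h[i] + lay["W_neigh"] @ agg + lay["b"]
            new[i] = np.maximum(z, 0.0)
        h = new
    out = np.zeros((n, params.n_classes))
    for i in range(n):
        logits = params.head_W @ h[i] + params.head_b
        e = np.exp(logits - logits.max())
        out[i] = e / e.sum()
    return out


class TestSimilarScore:
    def test_self_similarity_is_one(self):
        v = np.array([1.0, -2.0, 3.0])
        assert similar_score(v, v) == pytest.approx(1.0)

    def test_orthogonal_unit_vectors(self):
        assert similar_score(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 0.0

    def test_collinear_vectors(self):
        assert similar_score(np.array([1.0, 2.0]),
                             np.array([2.0, 4.0])) == pytest.approx(1.0)

    def test_zero_norm_gives_zero(self):
        assert similar_score(np.zeros(3), np.array([1.0, 0.0, 0.0])) == 0.0

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            similar_score(np.zeros(2), np.zeros(3))


class TestBuildGraph:
    def test_duplicate_vectors_become_mutual_neighbors(self):
        e1 = np.array([1.0, 0.0])
        e2 = np.array([0.0, 1.0])
        g = build_graph(np.vstack([e1, e1, e2]), k_neighbors=1)
        assert g.adjacency[0, 1] == pytest.approx(1.0)
        assert g.adjacency[1, 0] == pytest.approx(1.0)

    def test_identical_vectors_give_complete_unit_graph(self):
        X = np.tile(np.array([1.0, 2.0]), (4, 1))
        g = build_graph(X, k_neighbors=3)
        expect = 1.0 - np.eye(4)
        np.testing.assert_allclose(g.adjacency, expect)

    def test_single_node_has_no_edges(self):
        g = build_graph(np.ones((1, 3)), k_neighbors=5)
        assert g.adjacency.shape == (1, 1) and g.adjacency.sum() == 0

    def test_oversized_k_truncated(self):
        g = build_graph(np.random.default_rng(0).normal(size=(4, 3)),
                        k_neighbors=10)
        assert g.k_neighbors == 3

    def test_no_self_loops_and_symmetry(self):
        X = np.random.default_rng(1).normal(size=(12, 5))
        g = build_graph(X, k_neighbors=3)
        assert np.all(np.diag(g.adjacency) == 0)
        np.testing.assert_allclose(g.adjacency, g.adjacency.T)

    def test_attach_contains_identical_training_node(self):
        X = np.random.default_rng(2).normal(size=(6, 4))
        g = build_graph(X, k_neighbors=2)
        P = attach_nodes(g, X[2:3])
        assert P[0, 2] > 0  # cosine 1 with itself, necessarily selected
        np.testing.assert_allclose(P.sum(axis=1), 1.0)


class TestSageForward:
    def test_identical_nodes_on_complete_graph_share_output(self):
        X = np.tile(np.array([0.3, -0.7, 0.2]), (5, 1))
        g = build_graph(X, k_neighbors=4)
        params = init_sage(3, hidden=8, seed=0)
        probs = sage_forward(g, params)
        np.testing.assert_allclose(probs, np.tile(probs[0], (5, 1)), atol=1e-12)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_isolated_node_uses_zero_aggregate(self):
        X = np.array([[1.0, 0.0], [0.0, 0.0]])  # zero row: no cosine edges
        A = np.zeros((2, 2))
        g = LesionGraph(features=X, adjacency=A, k_neighbors=1)
        params = init_sage(2, hidden=4, n_layers=1, seed=1)
        probs = sage_forward(g, params)
        # oracle: agg = 0 for isolated nodes
        np.testing.assert_allclose(probs, dense_oracle(X, A, params), atol=1e-12)

    def test_hand_set_single_layer_path_graph(self):
        # 3-node path, 1 layer, hand-set weights; compare to explicit algebra
        X = np.array([[1.0], [2.0], [4.0]])
        A = np.array([[0.0, 0.5, 0.0], [0.5, 0.0, 0.5], [0.0, 0.5, 0.0]])
        lay = {"W_self": np.array([[1.0]]), "W_neigh": np.array([[2.0]]),
               "b": np.array([0.0])}
        params = SageParams(layers=[lay], head_W=np.array([[1.0], [-1.0], [0.0]]),
                            head_b=np.zeros(3), dropout=0.0)
        g = LesionGraph(features=X, adjacency=A, k_neighbors=1)
        probs = sage_forward(g, params)
        # weighted-mean aggregates: node0 <- h1 = 2; node1 <- (1+4)/2 = 2.5;
        # node2 <- h1 = 2
        h = np.array([1.0 + 2 * 2.0, 2.0 + 2 * 2.5, 4.0 + 2 * 2.0])
        logits = np.stack([h, -h, np.zeros(3)], axis=1)
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        np.testing.assert_allclose(probs, e / e.sum(axis=1, keepdims=True),
                                   atol=1e-12)

    def test_matches_dense_oracle_on_random_small_graphs(self):
        rng = np.random.default_rng(3)
        for trial in range(30):
            n = int(rng.integers(2, 11))
            X = rng.normal(size=(n, 4))
            g = build_graph(X, k_neighbors=int(rng.integers(1, n)))
            params = init_sage(4, hidden=6, n_layers=2, seed=trial)
            np.testing.assert_allclose(
                sage_forward(g, params),
                dense_oracle(X, g.adjacency, params), atol=1e-8)

    def test_node_relabeling_permutes_outputs(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(8, 3))
        g = build_graph(X, k_neighbors=3)
        params = init_sage(3, hidden=5, seed=2)
        perm = rng.permutation(8)
        gp = LesionGraph(features=X[perm],
                         adjacency=g.adjacency[np.ix_(perm, perm)],
                         k_neighbors=3)
        np.testing.assert_allclose(sage_forward(gp, params),
                                   sage_forward(g, params)[perm], atol=1e-12)

    def test_width_mismatch_rejected(self):
        g = build_graph(np.ones((3, 4)), k_neighbors=1)
        with pytest.raises(ValueError):
            sage_forward(g, init_sage(5, seed=0))


class TestSageBackward:
    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(5)
        n = 6
        X = rng.normal(size=(n, 3))
        g = build_graph(X, k_neighbors=2)
        P = g.aggregator
        params = init_sage(3, hidden=4, n_layers=2, seed=0)
        y = rng.integers(0, 3, size=n)

        def loss_and_dlogits():
            probs, cache = sage_forward_cached(X, P, params)
            ll = -np.log(probs[np.arange(n), y] + 1e-12).mean()
            onehot = np.eye(3)[y]
            return ll, (probs - onehot) / n, cache

        _, dlogits, cache = loss_and_dlogits()
        grads = sage_backward(dlogits, params, cache)

        eps = 1e-6
        arrays = [(params.layers[0]["W_self"], grads["layers"][0]["W_self"]),
                  (params.layers[1]["W_neigh"], grads["layers"][1]["W_neigh"]),
                  (params.head_W, grads["head_W"]),
                  (params.layers[1]["b"], grads["layers"][1]["b"])]
        for arr, grad in arrays:
            flat = arr.ravel()
            for idx in rng.choice(flat.size, size=min(5, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                up = loss_and_dlogits()[0]
                flat[idx] = orig - eps
                down = loss_and_dlogits()[0]
                flat[idx] = orig
                assert abs((up - down) / (2 * eps) - grad.ravel()[idx]) < 1e-5

    def test_input_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(6)
        n = 5
        X = rng.normal(size=(n, 3))
        g = build_graph(X, k_neighbors=2)
        P = g.aggregator
        params = init_sage(3, hidden=4, n_layers=1, seed=1)
        y = rng.integers(0, 3, size=n)

        probs, cache = sage_forward_cached(X, P, params)
        onehot = np.eye(3)[y]
        grads = sage_backward((probs - onehot) / n, params, cache)

        eps = 1e-6
        for idx in rng.choice(X.size, size=6, replace=False):
            flat = X.ravel()
            orig = flat[idx]
            flat[idx] = orig + eps
            up = -np.log(sage_forward_cached(X, P, params)[0][np.arange(n), y]
                         + 1e-12).mean()
            flat[idx] = orig - eps
            down = -np.log(sage_forward_cached(X, P, params)[0][np.arange(n), y]
                           + 1e-12).mean()
            flat[idx] = orig
            assert abs((up - down) / (2 * eps) - grads["X"].ravel()[idx]) < 1e-5
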