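"""Graph encoder: Laplacian, Chebyshev filtering, attention, training."""

import numpy as np
import pytest

from bchem import (
    AdjacencyMatrix,
    AttentionParams,
    ChebLayerParams,
    ModelConfig,
    attention_weights,
    build_adjacency,
    cheb_conv_forward,
    init_model,
    model_forward,
    multi_head_attention,
    normalized_laplacian,
    score_pairs,
    train_model,
)
from bchem.errors import SingleClassError
from bchem.gnn import LaplacianMatrix
from bchem.pipeline import network_pairs


def _adj(values):
    return AdjacencyMatrix(values=np.asarray(values, dtype=float))


def _random_bipartite(n_left, n_right, p, seed):
    rng = np.random.default_rng(seed)
    B = (rng.random((n_left, n_right)) < p).astype(float)
    n = n_left + n_right
    A = np.zeros((n, n))
    A[:n_left, n_left:] = B
    A[n_left:, :n_left] = B.T
    return _adj(A)


class TestNormalizedLaplacian:
    def test_two_node_path(self):
        L = normalized_laplacian(_adj([[0, 1], [1, 0]]), scale=False)
        np.testing.assert_allclose(L.values, [[1, -1], [-1, 1]])

    def test_empty_graph_isolated_convention(self):
        L = normalized_laplacian(_adj(np.zeros((3, 3))), scale=False)
        np.testing.assert_allclose(L.values, np.eye(3))

    @pytest.mark.parametrize("seed", range(4))
    def test_eigenvalues_in_range(self, seed):
        A = _random_bipartite(4, 4, 0.5, seed)
        w = np.linalg.eigvalsh(normalized_laplacian(A, scale=False).values)
        assert w.min() > -1e-10 and w.max() < 2 + 1e-10
        w_scaled = np.linalg.eigvalsh(normalized_laplacian(A, scale=True).values)
        assert w_scaled.min() > -1 - 1e-10 and w_scaled.max() < 1 + 1e-10

    def test_asymmetric_adjacency_errors(self):
        with pytest.raises(ValueError, match="symmetric"):
            normalized_laplacian(_adj([[0, 1], [0, 0]]))


class TestChebConvForward:
    def test_order_zero_is_plain_linear_map(self):
        rng = np.random.default_rng(0)
        H, W0 = rng.standard_normal((5, 3)), rng.standard_normal((3, 2))
        L = LaplacianMatrix(values=rng.standard_normal((5, 5)), scaled=True)
        out = cheb_conv_forward(H, L, ChebLayerParams(order_K=0, weights=[W0]))
        np.testing.assert_allclose(out, H @ W0)

    def test_order_one_identity_weight_applies_laplacian(self):
        rng = np.random.default_rng(1)
        H = rng.standard_normal((4, 3))
        Lv = rng.standard_normal((4, 4))
        L = LaplacianMatrix(values=Lv, scaled=True)
        params = ChebLayerParams(order_K=1, weights=[np.zeros((3, 3)), np.eye(3)])
        np.testing.assert_allclose(cheb_conv_forward(H, L, params), Lv @ H)

    @pytest.mark.parametrize("seed", range(20))
    @pytest.mark.parametrize("K", [1, 2, 3])
    def test_matches_spectral_domain_oracle(self, seed, K):
        """The polynomial recurrence must equal filtering in the eigenbasis."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        A = _random_bipartite(n // 2, n - n // 2, 0.5, seed + 100)
        L = normalized_laplacian(A, scale=True)
        n_nodes = L.values.shape[0]
        d_in, d_out = 3, 2
        H = rng.standard_normal((n_nodes, d_in))
        weights = [rng.standard_normal((d_in, d_out)) for _ in range(K + 1)]
        out = cheb_conv_forward(H, L, ChebLayerParams(order_K=K, weights=weights))

        lam, U = np.linalg.eigh(L.values)
        Tk = [np.ones_like(lam), lam]
        for _ in range(2, K + 1):
            Tk.append(2 * lam * Tk[-1] - Tk[-2])
        oracle = sum(
            (U * Tk[k]) @ U.T @ H @ weights[k] for k in range(K + 1)
        )
        assert np.abs(out - oracle).max() < 1e-6

    def test_dimension_mismatch_errors(self):
        L = LaplacianMatrix(values=np.eye(4), scaled=True)
        params = ChebLayerParams(order_K=0, weights=[np.eye(5)])
        with pytest.raises(ValueError):
            cheb_conv_forward(np.zeros((4, 3)), L, params)

    def test_weight_count_enforced(self):
        with pytest.raises(ValueError):
            ChebLayerParams(order_K=2, weights=[np.eye(2)])


def _attn_params(C, H, seed=0):
    rng = np.random.default_rng(seed)
    d_k = C // H
    return AttentionParams(
        n_heads=H,
        W_q=[rng.standard_normal((C, d_k)) for _ in range(H)],
        W_k=[rng.standard_normal((C, d_k)) for _ in range(H)],
        W_v=[rng.standard_normal((C, d_k)) for _ in range(H)],
        W_out=rng.standard_normal((H * d_k, C)),
    )


class TestMultiHeadAttention:
    def test_head_dim_is_c_over_h(self):
        params = _attn_params(32, 2)
        assert params.head_dim == 16

    def test_indivisible_heads_error(self):
        with pytest.raises(ValueError, match="divisible"):
            multi_head_attention(np.zeros((3, 5)), _attn_params(4, 2))

    def test_single_node_softmax_is_one(self):
        params = _attn_params(4, 2, seed=1)
        X = np.random.default_rng(0).standard_normal((1, 4))
        W = attention_weights(X, params)
        np.testing.assert_allclose(W, np.ones((2, 1, 1)))
        V = np.hstack([X @ w for w in params.W_v])
        np.testing.assert_allclose(multi_head_attention(X, params), V @ params.W_out)

    def test_two_node_hand_enumeration(self):
        """n=2, one head, d_k=1, Q=K=[1,0], V=[2,4]: weights via softmax([1,0])."""
        X = np.array([[1.0, 2.0], [0.0, 4.0]])
        params = AttentionParams(
            n_heads=1,
            W_q=[np.array([[1.0], [0.0]])],
            W_k=[np.array([[1.0], [0.0]])],
            W_v=[np.array([[0.0], [1.0]])],
            W_out=np.array([[1.0, 0.0]]),
        )
        w0 = np.exp(1) / (np.exp(1) + 1)
        W = attention_weights(X, params)[0]
        np.testing.assert_allclose(W[0], [w0, 1 - w0], atol=1e-12)
        np.testing.assert_allclose(W[1], [0.5, 0.5], atol=1e-12)
        out = multi_head_attention(X, params)
        np.testing.assert_allclose(out[0, 0], w0 * 2 + (1 - w0) * 4, atol=1e-12)
        np.testing.assert_allclose(out[:, 1], 0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_rows_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((7, 8))
        W = attention_weights(X, _attn_params(8, 2, seed))
        np.testing.assert_allclose(W.sum(axis=2), 1.0, atol=1e-9)

    def test_identical_features_give_uniform_weights(self):
        X = np.tile(np.random.default_rng(0).standard_normal(6), (5, 1))
        W = attention_weights(X, _attn_params(6, 2))
        np.testing.assert_allclose(W, 1.0 / 5, atol=1e-12)

    def test_row_stochastic_under_feature_scaling(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((6, 4))
        params = _attn_params(4, 2, seed=2)
        for scale in (1.0, 2.0):
            W = attention_weights(scale * X, params)
            np.testing.assert_allclose(W.sum(axis=2), 1.0, atol=1e-9)


class TestModelForward:
    def test_zero_weight_model_repeatable(self):
        model = init_model(4, n_diseases=3, config=ModelConfig(embed_dim=4), seed=0)
        for m in model.input_maps.values():
            m["W"][:] = 0
        for layer in model.layers:
            layer.weights = [np.zeros_like(w) for w in layer.weights]
        L = LaplacianMatrix(values=np.zeros((6, 6)), scaled=True)
        H0 = np.random.default_rng(0).standard_normal((6, 4))
        a = model_forward(model, H0, L)
        b = model_forward(model, H0, L)
        np.testing.assert_array_equal(a, b)
        np.testing.assert_allclose(a, 0.0)

    def test_output_shape_default_config(self, planted):
        net = planted["network"]
        A = build_adjacency(net)
        L = normalized_laplacian(A)
        emb = model_forward(
            init_model(32, net.n_diseases, seed=0), planted["attrs"], L
        )
        assert emb.shape == (net.n_nodes, 32)

    @pytest.mark.parametrize("seed", range(3))
    def test_permutation_equivariance_within_modalities(self, seed):
        """Jointly permuting nodes (within each modality block) permutes rows."""
        rng = np.random.default_rng(seed)
        nd, nr = 3, 3
        A = _random_bipartite(nd, nr, 0.6, seed)
        H0 = rng.standard_normal((6, 5))
        model = init_model(5, nd, ModelConfig(embed_dim=4, n_heads=2), seed=seed)
        L = normalized_laplacian(A)
        base = model_forward(model, H0, L)

        perm = np.concatenate([rng.permutation(nd), nd + rng.permutation(nr)])
        Lp = LaplacianMatrix(values=L.values[np.ix_(perm, perm)], scaled=True)
        permuted = model_forward(model, H0[perm], Lp)
        np.testing.assert_allclose(permuted, base[perm], atol=1e-10)


class TestTraining:
    def test_loss_decreases_on_planted_signal(self, planted):
        net = planted["network"]
        L = normalized_laplacian(build_adjacency(net))
        ds = network_pairs(net)
        model = init_model(32, net.n_diseases, ModelConfig(epochs=30), seed=0)
        train_model(model, planted["attrs"], L, ds.pairs, ds.labels)
        assert model.loss_history[-1] < model.loss_history[0]

    def test_seeded_determinism(self, planted):
        net = planted["network"]
        L = normalized_laplacian(build_adjacency(net))
        ds = network_pairs(net)
        finals = []
        for _ in range(2):
            model = init_model(32, net.n_diseases, ModelConfig(epochs=10), seed=4)
            train_model(model, planted["attrs"], L, ds.pairs, ds.labels)
            finals.append(model.link_bilinear.copy())
        np.testing.assert_array_equal(finals[0], finals[1])

    def test_training_auc_on_planted_benchmark(self, planted):
        from sklearn.metrics import roc_auc_score

        net = planted["network"]
        L = normalized_laplacian(build_adjacency(net))
        ds = network_pairs(net)
        model = init_model(32, net.n_diseases, ModelConfig(epochs=200), seed=0)
        train_model(model, planted["attrs"], L, ds.pairs, ds.labels)
        emb = model_forward(model, planted["attrs"], L)
        scores = score_pairs(model, emb, ds.pairs)
        assert roc_auc_score(ds.labels, scores) >= 0.9

    def test_single_class_training_errors(self, planted):
        net = planted["network"]
        L = normalized_laplacian(build_adjacency(net))
        ds = network_pairs(net)
        model = init_model(32, net.n_diseases, ModelConfig(epochs=1), seed=0)
        with pytest.raises(SingleClassError):
            train_model(model, planted["attrs"], L, ds.pairs, np.ones(len(ds)))
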