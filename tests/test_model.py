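import numpy as np
import pytest

from lbmff import (
    SimilarityMatrix,
    TrainConfig,
    ValidationError,
    build_feature_graph,
    decode,
    gcn_layer,
    init_embeddings,
    layer_attention,
    load_model,
    predict,
    save_model,
    train,
)
from lbmff.model import _backward, _forward, _weighted_bce, initial_attention
from oracles import forward_oracle


def _random_graph(rng, m, n):
    sr = rng.random((m, m)); sr = (sr + sr.T) / 2; np.fill_diagonal(sr, 1.0)
    sd = rng.random((n, n)); sd = (sd + sd.T) / 2; np.fill_diagonal(sd, 1.0)
    A = (rng.random((m, n)) < 0.5).astype(int)
    if A.sum() == 0:
        A[0, 0] = 1
    labels_r = tuple(f"r{i}" for i in range(m))
    labels_d = tuple(f"d{i}" for i in range(n))
    graph = build_feature_graph(
        SimilarityMatrix(sr, labels_r), SimilarityMatrix(sd, labels_d), A
    )
    return graph, A


class TestInitEmbeddings:
    def test_block_assembly(self):
        H0 = init_embeddings(np.array([[1]]))
        assert np.array_equal(H0, [[0.0, 1.0], [1.0, 0.0]])

    def test_all_zero(self):
        assert init_embeddings(np.zeros((2, 3))).sum() == 0

    def test_masked_test_pair_stays_zero(self):
        A = np.array([[1, 1], [0, 1]])
        A_train = A.copy()
        A_train[0, 1] = 0  # held-out association
        H0 = init_embeddings(A_train)
        assert H0[0, 2 + 1] == 0.0
        assert H0[0, 2 + 0] == 1.0


class TestGCNLayer:
    def test_identity_propagation(self, rng):
        H = rng.random((4, 4))
        out = gcn_layer(H, np.eye(4), np.eye(4))
        assert np.allclose(out, H)

    def test_relu_zeroes_negative_preactivations(self):
        H = np.array([[1.0]])
        out = gcn_layer(H, np.eye(1), np.array([[-2.0]]))
        assert out[0, 0] == 0.0

    def test_matches_dense_product_oracle(self, rng):
        A_H = rng.random((5, 5)); A_H = (A_H + A_H.T) / 2
        H = rng.random((5, 3))
        W = rng.standard_normal((3, 2))
        d = A_H.sum(axis=1)
        expect = np.maximum(
            (A_H / np.sqrt(np.outer(d, d))) @ H @ W, 0.0
        )
        assert np.allclose(gcn_layer(H, A_H, W), expect, atol=1e-6)


class TestLayerAttention:
    def test_initial_coefficients(self):
        assert np.allclose(initial_attention(3, True), [1.0, 0.5, 1 / 3])
        assert np.allclose(initial_attention(2, False), [0.5, 1 / 3])

    def test_single_layer_passthrough(self, rng):
        H = rng.random((3, 2))
        assert np.allclose(layer_attention([H], np.array([1.0])), H)

    def test_two_equal_layers_average_to_the_layer(self, rng):
        H = rng.random((3, 2))
        assert np.allclose(layer_attention([H, H], np.array([0.5, 0.5])), H)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValidationError):
            layer_attention([rng.random((2, 2)), rng.random((3, 2))], np.array([0.5, 0.5]))


class TestDecoder:
    def test_hand_bilinear_form(self):
        E_r = np.array([[1.0, 0.0]])
        E_d = np.array([[0.0, 1.0]])
        W = np.array([[0.0, 1.0], [0.0, 0.0]])
        assert decode(E_r, E_d, W)[0, 0] == pytest.approx(1 / (1 + np.exp(-1)), abs=1e-6)

    def test_zero_decoder_gives_half(self, rng):
        scores = decode(rng.random((2, 3)), rng.random((4, 3)), np.zeros((3, 3)))
        assert np.allclose(scores, 0.5)

    def test_negated_decoder_flips_scores(self, rng):
        E_r, E_d = rng.random((2, 3)), rng.random((4, 3))
        W = rng.standard_normal((3, 3))
        assert np.allclose(decode(E_r, E_d, -W), 1 - decode(E_r, E_d, W), atol=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValidationError):
            decode(rng.random((2, 3)), rng.random((4, 3)), np.zeros((2, 2)))


class TestForwardPass:
    @pytest.mark.parametrize("m, n", [(2, 3), (4, 5), (5, 5)])
    def test_matches_from_scratch_dense_oracle(self, rng, m, n):
        graph, A = _random_graph(rng, m, n)
        model = train(graph, A, TrainConfig(epochs=0, seed=4))
        scores = predict(model, graph, A)
        expect = forward_oracle(
            graph.a_h, init_embeddings(A), model.weights,
            model.attention, model.decoder, m, model.attends_input,
        )
        assert np.allclose(scores, expect, atol=1e-6)
        assert scores.min() > 0 and scores.max() < 1

    def test_permutation_equivariance(self, rng):
        m, n = 3, 4
        graph, A = _random_graph(rng, m, n)
        model = train(graph, A, TrainConfig(epochs=0, seed=0))
        scores = predict(model, graph, A)

        pr = rng.permutation(m)
        pd_ = rng.permutation(n)
        full = np.concatenate([pr, m + pd_])
        P = np.eye(m + n)[full]  # x' = P x reorders nodes

        from lbmff.fusion import FeatureGraph

        graph_p = FeatureGraph(P @ graph.a_h @ P.T, m, n)
        model_p = train(graph_p, A[pr][:, pd_], TrainConfig(epochs=0, seed=0))
        model_p.weights = [P @ W @ P.T for W in model.weights]
        model_p.decoder = P @ model.decoder @ P.T
        model_p.attention = model.attention.copy()
        scores_p = predict(model_p, graph_p, A[pr][:, pd_])
        assert np.allclose(scores_p, scores[pr][:, pd_], atol=1e-10)


class TestGradients:
    def test_backward_matches_finite_differences(self, rng):
        m, n = 3, 4
        graph, A = _random_graph(rng, m, n)
        model = train(graph, A, TrainConfig(epochs=0, seed=11))
        Y = A.astype(float)
        w = 1.0 + 2.0 * Y
        H0 = init_embeddings(A)
        a_hat = graph.a_hat

        def loss_value():
            logits, _ = _forward(model, a_hat, H0, None)
            return _weighted_bce(logits, Y, w)[0]

        logits, cache = _forward(model, a_hat, H0, None)
        _, G = _weighted_bce(logits, Y, w)
        g_weights, g_att, g_dec = _backward(model, a_hat, cache, G)

        eps = 1e-6
        for param, grad in [
            (model.weights[0], g_weights[0]),
            (model.weights[1], g_weights[1]),
            (model.decoder, g_dec),
            (model.attention, g_att),
        ]:
            it = np.nditer(param, flags=["multi_index"])
            checked = 0
            while not it.finished and checked < 12:
                idx = it.multi_index
                orig = param[idx]
                param[idx] = orig + eps
                up = loss_value()
                param[idx] = orig - eps
                down = loss_value()
                param[idx] = orig
                numeric = (up - down) / (2 * eps)
                assert np.asarray(grad)[idx] == pytest.approx(numeric, abs=5e-6)
                checked += 1
                it.iternext()


class TestTraining:
    def test_zero_epochs_returns_initial_model(self, rng):
        graph, A = _random_graph(rng, 3, 3)
        model = train(graph, A, TrainConfig(epochs=0, seed=1))
        assert model.loss_trajectory == []

    def test_same_seed_gives_bit_identical_trajectories(self, rng):
        graph, A = _random_graph(rng, 4, 5)
        cfg = TrainConfig(epochs=30, seed=9)
        t1 = train(graph, A, cfg).loss_trajectory
        t2 = train(graph, A, cfg).loss_trajectory
        assert t1 == t2

    def test_loss_decreases_on_learnable_problem(self, rng):
        graph, A = _random_graph(rng, 5, 6)
        traj = train(graph, A, TrainConfig(epochs=200, seed=2, dropout=0.0)).loss_trajectory
        assert traj[-1] < traj[0]

    def test_scores_strictly_inside_unit_interval(self, rng):
        graph, A = _random_graph(rng, 4, 4)
        model = train(graph, A, TrainConfig(epochs=100, seed=3))
        scores = predict(model, graph, A)
        assert scores.min() > 0.0 and scores.max() < 1.0

    def test_all_zero_training_matrix_rejected(self, rng):
        graph, _ = _random_graph(rng, 3, 3)
        with pytest.raises(ValidationError):
            train(graph, np.zeros((3, 3), int), TrainConfig(epochs=5))

    def test_edge_dropout_mode_is_deterministic_and_finite(self, rng):
        graph, A = _random_graph(rng, 4, 5)
        cfg = TrainConfig(epochs=30, seed=2, dropout=0.3, dropout_mode="edge")
        t1 = train(graph, A, cfg).loss_trajectory
        t2 = train(graph, A, cfg).loss_trajectory
        assert t1 == t2
        assert np.isfinite(t1).all()

    def test_config_validation(self):
        with pytest.raises(ValidationError):
            TrainConfig(dropout=1.0)
        with pytest.raises(ValidationError):
            TrainConfig(epochs=-1)
        with pytest.raises(ValidationError):
            TrainConfig(dropout_mode="weights")

    def test_save_load_round_trip(self, tmp_path, rng):
        graph, A = _random_graph(rng, 3, 4)
        model = train(graph, A, TrainConfig(epochs=20, seed=5))
        save_model(model, tmp_path / "m")
        back = load_model(tmp_path / "m")
        assert np.allclose(
            predict(back, graph, A), predict(model, graph, A), atol=1e-15
        )
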