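"""Network building blocks vs independently coded scalar oracles + gradients."""
import numpy as np
import pytest

from oracle_helpers import oracle_attend, oracle_compose, oracle_lstm_step

from aderex.neural import (
    AttentionParams,
    LSTMStepParams,
    NeuralConfig,
    NeuralNetwork,
    attend,
    attention_weights,
    compose_and_classify,
    lstm_step,
)

def _random_step_params(rng, k):
    mats = {f"W{i}": rng.normal(size=(k, k)) for i in range(1, 9)}
    biases = {f"b{i}": rng.normal(size=k) for i in range(1, 5)}
    return LSTMStepParams(**mats, **biases)


class TestLstmStep:
    def test_zero_weights_zero_state(self):
        k = 3
        p = LSTMStepParams(
            **{f"W{i}": np.zeros((k, k)) for i in range(1, 9)},
            **{f"b{i}": np.zeros(k) for i in range(1, 5)},
        )
        h, c = lstm_step(p, np.zeros(k), np.zeros(k), np.zeros(k))
        np.testing.assert_allclose(c, 0.0)
        np.testing.assert_allclose(h, 0.0)

    def test_zero_weights_halve_previous_cell(self):
        k = 3
        p = LSTMStepParams(
            **{f"W{i}": np.zeros((k, k)) for i in range(1, 9)},
            **{f"b{i}": np.zeros(k) for i in range(1, 5)},
        )
        c_prev = np.array([0.4, -0.6, 1.0])
        _, c = lstm_step(p, np.zeros(k), np.zeros(k), c_prev)
        np.testing.assert_allclose(c, 0.5 * c_prev)  # f = sigma(0) = 0.5

    def test_matches_scalar_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            k = 3
            p = _random_step_params(rng, k)
            x, h0, c0 = rng.normal(size=(3, k))
            h, c = lstm_step(p, x, h0, c0)
            oh, oc = oracle_lstm_step(p, x, h0, c0)
            np.testing.assert_allclose(h, oh, atol=1e-10)
            np.testing.assert_allclose(c, oc, atol=1e-10)

    def test_gates_bounded(self):
        rng = np.random.default_rng(7)
        k = 4
        p = _random_step_params(rng, k)
        h, c = lstm_step(p, rng.normal(size=k) * 5, rng.normal(size=k), rng.normal(size=k))
        assert np.all(np.abs(h) < 1.0)  # |h| = |o * tanh(c)| < 1

    def test_shape_mismatch_rejected(self):
        rng = np.random.default_rng(0)
        p = _random_step_params(rng, 3)
        with pytest.raises(ValueError):
            lstm_step(p, np.zeros(4), np.zeros(3), np.zeros(3))


class TestAttention:
    def _params(self, rng, k):
        return AttentionParams(
            W1=rng.normal(size=(k, k)), W2=rng.normal(size=(k, k)),
            W3=rng.normal(size=(k, k)), W4=rng.normal(size=(k, k)),
            w=rng.normal(size=k),
        )

    def test_single_column_full_weight(self):
        rng = np.random.default_rng(1)
        k = 3
        p = self._params(rng, k)
        S = rng.normal(size=(k, 1))
        a = attention_weights(p, S, S[:, 0])
        np.testing.assert_allclose(a, [1.0])

    def test_identical_columns_convexity(self):
        rng = np.random.default_rng(2)
        k = 3
        p = self._params(rng, k)
        col = rng.normal(size=k)
        S = np.tile(col[:, None], (1, 5))
        h = attend(p, S, col)
        expected = np.tanh(p.W3 @ col + p.W4 @ col)  # z = col for any a
        np.testing.assert_allclose(h, expected, atol=1e-12)

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(3)
        k, L = 4, 6
        p = self._params(rng, k)
        a = attention_weights(p, rng.normal(size=(k, L)), rng.normal(size=k))
        assert a.shape == (L,)
        assert np.all(a > 0)
        assert np.isclose(a.sum(), 1.0)

    def test_matches_scalar_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            k, L = 3, 4
            p = self._params(rng, k)
            S = rng.normal(size=(k, L))
            h_last = rng.normal(size=k)
            got = attend(p, S, h_last)
            expected, oa = oracle_attend(p, S.tolist(), h_last.tolist())
            np.testing.assert_allclose(got, expected, atol=1e-10)
            np.testing.assert_allclose(attention_weights(p, S, h_last), oa, atol=1e-10)


class TestComposeAndClassify:
    def test_zero_weights_uniform(self):
        W = np.zeros((5, 6))
        probs = compose_and_classify(W, np.zeros(5), np.ones(3), -np.ones(3))
        np.testing.assert_allclose(probs, 0.2)

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(5)
        W = rng.normal(size=(7, 10))
        probs = compose_and_classify(W, rng.normal(size=7), rng.normal(size=4),
                                     rng.normal(size=4), rng.normal(size=2))
        assert np.isclose(probs.sum(), 1.0, atol=1e-9)
        assert np.all(probs > 0)

    def test_matches_scalar_oracle(self):
        rng = np.random.default_rng(6)
        W = rng.normal(size=(4, 6))
        b = rng.normal(size=4)
        hl, hr = rng.normal(size=3), rng.normal(size=3)
        np.testing.assert_allclose(
            compose_and_classify(W, b, hl, hr),
            oracle_compose(W.tolist(), b.tolist(), hl.tolist(), hr.tolist()),
            atol=1e-10,
        )

    def test_width_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compose_and_classify(np.zeros((2, 5)), np.zeros(2), np.ones(3), np.ones(3))


class TestNetworkShapes:
    def test_bidirectional_output_width_doubles(self):
        rng = np.random.default_rng(0)
        E = rng.normal(size=(10, 6))
        ids = rng.integers(2, 10, size=(4, 5))
        for bi, width in ((False, 8), (True, 16)):
            cfg = NeuralConfig(hidden_size=8, window=5, embedding_dim=6,
                               bidirectional=bi, attention=True, input_dropout=0,
                               output_dropout=0, seed=0)
            net = NeuralNetwork(cfg, n_labels=3, embedding_matrix=E)
            assert net.params["att_l_W1"].shape == (width, width)
            assert net.params["att_l_w"].shape == (width,)
            probs, cache = net.forward(ids, ids)
            assert cache["Sl"].shape == (4, 5, width)
            assert probs.shape == (4, 3)
            np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_forward_deterministic_without_dropout(self):
        rng = np.random.default_rng(1)
        E = rng.normal(size=(10, 4))
        ids = rng.integers(0, 10, size=(3, 4))
        cfg = NeuralConfig(hidden_size=5, window=4, embedding_dim=4,
                           input_dropout=0, output_dropout=0, seed=2)
        net = NeuralNetwork(cfg, n_labels=4, embedding_matrix=E)
        p1, _ = net.forward(ids, ids)
        p2, _ = net.forward(ids, ids)
        np.testing.assert_array_equal(p1, p2)


class TestGradientCheck:
    @pytest.mark.parametrize(
        "flags",
        [
            {"bidirectional": False, "attention": False, "augmented": False},
            {"bidirectional": True, "attention": True, "augmented": True},
        ],
        ids=["plain-lstm", "bilstm-att-aug"],
    )
    def test_analytic_matches_numerical(self, flags):
        """Backprop gradients agree with central differences to 1e-4 relative."""
        rng = np.random.default_rng(11)
        k, L, d, V, Y = 3, 2, 4, 8, 3
        E = rng.normal(size=(V, d))
        cfg = NeuralConfig(hidden_size=k, window=L, embedding_dim=d,
                           input_dropout=0, output_dropout=0, l2=1e-3,
                           aug_embedding_dim=2, seed=5, **flags)
        net = NeuralNetwork(cfg, n_labels=Y, embedding_matrix=E)
        B = 3
        ids_l = rng.integers(0, V, size=(B, L))
        ids_r = rng.integers(0, V, size=(B, L))
        ids_l[0, 0] = 1  # exercise the learned-UNK path
        aug = rng.integers(0, 3, size=(B, 4)) if flags["augmented"] else None
        labels = rng.integers(0, Y, size=B)

        def loss_fn():
            loss, _ = net.loss_and_grads(ids_l, ids_r, labels, aug, train=False)
            return loss

        _, grads = net.loss_and_grads(ids_l, ids_r, labels, aug, train=False)
        eps = 1e-6
        check_rng = np.random.default_rng(0)
        worst = 0.0
        for key, arr in net.params.items():
            flat = arr.reshape(-1)
            n_check = min(flat.size, 25)
            for idx in check_rng.choice(flat.size, size=n_check, replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                up = loss_fn()
                flat[idx] = orig - eps
                down = loss_fn()
                flat[idx] = orig
                num = (up - down) / (2 * eps)
                ana = grads[key].reshape(-1)[idx]
                rel = abs(num - ana) / max(1e-8, abs(num) + abs(ana))
                worst = max(worst, rel)
        assert worst < 1e-4
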