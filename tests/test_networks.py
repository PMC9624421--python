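import numpy as np
import pytest

from osteoscreen import networks as nk
from tests.conftest import finite_difference_gradient


def small_spec(kind="feedforward", depth=1, ae=None):
    return nk.NetworkSpec(kind, depth, hidden_units=6, autoencoder_units=ae,
                          input_dim=5, output_dim=3)


def random_batch(spec, rng, n=4):
    X = rng.uniform(0, 1, size=(n, spec.input_dim))
    Y = rng.uniform(0, 1, size=(n, spec.output_dim))
    mask = rng.uniform(size=Y.shape) < 0.7
    mask[:, 0] = True
    return X, Y, mask


class TestSpecsAndInit:
    def test_sixteen_candidate_types(self):
        specs = nk.candidate_network_specs()
        assert len(specs) == 16
        labels = {s.label for s in specs}
        assert "ff0" in labels and "recurrent+ae50" in labels
        assert len(labels) == 16

    def test_init_deterministic(self):
        spec = small_spec(ae=4)
        a, b = nk.init_network(spec, 3), nk.init_network(spec, 3)
        assert np.array_equal(a.pack(), b.pack())
        assert np.array_equal(a.encoder[0], b.encoder[0])

    def test_depth_zero_shapes(self):
        ws = nk.init_network(nk.NetworkSpec("feedforward", 0), 0)
        assert len(ws.weights) == 1
        assert ws.weights[0].shape == (17, 26)
        assert ws.biases[0].shape == (26,)
        assert ws.encoder is None

    def test_autoencoder_chain_shapes(self):
        spec = nk.NetworkSpec("feedforward", 2, hidden_units=100,
                              autoencoder_units=50)
        ws = nk.init_network(spec, 0)
        assert ws.encoder[0].shape == (17, 50)
        assert [w.shape for w in ws.weights] == [(50, 100), (100, 100),
                                                 (100, 26)]

    def test_init_range_and_zero_biases(self):
        ws = nk.init_network(small_spec(), 5)
        r = 1 / np.sqrt(5)
        assert np.all(np.abs(ws.weights[0]) <= r)
        assert np.all(ws.biases[0] == 0)

    def test_serialization_roundtrip(self, rng):
        spec = small_spec("recurrent", ae=4)
        ws = nk.init_network(spec, 2)
        back = nk.WeightSet.from_dict(ws.to_dict())
        assert np.array_equal(ws.pack(), back.pack())
        assert np.array_equal(ws.encoder[0], back.encoder[0])


class TestForward:
    def test_zero_weights_give_half_activation(self):
        ws = nk.init_network(small_spec(depth=2), 0)
        ws.unpack(np.zeros(ws.pack().size))
        out = nk.forward(ws, np.zeros((2, 5))).output
        np.testing.assert_array_equal(out, 0.5)

    def test_hand_calculation_two_inputs(self):
        spec = nk.NetworkSpec("feedforward", 0, input_dim=2, output_dim=1)
        ws = nk.init_network(spec, 0)
        ws.weights[0][:] = np.array([[1.0], [-1.0]])
        ws.biases[0][:] = 0.0
        assert nk.forward(ws, [[1.0, 1.0]]).output[0, 0] == pytest.approx(0.5)

    def test_matches_straight_line_reference(self, rng):
        """Layer-by-layer loop re-evaluation agrees to 1e-12."""
        spec = nk.NetworkSpec("feedforward", 2, hidden_units=100,
                              autoencoder_units=50)
        ws = nk.init_network(spec, 7)
        x = rng.uniform(0, 1, size=(1, 17))
        a = 1.0 / (1.0 + np.exp(-(x @ ws.encoder[0] + ws.encoder[1])))
        for w, b in zip(ws.weights, ws.biases):
            a = 1.0 / (1.0 + np.exp(-(a @ w + b)))
        np.testing.assert_allclose(nk.forward(ws, x).output, a, atol=1e-12)

    def test_activations_bounded(self, rng):
        ws = nk.init_network(small_spec("recurrent"), 1)
        acts = nk.forward(ws, rng.uniform(0, 1, size=(3, 5)))
        for layer in acts.layers[1:]:
            assert np.all((layer > 0) & (layer < 1))

    def test_recurrent_settles_to_fixed_point(self, rng):
        ws = nk.init_network(small_spec("recurrent"), 4)
        x = rng.uniform(0, 1, size=(2, 5))
        acts = nk.forward(ws, x)
        s = acts.settled_state
        z = x @ ws.weights[0] + s @ ws.w_rec + ws.biases[0]
        np.testing.assert_allclose(nk.sigmoid(z), s, atol=1e-7)

    def test_recurrent_oscillation_raises(self):
        spec = nk.NetworkSpec("recurrent", 1, hidden_units=2,
                              input_dim=2, output_dim=1)
        ws = nk.init_network(spec, 0)
        ws.weights[0][:] = 0.0
        ws.w_rec[:] = [[-100.0, 0.0], [0.0, -100.0]]
        ws.biases[0][:] = 40.0  # period-2 flip-flop, never settles
        with pytest.raises(nk.SettlingError):
            nk.forward(ws, [[0.0, 0.0]])


class TestGradients:
    @pytest.mark.parametrize("kind,depth,ae", [
        ("feedforward", 0, None), ("feedforward", 0, 4),
        ("feedforward", 3, None), ("feedforward", 2, 4),
        ("recurrent", 1, None), ("recurrent", 1, 4),
    ])
    def test_matches_central_finite_differences(self, kind, depth, ae, rng):
        spec = small_spec(kind, depth, ae)
        ws = nk.init_network(spec, 9)
        X, Y, mask = random_batch(spec, rng)
        _, grad = nk.loss_and_gradient(ws, X, Y, mask)
        fd = finite_difference_gradient(ws, X, Y, mask)
        g = grad.pack()
        assert np.linalg.norm(g - fd) / np.linalg.norm(fd) < 1e-6

    def test_perfect_prediction_zero_loss_zero_gradient(self, rng):
        spec = small_spec()
        ws = nk.init_network(spec, 1)
        X = rng.uniform(0, 1, size=(3, 5))
        Y = nk.forward(ws, X).output
        mask = np.ones_like(Y, dtype=bool)
        loss, grad = nk.loss_and_gradient(ws, X, Y, mask)
        assert loss == 0.0
        assert np.all(grad.pack() == 0.0)

    def test_fully_masked_pattern_contributes_nothing(self, rng):
        spec = small_spec(depth=2)
        ws = nk.init_network(spec, 1)
        X = rng.uniform(0, 1, size=(2, 5))
        Y = rng.uniform(0, 1, size=(2, 3))
        loss, grad = nk.loss_and_gradient(ws, X, Y, np.zeros((2, 3), bool))
        assert loss == 0.0
        assert np.all(grad.pack() == 0.0)

    def test_delta_rule_specialisation(self, rng):
        """Depth-0 backprop equals the textbook delta rule computed directly."""
        spec = nk.NetworkSpec("feedforward", 0, input_dim=4, output_dim=3)
        ws = nk.init_network(spec, 2)
        X = rng.uniform(0, 1, size=(1, 4))
        Y = rng.uniform(0, 1, size=(1, 3))
        mask = np.ones((1, 3), bool)
        _, grad = nk.loss_and_gradient(ws, X, Y, mask)
        o = nk.sigmoid(X @ ws.weights[0] + ws.biases[0])
        delta = (o - Y) * o * (1 - o)
        np.testing.assert_allclose(grad.weights[0], X.T @ delta, atol=1e-14)
        np.testing.assert_allclose(grad.biases[0], delta[0], atol=1e-14)


class TestUpdatesAndPretraining:
    def test_zero_learning_rate_is_identity(self, rng):
        spec = small_spec()
        ws = nk.init_network(spec, 0)
        before = ws.pack()
        X, Y, mask = random_batch(spec, rng)
        nk.sgd_step(ws, X, Y, mask, learning_rate=0.0)
        assert np.array_equal(ws.pack(), before)

    def test_duplicated_pattern_batch_equals_single(self, rng):
        spec = small_spec()
        X, Y, mask = random_batch(spec, rng, n=1)
        a = nk.init_network(spec, 0)
        b = nk.init_network(spec, 0)
        nk.sgd_step(a, X, Y, mask, 0.3)
        nk.sgd_step(b, np.repeat(X, 2, 0), np.repeat(Y, 2, 0),
                    np.repeat(mask, 2, 0), 0.3)
        np.testing.assert_allclose(a.pack(), b.pack(), atol=1e-14)

    def test_small_step_decreases_batch_loss(self, rng):
        spec = small_spec(depth=2)
        ws = nk.init_network(spec, 3)
        X, Y, mask = random_batch(spec, rng)
        loss0, _ = nk.loss_and_gradient(ws, X, Y, mask)
        nk.sgd_step(ws, X, Y, mask, 0.01)
        loss1, _ = nk.loss_and_gradient(ws, X, Y, mask)
        assert loss1 < loss0

    def test_autoencoder_pretraining_deterministic_and_shaped(self, rng):
        X = rng.uniform(0, 1, size=(30, 5))
        w, b = nk.pretrain_autoencoder(X, 4, iterations=2000, seed=0)
        w2, b2 = nk.pretrain_autoencoder(X, 4, iterations=2000, seed=0)
        assert w.shape == (5, 4) and b.shape == (4,)
        assert np.array_equal(w, w2) and np.array_equal(b, b2)
        assert not np.array_equal(
            w, nk.pretrain_autoencoder(X, 4, iterations=2000, seed=1)[0])

    def test_capacity_sufficient_autoencoder_fits_well(self, rng):
        X = rng.uniform(0.1, 0.9, size=(20, 4))
        spec = nk.NetworkSpec("feedforward", 1, hidden_units=6,
                              input_dim=4, output_dim=4)
        ws = nk.init_network(spec, 1)
        rms0 = nk.reconstruction_rms(ws, X)
        mask = np.ones_like(X, dtype=bool)
        rng2 = np.random.default_rng(0)
        for _ in range(4000):
            idx = rng2.integers(0, len(X), size=8)
            nk.sgd_step(ws, X[idx], X[idx], mask[:8], 1.0)
        rms1 = nk.reconstruction_rms(ws, X)
        assert rms1 < rms0
        assert rms1 < 0.05

    def test_frozen_encoder_untouched_by_updates(self, rng):
        spec = small_spec(depth=2, ae=4)
        ws = nk.init_network(spec, 6)
        enc_w = ws.encoder[0].copy()
        enc_b = ws.encoder[1].copy()
        X, Y, mask = random_batch(spec, rng)
        for _ in range(50):
            nk.sgd_step(ws, X, Y, mask, 0.5)
        assert np.array_equal(ws.encoder[0], enc_w)
        assert np.array_equal(ws.encoder[1], enc_b)
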