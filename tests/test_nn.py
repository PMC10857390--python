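"""Network layers against brute-force loops and numerical gradients."""

import numpy as np
import pytest

from gaitforce.nn import (
    LSTM,
    Conv1D,
    LinearUpsample,
    MaxPool1D,
    ModelSpec,
    TimeDense,
    TrainConfig,
    build_model,
    conv_forward,
    max_pool,
    predict,
    train,
)
from gaitforce.nn.network import mae_loss


def brute_conv(x, w, bias=0.0, stride=1):
    """Loop implementation of valid cross-correlation, one channel."""
    K = len(w)
    out = []
    t = 0
    while t + K <= len(x):
        out.append(sum(x[t + k] * w[k] for k in range(K)) + bias)
        t += stride
    return np.array(out)


def numerical_grad(f, x, eps=1e-6):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        old = x[i]
        x[i] = old + eps
        fp = f()
        x[i] = old - eps
        fm = f()
        x[i] = old
        g[i] = (fp - fm) / (2 * eps)
        it.iternext()
    return g


class TestConvForward:
    def test_identity_tap_kernel(self):
        out = conv_forward([1.0, 2.0, 3.0], [0.0, 1.0, 0.0],
                           activation=None)
        assert np.allclose(out, [2.0])

    def test_edge_kernel_with_relu_clips_negatives(self):
        out = conv_forward([1.0, 2.0, 3.0, 4.0], [1.0, 0.0, -1.0],
                           activation="relu")
        # pre-activation is [-2, -2]
        assert np.allclose(out, [0.0, 0.0])

    def test_positive_bias_passes_relu_unchanged(self):
        pre = conv_forward([0.1, 0.2, 0.3, 0.4], [1.0, 1.0], bias=10.0,
                           activation=None)
        post = conv_forward([0.1, 0.2, 0.3, 0.4], [1.0, 1.0], bias=10.0,
                            activation="relu")
        assert np.all(post > 0)
        assert np.allclose(pre, post)

    def test_agrees_with_brute_force_on_random_inputs(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 30))
            k = int(rng.integers(1, 5))
            stride = int(rng.integers(1, 3))
            x = rng.standard_normal(n)
            w = rng.standard_normal(k)
            b = float(rng.standard_normal())
            got = conv_forward(x, w, bias=b, stride=stride,
                               activation=None)
            assert np.allclose(got, brute_conv(x, w, b, stride),
                               atol=1e-10)

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            conv_forward([1.0, 2.0], [1.0, 1.0, 1.0])


class TestMaxPool:
    def test_windowed_max(self):
        assert np.allclose(max_pool([1.0, 3.0, 2.0]), [3.0, 3.0])

    def test_constant_input_unchanged(self):
        assert np.allclose(max_pool([5.0] * 10), [5.0] * 9)

    def test_output_length_formula(self, rng):
        x = rng.standard_normal(100)
        assert max_pool(x, pool_size=2, stride=1).shape == (99,)
        assert max_pool(x, pool_size=2, stride=2).shape == (50,)

    def test_agrees_with_brute_force(self, rng):
        x = rng.standard_normal(37)
        got = max_pool(x, pool_size=3, stride=2)
        expected = [max(x[t:t + 3]) for t in range(0, 35, 2)]
        assert np.allclose(got, expected, atol=1e-12)


class TestGradients:
    """Analytic backward passes against central finite differences."""

    @pytest.mark.parametrize("layer_factory", [
        lambda rng: Conv1D(3, 4, 3, 1, "relu", rng),
        lambda rng: Conv1D(3, 4, 3, 2, "relu", rng),
        lambda rng: Conv1D(3, 4, 3, 1, None, rng),
        lambda rng: MaxPool1D(2, 1),
        lambda rng: LSTM(3, 5, rng),
        lambda rng: TimeDense(3, 4, rng),
        lambda rng: LinearUpsample(20),
    ], ids=["conv", "conv-stride2", "conv-linear", "pool", "lstm",
            "dense", "upsample"])
    def test_layer_gradients(self, layer_factory):
        rng = np.random.default_rng(0)
        layer = layer_factory(rng)
        x = rng.standard_normal((2, 12, 3))

        def loss():
            return float(np.sum(np.sin(layer.forward(x))))

        y = layer.forward(x)
        dx = layer.backward(np.cos(y))
        assert np.abs(dx - numerical_grad(loss, x)).max() < 1e-7
        for name in layer.params:
            num = numerical_grad(loss, layer.params[name])
            assert np.abs(layer.grads[name] - num).max() < 1e-7, name

    @pytest.mark.parametrize("kind", ["cnn", "lstm", "cnn_lstm"])
    def test_end_to_end_gradient_through_mae(self, kind):
        rng = np.random.default_rng(1)
        # reduced layer widths keep the finite-difference sweep tractable
        spec = ModelSpec(kind=kind, conv_kernels=(4, 6), lstm_units=6,
                         cnn_lstm_kernels=5)
        net = build_model(spec, 30, 5, seed=2)
        x = rng.standard_normal((2, 30, 5))
        y = rng.standard_normal((2, 30, 4))

        def loss():
            return float(np.mean(np.abs(net.forward(x) - y)))

        pred = net.forward(x)
        _, dloss = mae_loss(pred, y)
        net.backward(dloss)
        layer = net.layers[0]
        name = sorted(layer.params)[0]
        num = numerical_grad(loss, layer.params[name])
        assert np.abs(layer.grads[name] - num).max() < 1e-7


class TestBuildModel:
    def test_cnn_has_two_conv_and_two_pool_stages(self):
        net = build_model(ModelSpec(kind="cnn"), 100, 16, seed=0)
        convs = [l for l in net.layers if isinstance(l, Conv1D)]
        pools = [l for l in net.layers if isinstance(l, MaxPool1D)]
        assert len(convs) == 2 and len(pools) == 2
        assert convs[0].params["W"].shape[2] == 64
        assert convs[1].params["W"].shape[2] == 128

    def test_lstm_has_two_recurrent_layers_of_128(self):
        net = build_model(ModelSpec(kind="lstm"), 100, 16, seed=0)
        lstms = [l for l in net.layers if isinstance(l, LSTM)]
        assert len(lstms) == 2
        assert all(l.hidden == 128 for l in lstms)

    def test_cnn_lstm_is_strided_conv_into_lstm(self):
        net = build_model(ModelSpec(kind="cnn_lstm"), 100, 16, seed=0)
        assert isinstance(net.layers[0], Conv1D)
        assert net.layers[0].stride == 2
        assert isinstance(net.layers[1], LSTM)

    def test_same_seed_gives_identical_initial_parameters(self):
        a = build_model(ModelSpec(kind="cnn_lstm"), 100, 16, seed=5)
        b = build_model(ModelSpec(kind="cnn_lstm"), 100, 16, seed=5)
        for (ka, pa), (kb, pb) in zip(a.parameters(), b.parameters()):
            assert ka == kb and np.array_equal(pa, pb)

    def test_output_shape_is_input_length_by_four(self, rng):
        for kind in ("cnn", "lstm", "cnn_lstm"):
            net = build_model(ModelSpec(kind=kind), 60, 16, seed=0)
            y = net.forward(rng.standard_normal((3, 60, 16)))
            assert y.shape == (3, 60, 4)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            ModelSpec(kind="transformer")


class TestTraining:
    def test_constant_target_learned_within_50_epochs(self, rng):
        X = rng.uniform(-1, 1, (32, 20, 16))
        Y = np.full((32, 20, 4), 0.5)
        net = build_model(ModelSpec(kind="cnn_lstm"), 20, 16, seed=0)
        hist = train(net, (X, Y), None,
                     TrainConfig(epochs=50, batch_size=8, seed=0))
        assert hist["train_mae"][-1] < 0.01

    def test_identical_seeds_give_identical_histories(self, rng):
        X = rng.uniform(-1, 1, (16, 20, 16))
        Y = rng.uniform(0, 1, (16, 20, 4))
        hists = []
        for _ in range(2):
            net = build_model(ModelSpec(kind="cnn_lstm"), 20, 16, seed=3)
            hists.append(train(net, (X, Y), None,
                               TrainConfig(epochs=5, batch_size=8,
                                           seed=3)))
        assert hists[0]["train_mae"] == hists[1]["train_mae"]

    def test_loss_decreases_on_learnable_data(self, rng):
        X = rng.uniform(-1, 1, (16, 20, 16))
        Y = np.tanh(X[:, :, :4])
        net = build_model(ModelSpec(kind="cnn_lstm"), 20, 16, seed=1)
        hist = train(net, (X, Y), None,
                     TrainConfig(epochs=50, batch_size=8, seed=1))
        assert hist["train_mae"][-1] < hist["train_mae"][0]

    def test_empty_training_set_rejected(self):
        net = build_model(ModelSpec(kind="lstm"), 20, 16, seed=0)
        with pytest.raises(ValueError, match="empty"):
            train(net, (np.empty((0, 20, 16)), np.empty((0, 20, 4))),
                  None, TrainConfig(epochs=1))

    def test_prediction_is_deterministic_and_nonnegative_pipeline(
            self, rng):
        net = build_model(ModelSpec(kind="lstm"), 20, 16, seed=0)
        x = rng.standard_normal((4, 20, 16))
        assert np.array_equal(predict(net, x), predict(net, x))
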