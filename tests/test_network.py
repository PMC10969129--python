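"""Numeric-gradient checks for the CNN engine.

Every layer's backward pass is verified against central finite differences;
these are the load-bearing tests for everything trained downstream.
"""

import numpy as np
import pytest

from alshift.errors import ConfigurationError
from alshift.network import (
    Adagrad,
    Conv2D,
    Dense,
    GlobalAvgPool,
    MaxPool2,
    ReLU,
    SmallCNN,
    softmax,
    softmax_cross_entropy,
)


# eps is large because layer forwards run in float32; central-difference
# truncation error O(eps^2) stays well under the assertion tolerances
def numeric_grad(f, x, eps=1e-3):
    g = np.zeros_like(x, dtype=np.float64)
    flat = x.reshape(-1)
    gf = g.reshape(-1)
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        fp = f()
        flat[i] = orig - eps
        fm = f()
        flat[i] = orig
        gf[i] = (fp - fm) / (2 * eps)
    return g


class TestConv2D:
    def test_forward_matches_direct_convolution(self):
        rng = np.random.default_rng(0)
        layer = Conv2D(2, 3, 3, "c", rng)
        x = rng.standard_normal((1, 2, 5, 5)).astype(np.float32)
        out = layer.forward(x)
        # direct dot product at an interior location
        i, j, f = 2, 3, 1
        patch = x[0, :, i - 1:i + 2, j - 1:j + 2]
        expected = float((patch * layer.W[f]).sum() + layer.b[f])
        assert out[0, f, i, j] == pytest.approx(expected, rel=1e-5)

    def test_input_gradient_numeric(self):
        rng = np.random.default_rng(1)
        layer = Conv2D(2, 2, 3, "c", rng)
        x = rng.standard_normal((2, 2, 4, 4)).astype(np.float64)
        dy = rng.standard_normal((2, 2, 4, 4)).astype(np.float64)

        def loss():
            return float((layer.forward(x.astype(np.float32), train=True) * dy).sum())

        loss()  # populate cache
        dx = layer.backward(dy.astype(np.float32))
        num = numeric_grad(loss, x)
        assert np.allclose(dx, num, atol=1e-3)

    def test_weight_gradient_numeric(self):
        rng = np.random.default_rng(2)
        layer = Conv2D(1, 2, 3, "c", rng)
        x = rng.standard_normal((2, 1, 4, 4)).astype(np.float32)
        dy = rng.standard_normal((2, 2, 4, 4)).astype(np.float64)

        def loss():
            return float((layer.forward(x, train=True) * dy).sum())

        loss()
        layer.backward(dy.astype(np.float32))
        dW, db = layer.dW.copy(), layer.db.copy()
        num_W = numeric_grad(loss, layer.W)
        assert np.allclose(dW, num_W, atol=1e-3)
        num_b = numeric_grad(loss, layer.b)
        assert np.allclose(db, num_b, atol=1e-3)

    def test_even_kernel_rejected(self):
        with pytest.raises(ConfigurationError):
            Conv2D(1, 1, 4, "c", np.random.default_rng(0))


class TestPoolingAndDense:
    def test_maxpool_forward(self):
        x = np.arange(16, dtype=np.float32).reshape(1, 1, 4, 4)
        out = MaxPool2("p").forward(x)
        assert np.array_equal(out[0, 0], [[5, 7], [13, 15]])

    def test_maxpool_gradient_numeric(self):
        rng = np.random.default_rng(3)
        layer = MaxPool2("p")
        x = rng.standard_normal((1, 2, 4, 4)).astype(np.float64)
        dy = rng.standard_normal((1, 2, 2, 2)).astype(np.float64)

        def loss():
            return float((layer.forward(x.astype(np.float32), train=True) * dy).sum())

        loss()
        dx = layer.backward(dy.astype(np.float32))
        assert np.allclose(dx, numeric_grad(loss, x), atol=1e-3)

    def test_gap_gradient_numeric(self):
        rng = np.random.default_rng(4)
        layer = GlobalAvgPool("g")
        x = rng.standard_normal((2, 3, 4, 4)).astype(np.float64)
        dy = rng.standard_normal((2, 3)).astype(np.float64)

        def loss():
            return float((layer.forward(x.astype(np.float32), train=True) * dy).sum())

        loss()
        dx = layer.backward(dy.astype(np.float32))
        assert np.allclose(dx, numeric_grad(loss, x), atol=1e-4)

    def test_dense_gradients_numeric(self):
        rng = np.random.default_rng(5)
        layer = Dense(4, 3, "d", rng)
        x = rng.standard_normal((5, 4)).astype(np.float64)
        dy = rng.standard_normal((5, 3)).astype(np.float64)

        def loss():
            return float((layer.forward(x.astype(np.float32), train=True) * dy).sum())

        loss()
        dx = layer.backward(dy.astype(np.float32))
        dW = layer.dW.copy()
        assert np.allclose(dx, numeric_grad(loss, x), atol=1e-3)
        assert np.allclose(dW, numeric_grad(loss, layer.W), atol=1e-3)

    def test_relu_gradient(self):
        layer = ReLU("r")
        x = np.array([[-1.0, 0.5], [2.0, -0.1]], dtype=np.float32)
        layer.forward(x, train=True)
        dy = np.ones_like(x)
        assert np.array_equal(layer.backward(dy), [[0, 1], [1, 0]])


class TestSoftmaxLoss:
    def test_softmax_rows_sum_to_one(self):
        rng = np.random.default_rng(6)
        p = softmax(rng.standard_normal((10, 2)) * 5)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-12)

    def test_loss_gradient_numeric(self):
        rng = np.random.default_rng(7)
        logits = rng.standard_normal((6, 2)).astype(np.float64)
        labels = np.array([0, 1, 1, 0, 1, 0])

        def loss():
            return softmax_cross_entropy(logits, labels)[0]

        _, grad = softmax_cross_entropy(logits, labels)
        assert np.allclose(grad, numeric_grad(loss, logits, eps=1e-4), atol=1e-6)

    def test_uniform_prediction_loss_is_log2(self):
        loss, _ = softmax_cross_entropy(np.zeros((4, 2)), np.array([0, 1, 0, 1]))
        assert loss == pytest.approx(np.log(2))


class TestSmallCNNEndToEnd:
    def test_full_network_gradient_numeric(self):
        net = SmallCNN((4, 4, 1), conv_filters=(2,), kernel_size=3, n_classes=2, seed=0)
        # give the zero head weights so gradients reach the conv stack
        net.layers[-1].W[...] = np.random.default_rng(1).standard_normal(
            net.layers[-1].W.shape
        ).astype(np.float32)
        rng = np.random.default_rng(2)
        x = rng.uniform(size=(3, 1, 4, 4)).astype(np.float64)
        y = np.array([0, 1, 0])

        def loss():
            logits = net.forward(x.astype(np.float32), train=True)
            return softmax_cross_entropy(logits, y)[0]

        l0 = loss()
        _, dlogits = softmax_cross_entropy(net.forward(x.astype(np.float32), train=True), y)
        net.backward(dlogits)
        grads = {k: v.copy() for k, v in net.grads().items()}
        params = net.params()
        for name in ("conv1.W", "conv1.b", "head.W", "head.b"):
            num = numeric_grad(loss, params[name])
            assert np.allclose(grads[name], num, atol=1e-3), name

    def test_input_shape_checked(self):
        net = SmallCNN((8, 8, 3), (4,), 3, 2, seed=0)
        with pytest.raises(ConfigurationError):
            net.forward(np.zeros((1, 3, 4, 4), dtype=np.float32))

    def test_odd_input_size_rejected(self):
        with pytest.raises(ConfigurationError):
            SmallCNN((7, 7, 3), (4,), 3, 2, seed=0)

    def test_weight_round_trip(self):
        net = SmallCNN((8, 8, 3), (4, 8), 3, 2, seed=5)
        w = net.get_weights()
        other = SmallCNN((8, 8, 3), (4, 8), 3, 2, seed=99)
        other.set_weights(w)
        x = np.random.default_rng(0).uniform(size=(2, 3, 8, 8)).astype(np.float32)
        assert np.array_equal(net.predict_proba(x), other.predict_proba(x))


class TestAdagrad:
    def test_update_matches_hand_computation(self):
        opt = Adagrad(learning_rate=0.5, initial_accumulator=0.1, epsilon=1e-7)
        p = {"w": np.array([1.0, 2.0], dtype=np.float32)}
        g = {"w": np.array([0.3, -0.4], dtype=np.float32)}
        opt.step(p, g)
        acc = 0.1 + np.array([0.09, 0.16])
        expected = np.array([1.0, 2.0]) - 0.5 * np.array([0.3, -0.4]) / (np.sqrt(acc) + 1e-7)
        assert np.allclose(p["w"], expected, atol=1e-6)

    def test_accumulator_state_round_trip(self):
        opt = Adagrad(0.1)
        p = {"w": np.ones(3, dtype=np.float32)}
        opt.step(p, {"w": np.ones(3, dtype=np.float32)})
        saved = opt.state()
        opt2 = Adagrad(0.1)
        opt2.load_state(saved)
        assert np.array_equal(opt2.acc["w"], opt.acc["w"])
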