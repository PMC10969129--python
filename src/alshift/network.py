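"""Minimal CNN engine in numpy: forward, backprop, Adagrad.

Implements exactly the pieces the desk-scale classifier needs — 'same'
convolution (im2col backed by BLAS matmul), ReLU, 2x2 max pooling, global
average pooling, a dense head, softmax cross-entropy and the Adagrad update.
All computation is float32; determinism on a fixed platform follows from
seeded initialization and a fixed reduction order.

Layers cache what their backward pass needs on forward; ``backward`` also
records the gradient with respect to each layer's *output*, which is what
Grad-CAM reads off intermediate feature maps.

Tensor layout is NCHW.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ConfigurationError


class Layer:
    name: str = ""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> dict[str, np.ndarray]:
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}


class Conv2D(Layer):
    """3x3-style 'same' convolution, stride 1, via im2col."""

    def __init__(self, in_ch: int, out_ch: int, ksize: int, name: str,
                 rng: np.random.Generator | None = None):
        if ksize % 2 != 1:
            raise ConfigurationError("kernel size must be odd for 'same' padding")
        self.in_ch, self.out_ch, self.ksize, self.name = in_ch, out_ch, ksize, name
        fan_in = in_ch * ksize * ksize
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        if rng is None:
            self.W = np.zeros((out_ch, in_ch, ksize, ksize), dtype=np.float32)
        else:
            self.W = (rng.standard_normal((out_ch, in_ch, ksize, ksize)) * scale).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._xshape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.in_ch:
            raise ConfigurationError(
                f"layer {self.name}: expected {self.in_ch} input channels, got {c}"
            )
        p = self.ksize // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        # (N, C, H, W, k, k) -> rows are receptive fields
        win = sliding_window_view(xp, (self.ksize, self.ksize), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, -1)
        out = cols @ self.W.reshape(self.out_ch, -1).T + self.b
        if train:
            self._cols, self._xshape = cols, x.shape
        return np.ascontiguousarray(
            out.reshape(n, h, w, self.out_ch).transpose(0, 3, 1, 2)
        )

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._cols is not None and self._xshape is not None
        n, c, h, w = self._xshape
        k, p = self.ksize, self.ksize // 2
        dyf = dy.transpose(0, 2, 3, 1).reshape(n * h * w, self.out_ch)
        self.dW = (dyf.T @ self._cols).reshape(self.W.shape).astype(np.float32)
        self.db = dyf.sum(axis=0).astype(np.float32)
        dcols = dyf @ self.W.reshape(self.out_ch, -1)  # (N*H*W, C*k*k)
        dcols = dcols.reshape(n, h, w, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + h, j:j + w] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        self._cols = None
        return dxp[:, :, p:p + h, p:p + w]

    def params(self) -> dict[str, np.ndarray]:
        return {f"{self.name}.W": self.W, f"{self.name}.b": self.b}

    def grads(self) -> dict[str, np.ndarray]:
        return {f"{self.name}.W": self.dW, f"{self.name}.b": self.db}


class ReLU(Layer):
    def __init__(self, name: str):
        self.name = name
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._mask is not None
        return dy * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2.  Ties route gradient to every maximum."""

    def __init__(self, name: str):
        self.name = name
        self._cache: tuple[np.ndarray, np.ndarray] | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ConfigurationError(f"layer {self.name}: spatial dims must be even, got {h}x{w}")
        win = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = win.max(axis=(3, 5))
        if train:
            self._cache = (x, out)
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._cache is not None
        x, out = self._cache
        n, c, h, w = x.shape
        win = x.reshape(n, c, h // 2, 2, w // 2, 2)
        mask = win == out[:, :, :, None, :, None]
        dwin = mask * dy[:, :, :, None, :, None]
        return dwin.reshape(n, c, h, w)


class GlobalAvgPool(Layer):
    def __init__(self, name: str):
        self.name = name
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._shape is not None
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None] / (h * w), self._shape).astype(np.float32)


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, name: str,
                 rng: np.random.Generator | None = None):
        self.name = name
        if rng is None:  # zero-initialized head: fresh nets predict 0.5/0.5
            self.W = np.zeros((in_dim, out_dim), dtype=np.float32)
        else:
            scale = np.sqrt(2.0 / in_dim)
            self.W = (rng.standard_normal((in_dim, out_dim)) * scale).astype(np.float32)
        self.b = np.zeros(out_dim, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.shape[1] != self.W.shape[0]:
            raise ConfigurationError(
                f"layer {self.name}: expected input dim {self.W.shape[0]}, got {x.shape[1]}"
            )
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._x is not None
        self.dW = (self._x.T @ dy).astype(np.float32)
        self.db = dy.sum(axis=0).astype(np.float32)
        return dy @ self.W.T

    def params(self) -> dict[str, np.ndarray]:
        return {f"{self.name}.W": self.W, f"{self.name}.b": self.b}

    def grads(self) -> dict[str, np.ndarray]:
        return {f"{self.name}.W": self.dW, f"{self.name}.b": self.db}


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and gradient w.r.t. logits."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    loss = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean()
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), (grad / n).astype(np.float32)


class SmallCNN:
    """Conv blocks (conv-ReLU-maxpool), GAP, 2-unit dense head."""

    def __init__(self, input_size: tuple[int, int, int], conv_filters: tuple[int, ...],
                 kernel_size: int, n_classes: int, seed: int | None):
        h, w, c = input_size
        for _ in conv_filters:
            if h % 2 or w % 2:
                raise ConfigurationError(
                    f"input size {input_size} not divisible by 2^{len(conv_filters)}"
                )
            h, w = h // 2, w // 2
        rng = None if seed is None else np.random.default_rng(seed)
        self.input_size = tuple(input_size)
        self.layers: list[Layer] = []
        in_ch = c
        for i, f in enumerate(conv_filters, start=1):
            self.layers.append(Conv2D(in_ch, f, kernel_size, f"conv{i}", rng))
            self.layers.append(ReLU(f"relu{i}"))
            self.layers.append(MaxPool2(f"pool{i}"))
            in_ch = f
        self.layers.append(GlobalAvgPool("gap"))
        # head is zero-initialized regardless of seed (symmetric start)
        self.layers.append(Dense(in_ch, n_classes, "head", rng=None))
        self.conv_names = [ly.name for ly in self.layers if isinstance(ly, Conv2D)]
        self._last_outputs: dict[str, np.ndarray] = {}
        self._output_grads: dict[str, np.ndarray] = {}

    # -- forward / backward -------------------------------------------------
    def _check_input(self, x: np.ndarray) -> None:
        h, w, c = self.input_size
        if x.ndim != 4 or x.shape[1:] != (c, h, w):
            raise ConfigurationError(
                f"expected input batch of shape (N, {c}, {h}, {w}), got {x.shape}"
            )

    #: fixed input centering constant; keeps He-init assumptions honest for
    #: [0, 1] images and stabilizes optimization (not data-dependent)
    INPUT_CENTER = 0.5

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._check_input(x)
        out = x.astype(np.float32, copy=False) - np.float32(self.INPUT_CENTER)
        self._last_outputs = {}
        for ly in self.layers:
            out = ly.forward(out, train=train)
            if train:
                self._last_outputs[ly.name] = out
        return out

    def backward(self, dlogits: np.ndarray) -> None:
        self._output_grads = {}
        dy = dlogits
        for ly in reversed(self.layers):
            self._output_grads[ly.name] = dy
            dy = ly.backward(dy)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x, train=False).astype(np.float64))

    # -- parameter access ---------------------------------------------------
    def params(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for ly in self.layers:
            out.update(ly.params())
        return out

    def grads(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for ly in self.layers:
            out.update(ly.grads())
        return out

    def get_weights(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params().items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        params = self.params()
        if set(weights) != set(params):
            raise ConfigurationError(
                f"weight keys {sorted(weights)} do not match architecture {sorted(params)}"
            )
        for k, v in weights.items():
            if params[k].shape != v.shape:
                raise ConfigurationError(f"shape mismatch for {k}")
            params[k][...] = v

    # -- Grad-CAM support ---------------------------------------------------
    def activation_and_gradient(
        self, x: np.ndarray, layer_name: str, class_index: int
    ) -> tuple[np.ndarray, np.ndarray]:
        """Feature map of ``layer_name`` and d(logit[class])/d(feature map)."""
        if layer_name not in [ly.name for ly in self.layers]:
            raise ConfigurationError(f"no layer named {layer_name!r}")
        logits = self.forward(x, train=True)
        seed_grad = np.zeros_like(logits)
        seed_grad[:, class_index] = 1.0
        self.backward(seed_grad)
        return self._last_outputs[layer_name], self._output_grads[layer_name]


class Adagrad:
    """Adagrad with Keras-style accumulator initialization."""

    def __init__(self, learning_rate: float, initial_accumulator: float = 0.1,
                 epsilon: float = 1e-7):
        self.lr = float(learning_rate)
        self.init_acc = float(initial_accumulator)
        self.eps = float(epsilon)
        self.acc: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        for k, p in params.items():
            g = grads[k]
            if k not in self.acc:
                self.acc[k] = np.full_like(p, self.init_acc, dtype=np.float32)
            self.acc[k] += g * g
            p -= self.lr * g / (np.sqrt(self.acc[k]) + self.eps)

    def state(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.acc.items()}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        self.acc = {k: v.copy() for k, v in state.items()}
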