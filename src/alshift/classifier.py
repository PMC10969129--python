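"""Trainable binary image classifier: build, train, predict, snapshot, Grad-CAM.

The architecture is a deliberately small CNN (conv blocks + global average
pooling + 2-unit softmax head) sized for CPU experiments; the contract —
probability pairs, warm-start training, named weight snapshots (``w1``,
``w2``, ``w12``), Grad-CAM heatmaps — is what the rest of the pipeline
depends on, not the backbone identity.
"""

from __future__ import annotations

import copy
import io
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

from .data_io import CLASS0, CLASS1, UNLABELED, ImageSample, labels_of, stack_pixels
from .errors import ConfigurationError, TrainingError
from .network import Adagrad, SmallCNN, softmax_cross_entropy

_OPTIMIZERS = ("adagrad",)
_LOSSES = ("categorical_cross_entropy",)
_ACTIVATIONS = ("relu",)


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters.

    The defaults are the published protocol: batch size 32, at most 30
    epochs, Adagrad at learning rate 0.001, ReLU activations and categorical
    cross-entropy.  ``max_epochs`` is the only stopping criterion — no early
    stopping, no schedule.
    """

    batch_size: int = 32
    max_epochs: int = 30
    optimizer: str = "adagrad"
    learning_rate: float = 0.001
    loss: str = "categorical_cross_entropy"
    activation: str = "relu"
    seed: int = 0

    def validate(self) -> None:
        if self.batch_size < 1:
            raise ConfigurationError(f"batch_size must be >= 1, got {self.batch_size}")
        if self.max_epochs < 0:
            raise ConfigurationError(f"max_epochs must be >= 0, got {self.max_epochs}")
        if self.optimizer not in _OPTIMIZERS:
            raise ConfigurationError(f"optimizer must be one of {_OPTIMIZERS}")
        if self.learning_rate <= 0:
            raise ConfigurationError(f"learning_rate must be > 0, got {self.learning_rate}")
        if self.loss not in _LOSSES:
            raise ConfigurationError(f"loss must be one of {_LOSSES}")
        if self.activation not in _ACTIVATIONS:
            raise ConfigurationError(f"activation must be one of {_ACTIVATIONS}")


@dataclass(frozen=True)
class ArchConfig:
    """Descriptor of the desk-scale CNN."""

    input_size: tuple[int, int, int] = (64, 64, 3)
    conv_filters: tuple[int, ...] = (8, 16, 32)
    kernel_size: int = 3
    n_classes: int = 2

    def validate(self) -> None:
        if self.n_classes != 2:
            raise ConfigurationError("only binary (2-class) heads are supported")
        if len(self.conv_filters) < 1:
            raise ConfigurationError("at least one conv block is required")


@dataclass
class ClassifierState:
    """Architecture + current weights + optimizer state + training history."""

    arch_config: ArchConfig
    net: SmallCNN
    optimizer: Adagrad
    weights_tag: str = "init"
    train_history: list[dict] = field(default_factory=list)
    n_train_calls: int = 0

    def clone(self) -> "ClassifierState":
        return copy.deepcopy(self)


def build_classifier(arch_config: ArchConfig, train_config: TrainConfig) -> ClassifierState:
    """Build an untrained classifier.

    Conv weights use seeded He initialization (``train_config.seed``); the
    softmax head starts at zero, so a fresh classifier predicts 0.5/0.5 for
    every input.
    """
    arch_config.validate()
    train_config.validate()
    net = SmallCNN(
        input_size=arch_config.input_size,
        conv_filters=arch_config.conv_filters,
        kernel_size=arch_config.kernel_size,
        n_classes=arch_config.n_classes,
        seed=train_config.seed,
    )
    return ClassifierState(
        arch_config=arch_config,
        net=net,
        optimizer=Adagrad(learning_rate=train_config.learning_rate),
    )


def _as_batch(state: ClassifierState, samples) -> np.ndarray:
    """Samples (ImageSample sequence or NHWC array) -> validated NCHW batch."""
    if isinstance(samples, np.ndarray):
        arr = samples
        if arr.ndim == 3:
            arr = arr[None]
    else:
        arr = stack_pixels(samples)
    h, w, c = state.arch_config.input_size
    if arr.shape[1:] != (h, w, c):
        raise ConfigurationError(
            f"samples of shape {arr.shape[1:]} do not match architecture input {(h, w, c)}"
        )
    return np.ascontiguousarray(arr.transpose(0, 3, 1, 2).astype(np.float32))


def train(
    state: ClassifierState,
    labeled_samples: Sequence[ImageSample],
    train_config: TrainConfig,
) -> ClassifierState:
    """Train in place from the current weights (warm start) and return state.

    Runs exactly ``train_config.max_epochs`` epochs of shuffled mini-batches.
    Optimizer accumulators persist across calls, so successive warm starts
    continue the same Adagrad trajectory.  Appends one record per epoch to
    ``train_history``.
    """
    train_config.validate()
    if len(labeled_samples) == 0:
        raise ValueError("empty training set")
    labels = labels_of(labeled_samples)
    if np.any(labels == UNLABELED):
        raise ValueError("training set contains unlabeled samples")
    if len(np.unique(labels)) < 2:
        raise TrainingError("training set contains a single class; loss is degenerate")
    if train_config.max_epochs == 0:
        return state

    x = _as_batch(state, labeled_samples)
    y = labels.astype(np.int64)
    n = len(y)
    state.optimizer.lr = train_config.learning_rate
    # distinct, reproducible shuffling stream per train call
    rng = np.random.default_rng([train_config.seed, state.n_train_calls, n])
    state.n_train_calls += 1

    for epoch in range(train_config.max_epochs):
        order = rng.permutation(n)
        losses, n_correct = [], 0
        for start in range(0, n, train_config.batch_size):
            idx = order[start:start + train_config.batch_size]
            logits = state.net.forward(x[idx], train=True)
            loss, dlogits = softmax_cross_entropy(logits, y[idx])
            state.net.backward(dlogits)
            state.optimizer.step(state.net.params(), state.net.grads())
            losses.append(loss * len(idx))
            n_correct += int((logits.argmax(axis=1) == y[idx]).sum())
        state.train_history.append(
            {
                "epoch": len(state.train_history),
                "loss": float(np.sum(losses) / n),
                "accuracy": n_correct / n,
                "n_samples": n,
            }
        )
    return state


def predict_proba(state: ClassifierState, samples) -> np.ndarray:
    """Probability of the positive class (``CLASS1``) per sample, batch order kept."""
    x = _as_batch(state, samples)
    probs = state.net.predict_proba(x)
    return probs[:, CLASS1]


def predict_labels(state: ClassifierState, samples, threshold: float = 0.5) -> np.ndarray:
    p = predict_proba(state, samples)
    return np.where(p >= threshold, CLASS1, CLASS0)


# -- snapshots ---------------------------------------------------------------

def snapshot(state: ClassifierState, tag: str | None = None) -> dict[str, np.ndarray]:
    """Copy of all weights; optionally retags the classifier."""
    if tag is not None:
        state.weights_tag = tag
    return state.net.get_weights()

def restore(state: ClassifierState, weights: dict[str, np.ndarray],
            tag: str | None = None) -> ClassifierState:
    state.net.set_weights(weights)
    if tag is not None:
        state.weights_tag = tag
    return state


def save_snapshot(state: ClassifierState, path: str | Path) -> Path:
    """Single-file ``.npz`` snapshot with the arch config embedded as JSON."""
    path = Path(path)
    meta = {
        "arch_config": asdict(state.arch_config),
        "weights_tag": state.weights_tag,
        "learning_rate": state.optimizer.lr,
        "n_train_calls": state.n_train_calls,
    }
    arrays = {f"w/{k}": v for k, v in state.net.get_weights().items()}
    arrays.update({f"acc/{k}": v for k, v in state.optimizer.state().items()})
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)
    return path


def load_snapshot(path: str | Path) -> ClassifierState:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        arch_d = meta["arch_config"]
        arch = ArchConfig(
            input_size=tuple(arch_d["input_size"]),
            conv_filters=tuple(arch_d["conv_filters"]),
            kernel_size=arch_d["kernel_size"],
            n_classes=arch_d["n_classes"],
        )
        state = build_classifier(arch, TrainConfig())
        state.net.set_weights({k[2:]: data[k] for k in data.files if k.startswith("w/")})
        acc = {k[4:]: data[k] for k in data.files if k.startswith("acc/")}
    if acc:
        state.optimizer.load_state(acc)
    state.optimizer.lr = meta["learning_rate"]
    state.weights_tag = meta["weights_tag"]
    state.n_train_calls = meta["n_train_calls"]
    return state


def weights_digest(state: ClassifierState) -> str:
    """Stable hex digest of the current weights (for manifests)."""
    import hashlib

    h = hashlib.sha256()
    for k in sorted(state.net.params()):
        h.update(k.encode())
        h.update(np.ascontiguousarray(state.net.params()[k]).tobytes())
    return h.hexdigest()


# -- Grad-CAM ----------------------------------------------------------------

def grad_cam(
    state: ClassifierState,
    sample: ImageSample | np.ndarray,
    target_layer: str | None = None,
    target_class: int | None = None,
) -> np.ndarray:
    """Gradient-weighted class activation map, upsampled to input size.

    The channel weights are the spatial means of d(logit)/d(activation) at
    ``target_layer`` (default: last conv layer); the map is the ReLU of the
    weighted activation sum, bilinearly upsampled and max-normalized to 1
    whenever any positive value exists.  ``target_class`` defaults to the
    predicted class.
    """
    pixels = sample.pixels if isinstance(sample, ImageSample) else sample
    x = _as_batch(state, np.asarray(pixels))
    if target_layer is None:
        target_layer = state.net.conv_names[-1]
    elif target_layer not in [ly.name for ly in state.net.layers]:
        raise ConfigurationError(f"no layer named {target_layer!r}")
    if target_class is None:
        target_class = int(state.net.predict_proba(x)[0].argmax())

    activation, grad = state.net.activation_and_gradient(x, target_layer, target_class)
    alpha = grad[0].mean(axis=(1, 2))  # (K,)
    cam = np.maximum((alpha[:, None, None] * activation[0]).sum(axis=0), 0.0)

    h, w, _ = state.arch_config.input_size
    if cam.shape != (h, w):
        cam = np.asarray(
            Image.fromarray(cam.astype(np.float32), mode="F").resize((w, h), Image.BILINEAR),
            dtype=np.float32,
        )
        cam = np.maximum(cam, 0.0)
    peak = float(cam.max())
    if peak > 0:
        cam = cam / peak
    return cam.astype(np.float32)


def save_heatmap_overlay(
    sample: ImageSample | np.ndarray, heatmap: np.ndarray, path: str | Path,
    alpha: float = 0.5,
) -> Path:
    """Blend a Grad-CAM heatmap over the image and save as PNG."""
    from matplotlib import cm

    pixels = np.asarray(sample.pixels if isinstance(sample, ImageSample) else sample)
    color = cm.jet(np.clip(heatmap, 0, 1))[:, :, :3]
    overlay = np.clip((1 - alpha) * pixels + alpha * color, 0, 1)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray((overlay * 255).astype(np.uint8)).save(path)
    return path
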