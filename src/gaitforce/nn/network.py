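"""Model assembly, Adam optimisation and the MAE training loop.

Three architectures share one sequence-to-sequence contract — input
(B, T, 16), output (B, T, 4):

* ``cnn``       conv(64, 3x1, stride 1, ReLU) -> maxpool(2x1, stride 1)
                -> conv(128) -> maxpool -> flatten
                -> dense(T x 4), reshaped to (T, 4)
* ``lstm``      LSTM(128) -> LSTM(128) -> per-step dense(4)
* ``cnn_lstm``  conv(64, 3x1, stride 2, ReLU) -> LSTM(128)
                -> per-step dense(4) -> linear upsample back to T

Valid convolutions and pooling shorten the time axis; the CNN decodes
its flattened feature map through one fully connected layer, while the
hybrid restores the input length with a fixed linear-interpolation
operator after its per-step head.  Training minimises mean absolute error on
normalized targets with Adam, with optional early stopping on the
validation loss; every random choice (init, shuffling) is seeded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from gaitforce.nn.layers import (
    LSTM,
    Conv1D,
    FlattenDense,
    Layer,
    LinearUpsample,
    MaxPool1D,
    TimeDense,
)

MODEL_KINDS = ("cnn", "lstm", "cnn_lstm")


@dataclass(frozen=True)
class ModelSpec:
    """Architecture hyperparameters for the three estimator families."""

    kind: str = "cnn_lstm"
    conv_kernels: tuple = (64, 128)   # CNN: kernel counts per conv layer
    kernel_size: int = 3              # 3x1 kernels
    conv_stride: int = 1
    pool_size: int = 2                # 2x1 pooling windows
    pool_strides: tuple = (1, 1)
    lstm_layers: int = 2
    lstm_units: int = 128
    cnn_lstm_kernels: int = 64        # conv block feeding the hybrid LSTM
    cnn_lstm_stride: int = 2
    output_dim: int = 4

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(
                f"unknown model kind {self.kind!r}; choose from "
                f"{MODEL_KINDS}")
        if min(self.kernel_size, self.conv_stride, self.pool_size,
               self.lstm_units, self.output_dim) < 1:
            raise ValueError("spec sizes must be positive")


@dataclass
class TrainConfig:
    """Optimisation settings: MAE loss, Adam, early stopping."""

    learning_rate: float = 1e-3
    epochs: int = 200
    batch_size: int = 32
    seed: int = 0
    patience: int = 20          # early stopping on validation MAE
    dtype: str = "float64"

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("hyperparameters must be positive")


class Network:
    """A plain sequential stack of layers."""

    def __init__(self, layers: list, spec: ModelSpec) -> None:
        self.layers = layers
        self.spec = spec

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def parameters(self):
        for li, layer in enumerate(self.layers):
            for name, value in layer.params.items():
                yield (li, name), value

    @property
    def n_params(self) -> int:
        return sum(layer.n_params for layer in self.layers)

    def get_state(self) -> dict:
        return {key: value.copy() for key, value in self.parameters()}

    def set_state(self, state: dict) -> None:
        for (li, name), value in state.items():
            self.layers[li].params[name] = value.copy()


def build_model(spec: ModelSpec, n_timesteps: int, n_features: int = 16,
                seed: int = 0) -> Network:
    """Instantiate a seeded network for fixed-length sequences."""
    rng = np.random.default_rng(seed)
    dt = np.float64
    layers: list[Layer] = []
    if spec.kind == "cnn":
        in_ch = n_features
        t = n_timesteps
        for n_kernels, pool_stride in zip(spec.conv_kernels,
                                          spec.pool_strides):
            layers.append(Conv1D(in_ch, n_kernels, spec.kernel_size,
                                 spec.conv_stride, "relu", rng, dt))
            t = (t - spec.kernel_size) // spec.conv_stride + 1
            layers.append(MaxPool1D(spec.pool_size, pool_stride))
            t = (t - spec.pool_size) // pool_stride + 1
            in_ch = n_kernels
        # the standard CNN decodes the flattened feature map through one
        # fully connected layer (no temporal weight sharing)
        layers.append(FlattenDense(t, in_ch, n_timesteps,
                                   spec.output_dim, rng, dt))
    elif spec.kind == "lstm":
        in_dim = n_features
        for _ in range(spec.lstm_layers):
            layers.append(LSTM(in_dim, spec.lstm_units, rng, dt))
            in_dim = spec.lstm_units
        layers.append(TimeDense(in_dim, spec.output_dim, rng, dt))
    else:  # cnn_lstm
        layers.append(Conv1D(n_features, spec.cnn_lstm_kernels,
                             spec.kernel_size, spec.cnn_lstm_stride,
                             "relu", rng, dt))
        layers.append(LSTM(spec.cnn_lstm_kernels, spec.lstm_units, rng, dt))
        layers.append(TimeDense(spec.lstm_units, spec.output_dim, rng, dt))
        layers.append(LinearUpsample(n_timesteps))
    return Network(layers, spec)


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m: dict = {}
        self.v: dict = {}
        self.t = 0

    def step(self, model: Network) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for li, layer in enumerate(model.layers):
            for name, grad in layer.grads.items():
                key = (li, name)
                if key not in self.m:
                    self.m[key] = np.zeros_like(grad)
                    self.v[key] = np.zeros_like(grad)
                self.m[key] = b1 * self.m[key] + (1 - b1) * grad
                self.v[key] = b2 * self.v[key] + (1 - b2) * grad ** 2
                m_hat = self.m[key] / (1 - b1 ** self.t)
                v_hat = self.v[key] / (1 - b2 ** self.t)
                layer.params[name] -= (
                    self.lr * m_hat / (np.sqrt(v_hat) + self.eps))


def mae_loss(pred: np.ndarray, target: np.ndarray):
    """Mean absolute error and its subgradient wrt the prediction."""
    diff = pred - target
    return float(np.mean(np.abs(diff))), np.sign(diff) / diff.size


def predict(model: Network, x: np.ndarray,
            batch_size: int = 64) -> np.ndarray:
    """Forward pass in evaluation mode, batched to bound memory."""
    x = np.asarray(x)
    single = x.ndim == 2
    if single:
        x = x[None]
    outs = [model.forward(x[i:i + batch_size])
            for i in range(0, x.shape[0], batch_size)]
    y = np.concatenate(outs, axis=0)
    return y[0] if single else y


def train(model: Network, train_data: tuple, val_data: tuple | None,
          cfg: TrainConfig) -> dict:
    """Fit with Adam on MAE; returns per-epoch train/val loss history.

    Early stopping restores the parameters with the best validation loss
    once ``cfg.patience`` epochs pass without improvement.  Aborts with a
    diagnostic if the loss goes non-finite.
    """
    X, Y = train_data
    X = np.asarray(X, dtype=cfg.dtype)
    Y = np.asarray(Y, dtype=cfg.dtype)
    if X.shape[0] == 0:
        raise ValueError("training set is empty")
    if X.shape[0] != Y.shape[0] or X.shape[1] != Y.shape[1]:
        raise ValueError(
            f"inconsistent train shapes {X.shape} vs {Y.shape}")
    if val_data is not None:
        Xv = np.asarray(val_data[0], dtype=cfg.dtype)
        Yv = np.asarray(val_data[1], dtype=cfg.dtype)

    for layer in model.layers:
        for name in layer.params:
            layer.params[name] = layer.params[name].astype(cfg.dtype)

    rng = np.random.default_rng(cfg.seed)
    adam = Adam(lr=cfg.learning_rate)
    history = {"train_mae": [], "val_mae": []}
    best_val = np.inf
    best_state = None
    wait = 0
    n = X.shape[0]
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        batch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            pred = model.forward(X[idx])
            loss, dloss = mae_loss(pred, Y[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}, "
                    f"batch starting {start}")
            model.backward(dloss)
            adam.step(model)
            batch_losses.append(loss)
        history["train_mae"].append(float(np.mean(batch_losses)))
        if val_data is not None:
            val_pred = predict(model, Xv)
            val_loss = float(np.mean(np.abs(val_pred - Yv)))
            history["val_mae"].append(val_loss)
            if val_loss < best_val - 1e-12:
                best_val = val_loss
                best_state = model.get_state()
                wait = 0
            else:
                wait += 1
                if wait >= cfg.patience:
                    break
    if best_state is not None:
        model.set_state(best_state)
    return history
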