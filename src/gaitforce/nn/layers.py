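"""Neural-network layers with explicit forward and backward passes.

Array convention: activations are (batch, time, channels).  Convolution
is the deep-learning cross-correlation convention, valid (no padding),
over the time axis:

    y[b, t, j] = f( sum_{k, i} x[b, t*stride + k, i] * W[k, i, j] + b[j] )

Each layer caches what its backward pass needs during forward; backward
consumes the upstream gradient, fills ``grads`` for its parameters and
returns the gradient with respect to its input.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def conv_forward(x: np.ndarray, weights: np.ndarray,
                 bias: np.ndarray | float = 0.0, stride: int = 1,
                 activation: str | None = "relu") -> np.ndarray:
    """Valid cross-correlation over time with optional ReLU.

    ``x`` may be (T,), (T, C) or (B, T, C); ``weights`` correspondingly
    (K,), (K, C, O) — 1-D inputs use a single channel and output map.
    """
    x = np.asarray(x, dtype=float)
    weights = np.asarray(weights, dtype=float)
    squeeze = x.ndim < 3
    if x.ndim == 1:
        x = x[None, :, None]
    elif x.ndim == 2:
        x = x[None, :, :]
    if weights.ndim == 1:
        weights = weights[:, None, None]
    K = weights.shape[0]
    if x.shape[1] < K:
        raise ValueError(
            f"input length {x.shape[1]} shorter than kernel {K}")
    win = sliding_window_view(x, K, axis=1)[:, ::stride]  # (B, T', C, K)
    z = np.einsum("btck,kco->bto", win, weights) + bias
    if activation == "relu":
        z = np.maximum(z, 0.0)
    elif activation is not None:
        raise ValueError(f"unknown activation {activation!r}")
    if squeeze:
        z = z[0, :, 0] if z.shape[2] == 1 else z[0]
    return z


def max_pool(x: np.ndarray, pool_size: int = 2,
             stride: int = 1) -> np.ndarray:
    """Sliding-window maximum over time; output length (T - P)//s + 1."""
    x = np.asarray(x, dtype=float)
    squeeze = x.ndim < 3
    if x.ndim == 1:
        x = x[None, :, None]
    elif x.ndim == 2:
        x = x[None, :, :]
    if x.shape[1] < pool_size:
        raise ValueError(
            f"input length {x.shape[1]} shorter than pool {pool_size}")
    win = sliding_window_view(x, pool_size, axis=1)[:, ::stride]
    y = win.max(axis=-1)
    if squeeze:
        y = y[0, :, 0] if y.shape[2] == 1 else y[0]
    return y


class Layer:
    """Base class: parameter dict, gradient dict, forward/backward."""

    def __init__(self) -> None:
        self.params: dict = {}
        self.grads: dict = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params.values())


def _glorot(rng: np.random.Generator, shape: tuple, fan_in: int,
            fan_out: int, dtype) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Conv1D(Layer):
    """Valid temporal convolution (cross-correlation) with ReLU option."""

    def __init__(self, in_channels: int, out_channels: int,
                 kernel_size: int = 3, stride: int = 1,
                 activation: str | None = "relu",
                 rng: np.random.Generator | None = None,
                 dtype=np.float64) -> None:
        super().__init__()
        if kernel_size < 1 or stride < 1:
            raise ValueError("kernel size and stride must be positive")
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.kernel_size = kernel_size
        self.activation = activation
        self.params["W"] = _glorot(
            rng, (kernel_size, in_channels, out_channels),
            kernel_size * in_channels, kernel_size * out_channels, dtype)
        self.params["b"] = np.zeros(out_channels, dtype=dtype)

    def forward(self, x: np.ndarray) -> np.ndarray:
        K = self.kernel_size
        if x.shape[1] < K:
            raise ValueError(
                f"input length {x.shape[1]} shorter than kernel {K}")
        win = sliding_window_view(x, K, axis=1)[:, ::self.stride]
        z = np.einsum("btck,kco->bto", win, self.params["W"])
        z += self.params["b"]
        self._win = win
        self._x_shape = x.shape
        if self.activation == "relu":
            self._mask = z > 0
            return np.maximum(z, 0.0)
        return z

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dz = dy * self._mask if self.activation == "relu" else dy
        self.grads["b"] = dz.sum(axis=(0, 1))
        self.grads["W"] = np.einsum("btck,bto->kco", self._win, dz)
        dx = np.zeros(self._x_shape, dtype=dy.dtype)
        W = self.params["W"]
        t_out = dz.shape[1]
        for k in range(self.kernel_size):
            sl = slice(k, k + self.stride * (t_out - 1) + 1, self.stride)
            dx[:, sl, :] += dz @ W[k].T
        return dx


class MaxPool1D(Layer):
    """Sliding-window max over time; ties route the gradient to the
    first maximal element of the window."""

    def __init__(self, pool_size: int = 2, stride: int = 1) -> None:
        super().__init__()
        if pool_size < 1 or stride < 1:
            raise ValueError("pool size and stride must be positive")
        self.pool_size = pool_size
        self.stride = stride

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] < self.pool_size:
            raise ValueError(
                f"input length {x.shape[1]} shorter than pool "
                f"{self.pool_size}")
        win = sliding_window_view(x, self.pool_size, axis=1)
        win = win[:, ::self.stride]
        self._argmax = win.argmax(axis=-1)
        self._x_shape = x.shape
        return win.max(axis=-1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, t_out, C = dy.shape
        dx = np.zeros(self._x_shape, dtype=dy.dtype)
        bb, tt, cc = np.indices((B, t_out, C), sparse=False)
        np.add.at(dx, (bb, tt * self.stride + self._argmax, cc), dy)
        return dx


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class LSTM(Layer):
    """Single LSTM layer returning the full hidden-state sequence.

    Gates in i/f/g/o order share one weight block:
    z_t = x_t Wx + h_{t-1} Wh + b.  tanh activations; forget-gate bias
    initialised to 1 for stable early training.
    """

    def __init__(self, in_dim: int, hidden: int,
                 rng: np.random.Generator | None = None,
                 dtype=np.float64) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.hidden = hidden
        self.params["Wx"] = _glorot(rng, (in_dim, 4 * hidden),
                                    in_dim, hidden, dtype)
        self.params["Wh"] = _glorot(rng, (hidden, 4 * hidden),
                                    hidden, hidden, dtype)
        b = np.zeros(4 * hidden, dtype=dtype)
        b[hidden:2 * hidden] = 1.0
        self.params["b"] = b

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, T, _ = x.shape
        H = self.hidden
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        xz = x @ Wx + b  # precompute input contribution for all t
        h = np.zeros((B, H), dtype=x.dtype)
        c = np.zeros((B, H), dtype=x.dtype)
        I = np.empty((B, T, H), dtype=x.dtype)
        F = np.empty_like(I)
        G = np.empty_like(I)
        O = np.empty_like(I)
        Cs = np.empty_like(I)
        TanhC = np.empty_like(I)
        Hs = np.empty_like(I)
        Cprev = np.empty_like(I)
        Hprev = np.empty_like(I)
        for t in range(T):
            Hprev[:, t] = h
            Cprev[:, t] = c
            z = xz[:, t] + h @ Wh
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            I[:, t], F[:, t], G[:, t], O[:, t] = i, f, g, o
            Cs[:, t], TanhC[:, t], Hs[:, t] = c, tc, h
        self._cache = (x, I, F, G, O, Cs, TanhC, Cprev, Hprev)
        return Hs

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, I, F, G, O, Cs, TanhC, Cprev, Hprev = self._cache
        B, T, H = dy.shape
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros_like(self.params["b"])
        dx = np.empty_like(x)
        dh_next = np.zeros((B, H), dtype=dy.dtype)
        dc_next = np.zeros((B, H), dtype=dy.dtype)
        for t in range(T - 1, -1, -1):
            dh = dy[:, t] + dh_next
            i, f, g, o = I[:, t], F[:, t], G[:, t], O[:, t]
            tc = TanhC[:, t]
            dc = dh * o * (1.0 - tc ** 2) + dc_next
            do = dh * tc
            di = dc * g
            dg = dc * i
            df = dc * Cprev[:, t]
            dz = np.concatenate([
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g ** 2),
                do * o * (1.0 - o),
            ], axis=1)
            dWx += x[:, t].T @ dz
            dWh += Hprev[:, t].T @ dz
            db += dz.sum(axis=0)
            dx[:, t] = dz @ Wx.T
            dh_next = dz @ Wh.T
            dc_next = dc * f
        self.grads["Wx"], self.grads["Wh"], self.grads["b"] = dWx, dWh, db
        return dx


class TimeDense(Layer):
    """Dense layer applied independently at every time step."""

    def __init__(self, in_dim: int, out_dim: int,
                 rng: np.random.Generator | None = None,
                 dtype=np.float64) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.params["W"] = _glorot(rng, (in_dim, out_dim), in_dim,
                                   out_dim, dtype)
        self.params["b"] = np.zeros(out_dim, dtype=dtype)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        self.grads["W"] = np.einsum("bti,bto->io", x, dy)
        self.grads["b"] = dy.sum(axis=(0, 1))
        return dy @ self.params["W"].T


class FlattenDense(Layer):
    """Flatten the whole feature map through one fully connected layer.

    Maps (B, T_in, C) -> (B, T_out, out_dim) via a single dense layer on
    the flattened (T_in * C) vector — the classic CNN head in which the
    entire encoded image is decoded at once, with no weight sharing
    across time.
    """

    def __init__(self, t_in: int, in_channels: int, t_out: int,
                 out_dim: int, rng: np.random.Generator | None = None,
                 dtype=np.float64) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        n_in = t_in * in_channels
        n_out = t_out * out_dim
        self.t_out = t_out
        self.out_dim = out_dim
        self.params["W"] = _glorot(rng, (n_in, n_out), n_in, n_out, dtype)
        self.params["b"] = np.zeros(n_out, dtype=dtype)

    def forward(self, x: np.ndarray) -> np.ndarray:
        B = x.shape[0]
        self._x_shape = x.shape
        flat = x.reshape(B, -1)
        self._flat = flat
        out = flat @ self.params["W"] + self.params["b"]
        return out.reshape(B, self.t_out, self.out_dim)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B = dy.shape[0]
        dflat = dy.reshape(B, -1)
        self.grads["W"] = self._flat.T @ dflat
        self.grads["b"] = dflat.sum(axis=0)
        return (dflat @ self.params["W"].T).reshape(self._x_shape)


class LinearUpsample(Layer):
    """Linear interpolation of the time axis to a fixed output length.

    A fixed linear operator y = U x (per batch and channel), so the
    backward pass is the exact transpose U^T dy.  Identity when the
    input already has the target length.
    """

    def __init__(self, t_out: int) -> None:
        super().__init__()
        self.t_out = t_out
        self._U: np.ndarray | None = None
        self._t_in: int | None = None

    def _operator(self, t_in: int, dtype) -> np.ndarray:
        if self._U is None or self._t_in != t_in:
            pos = np.linspace(0.0, t_in - 1.0, self.t_out)
            lo = np.clip(np.floor(pos).astype(int), 0, t_in - 1)
            hi = np.clip(lo + 1, 0, t_in - 1)
            w = pos - lo
            U = np.zeros((self.t_out, t_in))
            U[np.arange(self.t_out), lo] += 1.0 - w
            U[np.arange(self.t_out), hi] += w
            self._U, self._t_in = U, t_in
        return self._U.astype(dtype, copy=False)

    def forward(self, x: np.ndarray) -> np.ndarray:
        U = self._operator(x.shape[1], x.dtype)
        return np.einsum("ji,bic->bjc", U, x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        U = self._operator(self._t_in, dy.dtype)
        return np.einsum("ji,bjc->bic", U, dy)
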