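"""Minimal seeded neural-network backend (NumPy).

Implements exactly the layers the quality classifier needs — feature
normalization, valid-mode 1-D convolution, max pooling, inverted dropout,
dense layers, a unidirectional LSTM — plus softmax / sigmoid losses and
the Adam optimizer. Everything is float64 and fully deterministic given a
seed: weight init draws from one generator, dropout masks and minibatch
shuffling from another, so identical seeds and data reproduce identical
training histories bit for bit on a fixed BLAS.

This is not a general framework; layer order and shapes are fixed by the
classifier topology and no attempt is made at GPU execution.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Normalization",
    "Conv1D",
    "ReLU",
    "MaxPool1D",
    "Dropout",
    "Dense",
    "LSTM",
    "Adam",
    "softmax_cross_entropy",
    "sigmoid_binary_cross_entropy",
    "softmax",
    "sigmoid",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(x: np.ndarray) -> np.ndarray:
    z = x - x.max(axis=-1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=-1, keepdims=True)


class Layer:
    """Base layer: named parameter/gradient dicts plus forward/backward."""

    trainable = True

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Normalization(Layer):
    """Per-feature standardization with statistics adapted from training data."""

    trainable = False

    def __init__(self, n_features: int) -> None:
        super().__init__()
        self.params = {
            "mean": np.zeros(n_features),
            "std": np.ones(n_features),
        }

    def adapt(self, x: np.ndarray) -> None:
        """Fit mean/std over all axes except the last (feature) axis."""
        flat = x.reshape(-1, x.shape[-1])
        self.params["mean"] = flat.mean(axis=0)
        std = flat.std(axis=0)
        self.params["std"] = np.where(std > 0, std, 1.0)

    def forward(self, x, train=False):
        return (x - self.params["mean"]) / self.params["std"]

    def backward(self, dout):
        return dout / self.params["std"]


class Conv1D(Layer):
    """Valid-mode 1-D convolution along the time axis: (B, T, Cin) -> (B, T-k+1, Cout)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.kernel = kernel
        fan_in, fan_out = kernel * c_in, kernel * c_out
        self.params = {
            "W": _glorot(rng, (kernel, c_in, c_out), fan_in, fan_out),
            "b": np.zeros(c_out),
        }

    def forward(self, x, train=False):
        # windows: (B, T-k+1, k, Cin)
        self._windows = sliding_window_view(x, self.kernel, axis=1).transpose(0, 1, 3, 2)
        self._x_shape = x.shape
        return (
            np.tensordot(self._windows, self.params["W"], axes=([2, 3], [0, 1]))
            + self.params["b"]
        )

    def backward(self, dout):
        # dout: (B, T_out, Cout)
        self.grads["W"] = np.tensordot(self._windows, dout, axes=([0, 1], [0, 1]))
        self.grads["b"] = dout.sum(axis=(0, 1))
        B, T, c_in = self._x_shape
        dx = np.zeros((B, T, c_in))
        # scatter-add each kernel tap: dx[:, t+j] += dout[:, t] @ W[j].T
        for j in range(self.kernel):
            dx[:, j : j + dout.shape[1]] += dout @ self.params["W"][j].T
        return dx


class ReLU(Layer):
    trainable = False

    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool1D(Layer):
    """Non-overlapping max pooling along time; a partial tail is dropped."""

    trainable = False

    def __init__(self, pool: int) -> None:
        super().__init__()
        self.pool = pool

    def forward(self, x, train=False):
        B, T, C = x.shape
        T2 = T // self.pool
        self._x_shape = x.shape
        blocks = x[:, : T2 * self.pool].reshape(B, T2, self.pool, C)
        self._argmax = blocks.argmax(axis=2)
        return blocks.max(axis=2)

    def backward(self, dout):
        B, T2, C = dout.shape
        dblocks = np.zeros((B, T2, self.pool, C))
        b_ix, t_ix, c_ix = np.ogrid[:B, :T2, :C]
        dblocks[b_ix, t_ix, self._argmax, c_ix] = dout
        dx = np.zeros(self._x_shape)
        dx[:, : T2 * self.pool] = dblocks.reshape(B, T2 * self.pool, C)
        return dx


class Dropout(Layer):
    """Inverted dropout; identity at inference. Masks come from the rng the
    trainer installs, keeping runs reproducible."""

    trainable = False

    def __init__(self, rate: float) -> None:
        super().__init__()
        self.rate = rate
        self.rng: np.random.Generator | None = None

    def forward(self, x, train=False):
        if not train or self.rate == 0.0 or self.rng is None:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Dense(Layer):
    """Affine map on the last axis; handles (B, D) and (B, T, D) inputs."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        self.params = {
            "W": _glorot(rng, (d_in, d_out), d_in, d_out),
            "b": np.zeros(d_out),
        }

    def forward(self, x, train=False):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        x = self._x
        if x.ndim == 3:
            self.grads["W"] = np.tensordot(x, dout, axes=([0, 1], [0, 1]))
            self.grads["b"] = dout.sum(axis=(0, 1))
        else:
            self.grads["W"] = x.T @ dout
            self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class LSTM(Layer):
    """Unidirectional LSTM returning the final hidden state.

    Gate layout in the fused weight matrices is (input, forget, cell,
    output); the forget-gate bias starts at 1 so early training does not
    wash out the cell state.
    """

    def __init__(self, d_in: int, units: int, rng: np.random.Generator):
        super().__init__()
        self.units = units
        self.params = {
            "Wx": _glorot(rng, (d_in, 4 * units), d_in, units),
            "Wh": _glorot(rng, (units, 4 * units), units, units),
            "b": np.zeros(4 * units),
        }
        self.params["b"][units : 2 * units] = 1.0

    def forward(self, x, train=False):
        B, T, _ = x.shape
        U = self.units
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        h = np.zeros((B, U))
        c = np.zeros((B, U))
        self._cache = []
        self._x = x
        for t in range(T):
            z = x[:, t] @ Wx + h @ Wh + b
            i = sigmoid(z[:, :U])
            f = sigmoid(z[:, U : 2 * U])
            g = np.tanh(z[:, 2 * U : 3 * U])
            o = sigmoid(z[:, 3 * U :])
            c_prev, h_prev = c, h
            c = f * c_prev + i * g
            h = o * np.tanh(c)
            self._cache.append((i, f, g, o, c, c_prev, h_prev))
        return h

    def backward(self, dout):
        x = self._x
        B, T, D = x.shape
        U = self.units
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros_like(self.params["b"])
        dx = np.zeros_like(x)
        dh = dout
        dc = np.zeros((B, U))
        for t in range(T - 1, -1, -1):
            i, f, g, o, c, c_prev, h_prev = self._cache[t]
            tanh_c = np.tanh(c)
            do = dh * tanh_c
            dc = dc + dh * o * (1.0 - tanh_c**2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g**2),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dWx += x[:, t].T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t] = dz @ Wx.T
            dh = dz @ Wh.T
            dc = dc * f
        self.grads = {"Wx": dWx, "Wh": dWh, "b": db}
        return dx


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean sparse categorical cross-entropy and its gradient w.r.t. logits."""
    p = softmax(logits)
    n = logits.shape[0]
    eps = 1e-12
    loss = float(-np.log(p[np.arange(n), y] + eps).mean())
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    return loss, dlogits / n


def sigmoid_binary_cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on 1-unit logits and its gradient."""
    z = logits[:, 0]
    p = sigmoid(z)
    eps = 1e-12
    loss = float(-(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)).mean())
    dz = (p - y) / y.shape[0]
    return loss, dz[:, None]


class Adam:
    """Adam optimizer over the trainable layers of a network."""

    def __init__(self, layers, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.layers = [ly for ly in layers if ly.trainable and ly.params]
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in ly.params.items()} for ly in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in ly.params.items()} for ly in self.layers]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for ly, m, v in zip(self.layers, self.m, self.v):
            for k, p in ly.params.items():
                g = ly.grads[k]
                m[k] = self.beta1 * m[k] + (1.0 - self.beta1) * g
                v[k] = self.beta2 * v[k] + (1.0 - self.beta2) * g**2
                p -= self.lr * (m[k] / b1t) / (np.sqrt(v[k] / b2t) + self.eps)
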