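"""Minimal seeded neural-network engine on NumPy.

Implements exactly the layers the classifiers need — 1-D convolution with
'same' padding, batch normalization (with optional frozen running
statistics for few-shot fine-tuning), ReLU, non-overlapping max pooling,
global average pooling, dropout, dense, an LSTM cell unrolled over time —
plus softmax cross-entropy and the Adam optimizer.  Everything is float32,
CPU-only, and a pure function of the seeds supplied at build and train
time, which makes training runs bit-reproducible.

Array convention: batches are (batch, channels, time); the LSTM consumes
(batch, time, features).
"""

from __future__ import annotations

import numpy as np

EPS_BN = 1e-5

__all__ = [
    "Layer", "Conv1d", "BatchNorm1d", "ReLU", "MaxPool1d",
    "GlobalAvgPool1d", "Dropout", "Flatten", "Dense", "LSTM",
    "Sequential", "Adam", "softmax", "softmax_cross_entropy",
]


class Layer:
    """Base layer: named parameters, matching gradients, forward/backward."""

    def params(self) -> dict[str, np.ndarray]:
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1d(Layer):
    """1-D convolution, odd kernel, 'same' (zero) padding.

    Realized as one batched matmul per kernel tap, which avoids the large
    im2col buffers a 5000-sample sequence would otherwise need.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator):
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd for 'same' padding")
        self.cin, self.cout, self.k = in_channels, out_channels, kernel
        scale = np.sqrt(2.0 / (in_channels * kernel))
        self.w = (rng.standard_normal((out_channels, in_channels, kernel))
                  * scale).astype(np.float32)
        self.b = np.zeros(out_channels, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.skip_input_grad = False
        self._xp: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def params(self):
        return {"w": self.w, "b": self.b}

    def grads(self):
        return {"w": self.dw, "b": self.db}

    def forward(self, x, training):
        b, c, length = x.shape
        pad = self.k // 2
        xp = np.pad(x.astype(np.float32, copy=False),
                    ((0, 0), (0, 0), (pad, pad)))
        y = np.zeros((b, self.cout, length), dtype=np.float32)
        for j in range(self.k):
            # (cout, cin) @ (b, cin, L) -> (b, cout, L)
            y += np.matmul(self.w[:, :, j], xp[:, :, j:j + length])
        y += self.b[None, :, None]
        if training:
            self._xp, self._shape = xp, (b, c, length)
        return y

    def backward(self, dy):
        b, c, length = self._shape
        pad = self.k // 2
        dy = dy.astype(np.float32, copy=False)
        self.db[:] = dy.sum(axis=(0, 2))
        for j in range(self.k):
            self.dw[:, :, j] = np.tensordot(
                dy, self._xp[:, :, j:j + length], axes=([0, 2], [0, 2]))
        self._xp = None
        if self.skip_input_grad:
            return None
        dxp = np.zeros((b, c, length + 2 * pad), dtype=np.float32)
        wt = np.ascontiguousarray(self.w.transpose(2, 1, 0))  # (k, cin, cout)
        for j in range(self.k):
            dxp[:, :, j:j + length] += np.matmul(wt[j], dy)
        return dxp[:, :, pad:pad + length]


class BatchNorm1d(Layer):
    """Per-channel batch normalization over (batch, time).

    ``freeze_stats=True`` makes training-mode forward passes use the stored
    running mean/variance (and stops updating them) while the scale/shift
    weights keep training — the few-shot fine-tuning regime.
    """

    def __init__(self, channels: int, momentum: float = 0.1):
        self.c = channels
        self.momentum = momentum
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.freeze_stats = False
        self._cache = None

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def grads(self):
        return {"gamma": self.dgamma, "beta": self.dbeta}

    def forward(self, x, training):
        if training and not self.freeze_stats:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + EPS_BN)
        xhat = (x - mean[None, :, None]) * inv[None, :, None]
        if training:
            self._cache = (xhat, inv, x.shape[0] * x.shape[2],
                           not self.freeze_stats)
        return self.gamma[None, :, None] * xhat + self.beta[None, :, None]

    def backward(self, dy):
        xhat, inv, n, batch_stats = self._cache
        self.dgamma[:] = (dy * xhat).sum(axis=(0, 2))
        self.dbeta[:] = dy.sum(axis=(0, 2))
        g_inv = (self.gamma * inv)[None, :, None]
        if not batch_stats:
            return dy * g_inv
        sum_dy = dy.sum(axis=(0, 2), keepdims=True)
        sum_dy_xhat = (dy * xhat).sum(axis=(0, 2), keepdims=True)
        return g_inv * (dy - sum_dy / n - xhat * sum_dy_xhat / n)


class ReLU(Layer):
    def forward(self, x, training):
        mask = x > 0
        if training:
            self._mask = mask
        return x * mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool1d(Layer):
    """Non-overlapping max pooling (size == stride)."""

    def __init__(self, size: int):
        self.size = size

    def forward(self, x, training):
        b, c, length = x.shape
        if length % self.size:
            raise ValueError(
                f"sequence length {length} not divisible by pool size {self.size}"
            )
        xr = x.reshape(b, c, length // self.size, self.size)
        if training:
            self._arg = xr.argmax(axis=3)
            self._shape = x.shape
        return xr.max(axis=3)

    def backward(self, dy):
        b, c, length = self._shape
        out = np.zeros((b, c, length // self.size, self.size), dtype=dy.dtype)
        np.put_along_axis(out, self._arg[..., None], dy[..., None], axis=3)
        return out.reshape(b, c, length)


class GlobalAvgPool1d(Layer):
    """Average over the remaining time axis: (B, C, L) -> (B, C)."""

    def forward(self, x, training):
        self._l = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dy):
        return np.repeat(dy[:, :, None], self._l, axis=2) / self._l


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self.rng = rng

    def forward(self, x, training):
        if not training or self.p == 0:
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask.astype(np.float32)

    def backward(self, dy):
        return dy * self._mask


class Flatten(Layer):
    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (n_in + n_out))
        self.w = (rng.standard_normal((n_in, n_out)) * scale).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return {"w": self.w, "b": self.b}

    def grads(self):
        return {"w": self.dw, "b": self.db}

    def forward(self, x, training):
        if training:
            self._x = x
        return x @ self.w + self.b

    def backward(self, dy):
        self.dw[:] = self._x.T @ dy
        self.db[:] = dy.sum(axis=0)
        return dy @ self.w.T


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


class LSTM(Layer):
    """Single-layer LSTM returning the final hidden state.

    Input (B, T, D) -> output (B, H).  Gate order in the fused weight
    matrices is [input, forget, cell, output]; the forget-gate bias is
    initialized to 1.
    """

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        self.d, self.h = n_in, hidden
        s = 1.0 / np.sqrt(hidden)
        self.wx = rng.uniform(-s, s, (n_in, 4 * hidden)).astype(np.float32)
        self.wh = rng.uniform(-s, s, (hidden, 4 * hidden)).astype(np.float32)
        self.b = np.zeros(4 * hidden, dtype=np.float32)
        self.b[hidden:2 * hidden] = 1.0
        self.dwx = np.zeros_like(self.wx)
        self.dwh = np.zeros_like(self.wh)
        self.db = np.zeros_like(self.b)

    def params(self):
        return {"wx": self.wx, "wh": self.wh, "b": self.b}

    def grads(self):
        return {"wx": self.dwx, "wh": self.dwh, "b": self.db}

    def forward(self, x, training):
        b, t, _ = x.shape
        h = np.zeros((b, self.h), dtype=np.float32)
        c = np.zeros((b, self.h), dtype=np.float32)
        caches = []
        for step in range(t):
            xt = x[:, step, :]
            z = xt @ self.wx + h @ self.wh + self.b
            i = _sigmoid(z[:, :self.h])
            f = _sigmoid(z[:, self.h:2 * self.h])
            g = np.tanh(z[:, 2 * self.h:3 * self.h])
            o = _sigmoid(z[:, 3 * self.h:])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            if training:
                caches.append((xt, h, c, i, f, g, o, tanh_c))
            h, c = h_new, c_new
        if training:
            self._caches = caches
        return h

    def backward(self, dh_final):
        t = len(self._caches)
        b = dh_final.shape[0]
        self.dwx[:] = 0
        self.dwh[:] = 0
        self.db[:] = 0
        dh = dh_final.astype(np.float32)
        dc = np.zeros_like(dh)
        dx = np.zeros((b, t, self.d), dtype=np.float32)
        for step in range(t - 1, -1, -1):
            xt, h_prev, c_prev, i, f, g, o, tanh_c = self._caches[step]
            do = dh * tanh_c
            dct = dc + dh * o * (1.0 - tanh_c ** 2)
            di = dct * g
            df = dct * c_prev
            dg = dct * i
            dz = np.concatenate([
                di * i * (1 - i),
                df * f * (1 - f),
                dg * (1 - g ** 2),
                do * o * (1 - o),
            ], axis=1)
            self.dwx += xt.T @ dz
            self.dwh += h_prev.T @ dz
            self.db += dz.sum(axis=0)
            dx[:, step, :] = dz @ self.wx.T
            dh = dz @ self.wh.T
            dc = dct * f
        self._caches = None
        return dx


class TransposeToTimeMajor(Layer):
    """(B, C, L) -> (B, L, C) adapter between conv and recurrent stages."""

    def forward(self, x, training):
        return np.ascontiguousarray(x.transpose(0, 2, 1))

    def backward(self, dy):
        return np.ascontiguousarray(dy.transpose(0, 2, 1))


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers
        # the gradient w.r.t. the network input is never consumed
        if layers and isinstance(layers[0], Conv1d):
            layers[0].skip_input_grad = True

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def named_params(self):
        for li, layer in enumerate(self.layers):
            for name, p in layer.params().items():
                yield f"{li}.{name}", p, layer.grads()[name]

    def state(self) -> dict[str, np.ndarray]:
        st = {}
        for li, layer in enumerate(self.layers):
            for name, p in layer.params().items():
                st[f"{li}.{name}"] = p.copy()
            if isinstance(layer, BatchNorm1d):
                st[f"{li}.running_mean"] = layer.running_mean.copy()
                st[f"{li}.running_var"] = layer.running_var.copy()
        return st

    def load_state(self, st: dict[str, np.ndarray]) -> None:
        for li, layer in enumerate(self.layers):
            for name, p in layer.params().items():
                p[...] = st[f"{li}.{name}"]
            if isinstance(layer, BatchNorm1d):
                layer.running_mean[...] = st[f"{li}.running_mean"]
                layer.running_var[...] = st[f"{li}.running_var"]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray
                          ) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = float(-np.log(np.maximum(p[np.arange(n), labels], 1e-12)).mean())
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


class Adam:
    def __init__(self, net: Sequential, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.net = net
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {name: np.zeros_like(p) for name, p, _ in net.named_params()}
        self.v = {name: np.zeros_like(p) for name, p, _ in net.named_params()}

    def step(self) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for name, p, g in self.net.named_params():
            m = self.m[name]
            v = self.v[name]
            m += (1.0 - self.beta1) * (g - m)
            v += (1.0 - self.beta2) * (g * g - v)
            p -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)
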