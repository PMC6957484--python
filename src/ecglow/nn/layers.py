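"""Minimal NumPy neural-network layers with manual backpropagation.

Float32 throughout; each layer caches what its backward pass needs.  Only the
pieces the beat classifiers require are implemented: length-preserving 1-D
convolution, batch normalisation, ReLU, dropout, dense layers, a single-layer
LSTM, softmax cross-entropy and Adam.  Initialisation is Glorot/Xavier
uniform, biases zero; all randomness flows through explicit generators.

Convolutional tensors use a time-first (L, B, C) layout: every shifted window
of the padded signal is then a contiguous view, so the convolution reduces to
k plain GEMMs without materialising an im2col matrix.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Param:
    __slots__ = ("v", "g")

    def __init__(self, value: np.ndarray):
        self.v = np.asarray(value, dtype=DTYPE)
        self.g = np.zeros_like(self.v)


def xavier_uniform(rng: np.random.Generator, fan_in: int, fan_out: int,
                   shape: tuple[int, ...]) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class Conv1DSame:
    """1-D convolution, stride 1, zero ('same') padding: (L, B, Cin) -> (L, B, Cout)."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        if k < 1 or k % 2 == 0:
            raise ValueError("kernel size must be odd and >= 1")
        self.k, self.c_in, self.c_out = k, c_in, c_out
        self.W = Param(xavier_uniform(rng, k * c_in, k * c_out, (k * c_in, c_out)))
        self.b = Param(np.zeros(c_out))
        self._xp = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        L, B, C = x.shape
        p = self.k // 2
        xp = np.zeros((L + 2 * p, B, C), dtype=DTYPE)
        xp[p:p + L] = x
        self._xp = xp
        y = None
        for j in range(self.k):
            xj = xp[j:j + L].reshape(L * B, C)
            wj = self.W.v[j * C:(j + 1) * C]
            y = xj @ wj if y is None else y + xj @ wj
        y += self.b.v
        return y.reshape(L, B, self.c_out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp = self._xp
        L, B, _ = dy.shape
        C, p = self.c_in, self.k // 2
        dy2 = dy.reshape(L * B, self.c_out)
        dxp = np.zeros_like(xp)
        for j in range(self.k):
            xj = xp[j:j + L].reshape(L * B, C)
            self.W.g[j * C:(j + 1) * C] += xj.T @ dy2
            dxp[j:j + L].reshape(L * B, C)[...] += dy2 @ self.W.v[j * C:(j + 1) * C].T
        self.b.g += dy2.sum(axis=0)
        return dxp[p:p + L]


class BatchNorm:
    """Batch normalisation over all axes but the last (channel) axis."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes, dtype=np.float64)
            var = x.var(axis=axes, dtype=np.float64)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean).astype(DTYPE)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var).astype(DTYPE)
            mean = mean.astype(DTYPE)
            var = var.astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(DTYPE)
        xhat = np.empty_like(x)
        np.subtract(x, mean, out=xhat)
        np.multiply(xhat, inv, out=xhat)
        self._cache = (xhat, inv, axes)
        y = xhat * self.gamma.v
        y += self.beta.v
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, axes = self._cache
        n = int(np.prod([xhat.shape[a] for a in axes]))
        sub = "abc,abc->c" if dy.ndim == 3 else "ac,ac->c"
        sum_dy = dy.sum(axis=axes, dtype=np.float64).astype(DTYPE)
        sum_dy_xhat = np.einsum(sub, dy, xhat, dtype=np.float64).astype(DTYPE)
        self.gamma.g += sum_dy_xhat
        self.beta.g += sum_dy
        g = self.gamma.v
        dx = dy * g
        dx -= (g * sum_dy) / n
        dx -= xhat * ((g * sum_dy_xhat) / n)
        dx *= inv
        return dx


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = Param(xavier_uniform(rng, n_in, n_out, (n_in, n_out)))
        self.b = Param(np.zeros(n_out))
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=DTYPE)
        self._cache = x
        return x @ self.W.v + self.b.v

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._cache
        dy = np.ascontiguousarray(dy, dtype=DTYPE)
        self.W.g += x.T @ dy
        self.b.g += dy.sum(axis=0)
        return dy @ self.W.v.T


class Dropout:
    def __init__(self, rate: float):
        self.rate = rate
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator) -> np.ndarray:
        if not training or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(DTYPE) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        return dy * self._mask


class LSTM:
    """Single-layer LSTM consuming (B, T, C); exposes the final hidden state.

    Gate order i, f, g, o; combined input/recurrent weight (C+H, 4H); biases 0.
    """

    def __init__(self, c_in: int, hidden: int, rng: np.random.Generator):
        self.c_in, self.hidden = c_in, hidden
        self.W = Param(xavier_uniform(rng, c_in + hidden, 4 * hidden,
                                      (c_in + hidden, 4 * hidden)))
        self.b = Param(np.zeros(4 * hidden))
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=DTYPE)
        B, T, C = x.shape
        H = self.hidden
        h = np.zeros((B, H), dtype=DTYPE)
        c = np.zeros((B, H), dtype=DTYPE)
        steps = []
        for t in range(T):
            xh = np.concatenate([x[:, t], h], axis=1)
            z = xh @ self.W.v + self.b.v
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h = o * tc
            steps.append((xh, i, f, g, o, c_prev, tc))
        self._cache = (steps, (B, T, C))
        return h

    def backward(self, dh_last: np.ndarray) -> np.ndarray:
        steps, (B, T, C) = self._cache
        H = self.hidden
        dx = np.zeros((B, T, C), dtype=DTYPE)
        dh = np.ascontiguousarray(dh_last, dtype=DTYPE)
        dc = np.zeros((B, H), dtype=DTYPE)
        for t in range(T - 1, -1, -1):
            xh, i, f, g, o, c_prev, tc = steps[t]
            do = dh * tc
            dc = dc + dh * o * (1 - tc ** 2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate([
                di * i * (1 - i), df * f * (1 - f),
                dg * (1 - g ** 2), do * o * (1 - o)], axis=1)
            self.W.g += xh.T @ dz
            self.b.g += dz.sum(axis=0)
            dxh = dz @ self.W.v.T
            dx[:, t] = dxh[:, :C]
            dh = dxh[:, C:]
            dc = dc * f
        return dx


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_xent(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Mean cross-entropy; returns (loss, dlogits, probabilities)."""
    probs = softmax(logits)
    n = logits.shape[0]
    eps = 1e-12
    loss = float(-np.mean(np.log(probs[np.arange(n), labels] + eps)))
    d = probs.copy()
    d[np.arange(n), labels] -= 1.0
    return loss, (d / n).astype(DTYPE), probs


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.v) for p in params]
        self.s = [np.zeros_like(p.v) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.g[...] = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, s in zip(self.params, self.m, self.s):
            m[...] = self.b1 * m + (1 - self.b1) * p.g
            s[...] = self.b2 * s + (1 - self.b2) * p.g ** 2
            p.v -= self.lr * (m / b1t) / (np.sqrt(s / b2t) + self.eps)
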