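"""Minimal 1-D neural-network primitives with explicit backprop.

Layers cache what their backward pass needs; ``forward`` then ``backward``
must be called in matched pairs. Convolutions use an im2col matmul; all
arrays are float64 for reproducibility across platforms.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit

SELU_LAMBDA = 1.0507009873554805
SELU_ALPHA = 1.6732632423543772


def selu(x, lam: float = SELU_LAMBDA, alpha: float = SELU_ALPHA):
    """Scaled exponential linear unit: lam*alpha*(e^x - 1) for x<0, lam*x else."""
    x = np.asarray(x, dtype=float)
    out = np.where(x < 0, lam * alpha * np.expm1(x), lam * x)
    return out if out.ndim else float(out)


def softplus(x):
    """Overflow-safe ln(1 + e^x)."""
    x = np.asarray(x, dtype=float)
    out = np.logaddexp(0.0, x)
    return out if out.ndim else float(out)


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Conv1d:
    """Same-length 1-D convolution, zero padding, stride 1.

    Input/output layout: (N, channels, length).
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 zero_init: bool = False):
        if kernel % 2 != 1:
            raise ValueError("kernel width must be odd")
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        fan_in = c_in * kernel
        scale = 0.0 if zero_init else 1.0 / np.sqrt(fan_in)
        self.W = Param(rng.normal(0.0, 1.0, size=(c_out, c_in * kernel)) * scale)
        self.b = Param(np.zeros(c_out))
        self._cols = None
        self._in_shape = None

    def parameters(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, ci, L = x.shape
        pad = self.kernel // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        # (N, Ci, L, K) -> (N, L, Ci*K)
        cols = sliding_window_view(xp, self.kernel, axis=2)
        cols = cols.transpose(0, 2, 1, 3).reshape(n, L, ci * self.kernel)
        self._cols = cols
        self._in_shape = x.shape
        out = cols @ self.W.value.T + self.b.value
        return out.transpose(0, 2, 1)  # (N, Co, L)

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, ci, L = self._in_shape
        pad = self.kernel // 2
        gt = g.transpose(0, 2, 1)  # (N, L, Co)
        self.W.grad += np.einsum("nlo,nlf->of", gt, self._cols)
        self.b.grad += gt.sum(axis=(0, 1))
        dcols = (gt @ self.W.value).reshape(n, L, ci, self.kernel)
        dxp = np.zeros((n, ci, L + 2 * pad))
        for k in range(self.kernel):
            dxp[:, :, k:k + L] += dcols[:, :, :, k].transpose(0, 2, 1)
        self._cols = None
        return dxp[:, :, pad:pad + L] if pad else dxp


class Selu:
    def __init__(self, lam: float = SELU_LAMBDA, alpha: float = SELU_ALPHA):
        self.lam, self.alpha = lam, alpha
        self._x = None

    def parameters(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return np.where(x < 0, self.lam * self.alpha * np.expm1(x), self.lam * x)

    def backward(self, g: np.ndarray) -> np.ndarray:
        x = self._x
        dx = np.where(x < 0, self.lam * self.alpha * np.exp(x), self.lam)
        return g * dx


class Softplus:
    def __init__(self):
        self._x = None

    def parameters(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return np.logaddexp(0.0, x)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * expit(self._x)


class MaxPool1d:
    """Max pooling with right -inf padding so any length divides evenly."""

    def __init__(self, factor: int):
        if factor < 2:
            raise ValueError("pool factor must be >= 2")
        self.factor = factor
        self._idx = None
        self._in_len = None

    def parameters(self):
        return []

    @staticmethod
    def out_len(L: int, factor: int) -> int:
        return -(-L // factor)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, L = x.shape
        p = self.out_len(L, self.factor)
        padded = np.full((n, c, p * self.factor), -np.inf)
        padded[:, :, :L] = x
        windows = padded.reshape(n, c, p, self.factor)
        self._idx = windows.argmax(axis=3)
        self._in_len = L
        return windows.max(axis=3)

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, c, p = g.shape
        dwin = np.zeros((n, c, p, self.factor))
        np.put_along_axis(dwin, self._idx[..., None], g[..., None], axis=3)
        return dwin.reshape(n, c, p * self.factor)[:, :, :self._in_len]


class Upsample1d:
    """Nearest-neighbor repeat along the length axis."""

    def __init__(self, factor: int):
        self.factor = factor

    def parameters(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.repeat(x, self.factor, axis=2)

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, c, L = g.shape
        return g.reshape(n, c, L // self.factor, self.factor).sum(axis=3)


class Crop1d:
    """Crop the length axis to a fixed size (decoder output back to Q)."""

    def __init__(self, length: int):
        self.length = length
        self._in_len = None

    def parameters(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_len = x.shape[2]
        return x[:, :, :self.length]

    def backward(self, g: np.ndarray) -> np.ndarray:
        if self._in_len == self.length:
            return g
        out = np.zeros(g.shape[:2] + (self._in_len,))
        out[:, :, :self.length] = g
        return out


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 zero_init: bool = False):
        scale = 0.0 if zero_init else 1.0 / np.sqrt(n_in)
        self.W = Param(rng.normal(0.0, 1.0, size=(n_in, n_out)) * scale)
        self.b = Param(np.zeros(n_out))
        self._x = None

    def parameters(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ g
        self.b.grad += g.sum(axis=0)
        return g @ self.W.value.T


class Dropout:
    """Inverted dropout; identity when inactive or rate == 0."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self._mask = None

    def parameters(self):
        return []

    def forward(self, x: np.ndarray, train: bool, rng=None) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g if self._mask is None else g * self._mask


class Adam:
    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
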