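"""Minimal CPU neural-network engine.

Implements the handful of layer types needed for the classification
backbone — 2-D convolution (im2col), max pooling, ReLU, dense layers,
global average pooling and the L2-constraint layer — together with
reverse-mode gradients, a soft-label softmax cross-entropy and the Adam
optimizer.  Arrays are NHWC; a leading batch axis is always present.

Gradients of every layer are validated against central finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter",
    "Layer",
    "Conv2D",
    "MaxPool2D",
    "ReLU",
    "Flatten",
    "GlobalAvgPool",
    "Dense",
    "L2Constraint",
    "Sequential",
    "Adam",
    "softmax",
    "softmax_cross_entropy",
    "DegenerateFeatureError",
]


class DegenerateFeatureError(ValueError):
    """Raised when a zero feature vector reaches the L2-constraint layer."""


class Parameter:
    """A trainable tensor with an accumulated gradient."""

    def __init__(self, value: np.ndarray, name: str = "", trainable: bool = True):
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name
        self.trainable = trainable

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    """Base layer: stateless by default, caches activations for backward."""

    def params(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, dtype) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Conv2D(Layer):
    """3x3-style convolution via im2col, NHWC layout, zero padding."""

    def __init__(self, in_ch: int, out_ch: int, ksize: int = 3, stride: int = 1,
                 pad: int = 1, rng: np.random.Generator | None = None,
                 dtype=np.float64, name: str = "conv"):
        rng = rng or np.random.default_rng(0)
        self.ksize, self.stride, self.pad = ksize, stride, pad
        self.in_ch, self.out_ch = in_ch, out_ch
        fan_in = ksize * ksize * in_ch
        self.W = Parameter(_he_init(rng, (fan_in, out_ch), fan_in, dtype), name + ".W")
        self.b = Parameter(np.zeros(out_ch, dtype=dtype), name + ".b")
        self._cache: tuple | None = None

    def params(self) -> list[Parameter]:
        return [self.W, self.b]

    def _im2col(self, xp: np.ndarray) -> np.ndarray:
        k, s = self.ksize, self.stride
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
        # win: (N, H', W', C, k, k) at stride 1 -> subsample to stride s
        win = win[:, ::s, ::s]
        n, oh, ow = win.shape[:3]
        # order (k, k, C) to match W's fan-in layout
        col = win.transpose(0, 1, 2, 4, 5, 3).reshape(n * oh * ow, k * k * self.in_ch)
        return np.ascontiguousarray(col), (n, oh, ow)

    def forward(self, x: np.ndarray) -> np.ndarray:
        p = self.pad
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        col, (n, oh, ow) = self._im2col(xp)
        out = col @ self.W.value + self.b.value
        self._cache = (xp.shape, col, (n, oh, ow))
        return out.reshape(n, oh, ow, self.out_ch)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xp_shape, col, (n, oh, ow) = self._cache
        g = grad.reshape(n * oh * ow, self.out_ch)
        self.W.grad += col.T @ g
        self.b.grad += g.sum(axis=0)
        dcol = (g @ self.W.value.T).reshape(n, oh, ow, self.ksize, self.ksize, self.in_ch)
        dxp = np.zeros(xp_shape, dtype=grad.dtype)
        s = self.stride
        for i in range(self.ksize):
            for j in range(self.ksize):
                dxp[:, i:i + s * oh:s, j:j + s * ow:s, :] += dcol[:, :, :, i, j, :]
        p = self.pad
        if p:
            return dxp[:, p:-p, p:-p, :]
        return dxp


class MaxPool2D(Layer):
    """Non-overlapping max pooling; trailing rows/cols beyond a full window
    are dropped (floor division), matching common framework behaviour."""

    def __init__(self, size: int = 2):
        self.size = size
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        s = self.size
        n, h, w, c = x.shape
        oh, ow = h // s, w // s
        xc = x[:, :oh * s, :ow * s, :]
        win = xc.reshape(n, oh, s, ow, s, c).transpose(0, 1, 3, 5, 2, 4)
        flat = win.reshape(n, oh, ow, c, s * s)
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        self._cache = (x.shape, idx)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        s = self.size
        (n, h, w, c), idx = self._cache
        oh, ow = h // s, w // s
        dflat = np.zeros((n, oh, ow, c, s * s), dtype=grad.dtype)
        np.put_along_axis(dflat, idx[..., None], grad[..., None], axis=-1)
        dwin = dflat.reshape(n, oh, ow, c, s, s).transpose(0, 1, 4, 2, 5, 3)
        dx = np.zeros((n, h, w, c), dtype=grad.dtype)
        dx[:, :oh * s, :ow * s, :] = dwin.reshape(n, oh * s, ow * s, c)
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, 0.0)


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class GlobalAvgPool(Layer):
    """Mean over the two spatial axes: (N, H, W, C) -> (N, C)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        return np.broadcast_to(grad[:, None, None, :] / (h * w), self._shape).copy()


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator | None = None,
                 dtype=np.float64, name: str = "dense"):
        rng = rng or np.random.default_rng(0)
        self.W = Parameter(_he_init(rng, (in_dim, out_dim), in_dim, dtype), name + ".W")
        self.b = Parameter(np.zeros(out_dim, dtype=dtype), name + ".b")

    def params(self) -> list[Parameter]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T


class L2Constraint(Layer):
    """Rescale each feature vector to a fixed L2 norm ``alpha``.

    y = alpha * x / ||x||.  Backward uses the exact Jacobian
    (alpha/||x||) (I - x̂ x̂ᵀ).  A zero input vector has no defined
    direction; with ``eps == 0`` it raises :class:`DegenerateFeatureError`,
    while a small positive ``eps`` guards the denominator for training
    stability.
    """

    def __init__(self, alpha: float, eps: float = 0.0):
        if alpha <= 0:
            raise ValueError("alpha must be positive")
        self.alpha = float(alpha)
        self.eps = float(eps)

    def forward(self, x: np.ndarray) -> np.ndarray:
        norms = np.linalg.norm(x, axis=-1, keepdims=True)
        if self.eps == 0.0 and np.any(norms == 0.0):
            raise DegenerateFeatureError("zero feature vector has no direction to rescale")
        denom = norms + self.eps
        self._x, self._denom = x, denom
        return self.alpha * x / denom

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x, denom = self._x, self._denom
        dot = np.sum(x * grad, axis=-1, keepdims=True)
        return self.alpha / denom * (grad - x * dot / denom ** 2)


class Sequential(Layer):
    """Layer pipeline with an optional marked feature (penultimate) layer."""

    def __init__(self, layers: list[Layer], feature_index: int | None = None):
        self.layers = layers
        #: index such that ``layers[:feature_index + 1]`` maps input -> descriptor
        self.feature_index = feature_index

    def params(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def forward_features(self, x: np.ndarray) -> np.ndarray:
        if self.feature_index is None:
            raise ValueError("no feature layer marked on this network")
        for layer in self.layers[: self.feature_index + 1]:
            x = layer.forward(x)
        return x


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy between softmax(logits) and soft targets.

    ``targets`` rows must lie on the probability simplex (one-hot labels
    are the special case).  Returns ``(loss, dlogits)``.
    """
    z = logits - logits.max(axis=-1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=-1, keepdims=True))
    n = logits.shape[0]
    loss = float(-(targets * logp).sum() / n)
    dlogits = (np.exp(logp) - targets) / n
    return loss, dlogits


class Adam:
    """Adam optimizer; parameters with ``trainable=False`` are skipped."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            if not p.trainable:
                continue
            m[...] = b1 * m + (1 - b1) * p.grad
            v[...] = b2 * v + (1 - b2) * p.grad ** 2
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
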