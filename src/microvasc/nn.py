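"""Minimal CPU neural-network core.

Small, deterministic building blocks (2-D convolution, max pooling, nearest
upsampling, dense layers) with hand-written backpropagation and an Adam
optimizer.  All heavy lifting is delegated to BLAS through ``numpy`` tensor
contractions, which keeps desk-scale training of the quality-control
classifier and the segmentation U-Nets in the minutes range on one core.

Conventions: activations are ``float64`` arrays shaped ``(N, C, H, W)``;
convolutions are stride-1 with "same" zero padding; every layer caches what
its backward pass needs, so a layer instance must not be shared between two
concurrent forward passes.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2d",
    "ReLU",
    "MaxPool2x2",
    "Upsample2x",
    "GlobalAvgPool",
    "Linear",
    "Adam",
    "sigmoid",
    "bce_with_logits",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, targets: np.ndarray):
    """Mean binary cross-entropy on logits.

    Returns ``(loss, dlogits)`` where ``dlogits`` is the gradient of the mean
    loss, i.e. ``(sigmoid(z) - y) / n``.
    """
    z = logits.astype(np.float64)
    y = targets.astype(np.float64)
    # log(1 + exp(-|z|)) formulation, numerically stable
    loss = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
    n = z.size
    grad = (sigmoid(z) - y) / n
    return float(loss.mean()), grad


class Layer:
    """Base class: parameters exposed as aligned ``params`` / ``grads`` lists."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


class Conv2d(Layer):
    """3x3 (or kxk) stride-1 'same' convolution.

    Implemented as k*k shifted tensor contractions rather than im2col: each
    kernel offset contributes one BLAS matmul, which is both fast and memory
    light at the feature-map sizes used here.
    """

    def __init__(self, c_in: int, c_out: int, k: int = 3, rng: np.random.Generator | None = None):
        if k % 2 != 1:
            raise ValueError("kernel size must be odd")
        rng = rng or np.random.default_rng(0)
        # He initialisation, appropriate for ReLU nets
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.W = rng.normal(0.0, scale, size=(c_out, c_in, k, k))
        self.b = np.zeros(c_out)
        self.k = k
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._xpad: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        n, c, h, w = x.shape
        xpad = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        self._xpad = xpad
        out = np.zeros((n, self.W.shape[0], h, w))
        for di in range(k):
            for dj in range(k):
                xs = xpad[:, :, di : di + h, dj : dj + w]
                # (N,C,H,W) x (O,C) -> (N,H,W,O)
                out += np.tensordot(xs, self.W[:, :, di, dj], axes=([1], [1])).transpose(0, 3, 1, 2)
        out += self.b[None, :, None, None]
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        k = self.k
        p = k // 2
        xpad = self._xpad
        n, c, hp, wp = xpad.shape
        h, w = dout.shape[2], dout.shape[3]
        dxpad = np.zeros_like(xpad)
        for di in range(k):
            for dj in range(k):
                xs = xpad[:, :, di : di + h, dj : dj + w]
                self.dW[:, :, di, dj] += np.tensordot(dout, xs, axes=([0, 2, 3], [0, 2, 3]))
                dxpad[:, :, di : di + h, dj : dj + w] += np.tensordot(
                    dout, self.W[:, :, di, dj], axes=([1], [0])
                ).transpose(0, 3, 1, 2)
        self.db += dout.sum(axis=(0, 2, 3))
        self._xpad = None
        return dxpad[:, :, p : hp - p, p : wp - p]

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0.0)


class MaxPool2x2(Layer):
    """2x2 max pooling; ties give gradient to the first maximal element."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("MaxPool2x2 requires even spatial dims")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        idx = xr.argmax(axis=-1)
        self._idx = idx
        self._shape = x.shape
        return np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dxr = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(dxr, self._idx[..., None], dout[..., None], axis=-1)
        return dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)


class Upsample2x(Layer):
    """Nearest-neighbour 2x upsampling; backward sums over each 2x2 block."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = dout.shape
        return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class GlobalAvgPool(Layer):
    """(N,C,H,W) -> (N,C) spatial mean."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None], self._shape) / (h * w)


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.W = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_out, d_in))
        self.b = np.zeros(d_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW += dout.T @ self._x
        self.db += dout.sum(axis=0)
        return dout @ self.W

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class Adam:
    """Adam optimizer over explicit (param, grad) array pairs (in-place)."""

    def __init__(self, params: list[np.ndarray], grads: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.grads = grads
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0.0


def collect_params(layers) -> tuple[list[np.ndarray], list[np.ndarray]]:
    ps: list[np.ndarray] = []
    gs: list[np.ndarray] = []
    for layer in layers:
        ps.extend(layer.params())
        gs.extend(layer.grads())
    return ps, gs


def params_fingerprint(params: list[np.ndarray]) -> str:
    """Stable hex digest of a parameter list (order-sensitive)."""
    import hashlib

    h = hashlib.sha256()
    for p in params:
        h.update(np.ascontiguousarray(p, dtype=np.float64).tobytes())
    return h.hexdigest()
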