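"""Minimal convolutional-network engine (NumPy + numba, CPU).

Implements exactly the pieces the segmentation U-Net and the anchor-free
detector need: 3x3 and 1x1 convolutions, ReLU, 2x2 max-pool, nearest
up-sampling, batch-norm, dropout, a fused sigmoid + binary-cross-entropy
loss, and Adam.  Activations are channels-first float32 (N, C, H, W);
the 3x3 convolution runs in numba kernels whose inner loops are
contiguous row FMAs, the 1x1 convolution is a batched BLAS matmul.
Layers cache what their backward pass needs; everything is seeded and
deterministic on CPU.
"""

from __future__ import annotations

import numpy as np

from ventriseg._conv_kernels import conv3_dw, conv3_dx, conv3_fwd

F32 = np.float32


class Param:
    __slots__ = ("value", "grad", "m", "v")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=F32)
        self.grad = np.zeros_like(self.value)
        self.m = np.zeros_like(self.value)
        self.v = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _pad1(x: np.ndarray) -> np.ndarray:
    n, c, h, w = x.shape
    xp = np.zeros((n, c, h + 2, w + 2), dtype=F32)
    xp[:, :, 1:h + 1, 1:w + 1] = x
    return xp


class Conv2d(Layer):
    """3x3 'same' or 1x1 convolution, stride 1, He-initialized."""

    def __init__(self, c_in: int, c_out: int, k: int = 3,
                 rng: np.random.Generator | None = None):
        if k not in (1, 3):
            raise ValueError("kernel size must be 1 or 3")
        rng = rng or np.random.default_rng(0)
        w = rng.standard_normal((k, k, c_in, c_out)) * np.sqrt(2.0 / (k * k * c_in))
        self.w = Param(w)
        self.b = Param(np.zeros(c_out))
        self.k, self.c_in, self.c_out = k, c_in, c_out
        self.needs_dx = True  # first layer of a net may switch this off

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train):
        n, c, h, w = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} channels, got {c}")
        if self.k == 1:
            xf = x.reshape(n, c, h * w)
            out = np.matmul(self.w.value[0, 0].T[None], xf)
            out += self.b.value[None, :, None]
            self._cache = xf
            return np.ascontiguousarray(out.reshape(n, self.c_out, h, w))
        xp = _pad1(x)
        out = np.empty((n, self.c_out, h, w), dtype=F32)
        conv3_fwd(xp, self.w.value, self.b.value, out)
        self._cache = xp
        return out

    def backward(self, dy):
        dy = np.ascontiguousarray(dy, dtype=F32)
        n, co, h, w = dy.shape
        if self.k == 1:
            xf = self._cache
            dyf = dy.reshape(n, co, h * w)
            self.w.grad[0, 0] += np.einsum("ncp,nop->co", xf, dyf, optimize=True)
            self.b.grad += dyf.sum(axis=(0, 2))
            self._cache = None
            if not self.needs_dx:
                return None
            dx = np.matmul(self.w.value[0, 0][None], dyf)
            return np.ascontiguousarray(dx.reshape(n, self.c_in, h, w))
        xp = self._cache
        conv3_dw(xp, dy, self.w.grad, self.b.grad)
        self._cache = None
        if not self.needs_dx:
            return None
        dxp = np.zeros_like(xp)
        conv3_dx(dxp, self.w.value, dy)
        return np.ascontiguousarray(dxp[:, :, 1:h + 1, 1:w + 1])


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return np.where(self._mask, x, F32(0))

    def backward(self, dy):
        return np.where(self._mask, dy, F32(0))


class MaxPool2(Layer):
    """2x2 max-pooling, stride 2 (even spatial sizes only)."""

    def forward(self, x, train):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        self._argmask = xr == out[:, :, :, None, :, None]
        return out

    def backward(self, dy):
        # gradient routed to every element equal to the window max; exact
        # float ties among positive activations are vanishingly rare and
        # ties at zero are masked out by the preceding ReLU's backward
        n, c, ho, wo = dy.shape
        dyr = np.where(self._argmask, dy[:, :, :, None, :, None], F32(0))
        return dyr.reshape(n, c, ho * 2, wo * 2).astype(F32)


class Upsample2(Layer):
    """Nearest-neighbour x2 up-sampling."""

    def forward(self, x, train):
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, dy):
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class BatchNorm(Layer):
    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones((1, c, 1, 1)))
        self.beta = Param(np.zeros((1, c, 1, 1)))
        self.run_mean = np.zeros((1, c, 1, 1), dtype=F32)
        self.run_var = np.ones((1, c, 1, 1), dtype=F32)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2, 3), keepdims=True)
            var = x.var(axis=(0, 2, 3), keepdims=True)
            self.run_mean = (self.momentum * self.run_mean
                             + (1 - self.momentum) * mean).astype(F32)
            self.run_var = (self.momentum * self.run_var
                            + (1 - self.momentum) * var).astype(F32)
        else:
            mean, var = self.run_mean, self.run_var
        self._std = np.sqrt(var + self.eps).astype(F32)
        self._xhat = ((x - mean) / self._std).astype(F32)
        self._train = train
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, dy):
        xhat = self._xhat
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3), keepdims=True)
        self.beta.grad += dy.sum(axis=(0, 2, 3), keepdims=True)
        if not self._train:
            return dy * self.gamma.value / self._std
        dxhat = dy * self.gamma.value
        return ((dxhat - dxhat.mean(axis=(0, 2, 3), keepdims=True)
                 - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True))
                / self._std).astype(F32)


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate, self.rng = rate, rng

    def forward(self, x, train):
        if not train or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(F32) / F32(keep)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
            if dy is None:
                break
        return dy


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    x = x.astype(np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bce_with_logits(logits: np.ndarray, targets: np.ndarray,
                    pos_weight: float = 1.0,
                    sample_weight: np.ndarray | None = None
                    ) -> tuple[float, np.ndarray]:
    """Numerically stable binary cross-entropy on logits.

    Returns (mean loss, d loss / d logits), the gradient already divided
    by the element count.
    """
    z = logits.astype(np.float64)
    t = targets.astype(np.float64)
    w = np.where(t > 0, pos_weight, 1.0)
    if sample_weight is not None:
        w = w * sample_weight
    loss = w * (np.logaddexp(0.0, z) - t * z)
    grad = w * (sigmoid(z) - t)
    return float(loss.sum() / z.size), (grad / z.size).astype(F32)


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params, self.lr, self.betas, self.eps = params, lr, betas, eps
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        bias1 = 1 - b1 ** self.t
        bias2 = 1 - b2 ** self.t
        for p in self.params:
            p.m = (b1 * p.m + (1 - b1) * p.grad).astype(F32)
            p.v = (b2 * p.v + (1 - b2) * p.grad * p.grad).astype(F32)
            p.value -= (self.lr * (p.m / bias1)
                        / (np.sqrt(p.v / bias2) + self.eps)).astype(F32)


def save_params(net: Layer) -> list[np.ndarray]:
    return [p.value.copy() for p in net.params()]


def load_params(net: Layer, values: list[np.ndarray]) -> None:
    own = net.params()
    if len(own) != len(values):
        raise ValueError("parameter count mismatch")
    for p, v in zip(own, values):
        if p.value.shape != v.shape:
            raise ValueError("parameter shape mismatch")
        p.value[...] = v
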