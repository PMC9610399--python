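"""Minimal CNN layer kit with explicit forward/backward passes.

Each layer caches what its backward pass needs; parameters and their
gradients live in ``Param`` holders so one Adam instance can step the whole
stack.  Convolutions use the kernel-offset gather/scatter trick (a k x k
python loop over vectorized strided slices), which is fast at the small map
sizes this model runs at.  Everything is float32.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Param:
    value: np.ndarray
    grad: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.value = np.ascontiguousarray(self.value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2d(Layer):
    """Same-ish padded strided 2-D convolution on (N, C, H, W) arrays."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int,
        stride: int,
        rng: np.random.Generator,
    ) -> None:
        self.kernel, self.stride, self.pad = kernel, stride, kernel // 2
        self.in_channels, self.out_channels = in_channels, out_channels
        fan_in = in_channels * kernel * kernel
        self.w = Param(he_init(rng, (out_channels, fan_in), fan_in))
        self.b = Param(np.zeros(out_channels, dtype=np.float32))
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def _out_hw(self, h: int, w: int) -> tuple[int, int]:
        k, s, p = self.kernel, self.stride, self.pad
        return (h + 2 * p - k) // s + 1, (w + 2 * p - k) // s + 1

    def _gather(self, xp: np.ndarray, oh: int, ow: int) -> np.ndarray:
        """(N, C, Hp, Wp) -> (N*oh*ow, C*k*k) patch matrix."""
        n, c = xp.shape[:2]
        k, s = self.kernel, self.stride
        cols = np.empty((n, c, k, k, oh, ow), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                cols[:, :, i, j] = xp[:, :, i : i + s * oh : s, j : j + s * ow : s]
        return cols.transpose(0, 4, 5, 1, 2, 3).reshape(n * oh * ow, c * k * k)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        oh, ow = self._out_hw(h, w)
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        cols = self._gather(xp, oh, ow)
        y = cols @ self.w.value.T + self.b.value
        if train:
            self._cache = (cols, xp.shape, (n, oh, ow))
        return y.reshape(n, oh, ow, self.out_channels).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, xp_shape, (n, oh, ow) = self._cache
        k, s, p = self.kernel, self.stride, self.pad
        dy2 = dy.transpose(0, 2, 3, 1).reshape(n * oh * ow, self.out_channels)
        self.w.grad += dy2.T @ cols
        self.b.grad += dy2.sum(axis=0)
        dcols = (dy2 @ self.w.value).reshape(n, oh, ow, self.in_channels, k, k)
        dcols = dcols.transpose(0, 3, 4, 5, 1, 2)  # (N, C, k, k, oh, ow)
        dxp = np.zeros(xp_shape, dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + s * oh : s, j : j + s * ow : s] += dcols[:, :, i, j]
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class SEBlock(Layer):
    """Squeeze-and-Excitation channel attention.

    Squeeze: global average pool each channel to a scalar.  Excite: a two-layer
    bottleneck (reduction r) with ReLU then sigmoid infers a weight in (0, 1)
    per channel.  Rescale: multiply the feature map channel-wise.  With the
    excitation forced to 1 the block is the identity.
    """

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator) -> None:
        hidden = max(1, channels // reduction)
        self.w1 = Param(he_init(rng, (hidden, channels), channels))
        self.b1 = Param(np.zeros(hidden, dtype=np.float32))
        self.w2 = Param(he_init(rng, (channels, hidden), hidden))
        self.b2 = Param(np.zeros(channels, dtype=np.float32))

    def params(self) -> list[Param]:
        return [self.w1, self.b1, self.w2, self.b2]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        z = x.mean(axis=(2, 3))  # squeeze: (N, C)
        h = np.maximum(z @ self.w1.value.T + self.b1.value, 0.0)
        gate = 1.0 / (1.0 + np.exp(-(h @ self.w2.value.T + self.b2.value)))
        if train:
            self._cache = (x, z, h, gate)
        return x * gate[:, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, z, h, gate = self._cache
        spatial = x.shape[2] * x.shape[3]
        dx = dy * gate[:, :, None, None]
        dgate = (dy * x).sum(axis=(2, 3))
        dpre2 = dgate * gate * (1.0 - gate)
        self.w2.grad += dpre2.T @ h
        self.b2.grad += dpre2.sum(axis=0)
        dh = dpre2 @ self.w2.value
        dpre1 = dh * (h > 0)
        self.w1.grad += dpre1.T @ z
        self.b1.grad += dpre1.sum(axis=0)
        dz = dpre1 @ self.w1.value
        dx += dz[:, :, None, None] / spatial
        return dx


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None], self._shape) / (h * w)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator) -> None:
        self.w = Param(he_init(rng, (out_features, in_features), in_features))
        self.b = Param(np.zeros(out_features, dtype=np.float32))

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.w.grad += dy.T @ self._x
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value


class Adam:
    """Plain Adam on a parameter list."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr, self.eps = lr, eps
        self.b1, self.b2 = betas
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad**2
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
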