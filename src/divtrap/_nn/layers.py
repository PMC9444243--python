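"""Feed-forward layers with explicit forward/backward passes.

Array layout is channel-first: images are (N, C, H, W) float64.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)


def _im2col(xp: np.ndarray, k: int) -> np.ndarray:
    """(N, C, Hp, Wp) padded input -> (N, C*k*k, H*W) column matrix."""
    n, c, hp, wp = xp.shape
    h, w = hp - k + 1, wp - k + 1
    cols = np.empty((n, c, k * k, h, w), dtype=xp.dtype)
    idx = 0
    for di in range(k):
        for dj in range(k):
            cols[:, :, idx] = xp[:, :, di : di + h, dj : dj + w]
            idx += 1
    return cols.reshape(n, c * k * k, h * w)


def _col2im(dcols: np.ndarray, shape: tuple[int, int, int, int], k: int) -> np.ndarray:
    """Adjoint of _im2col; returns gradient w.r.t. the padded input."""
    n, c, hp, wp = shape
    h, w = hp - k + 1, wp - k + 1
    dxp = np.zeros(shape, dtype=dcols.dtype)
    dcols = dcols.reshape(n, c, k * k, h, w)
    idx = 0
    for di in range(k):
        for dj in range(k):
            dxp[:, :, di : di + h, dj : dj + w] += dcols[:, :, idx]
            idx += 1
    return dxp


class Conv2d:
    """k x k convolution, stride 1, 'same' zero padding."""

    def __init__(self, cin: int, cout: int, k: int = 3, *, rng: np.random.Generator) -> None:
        if k % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.cin, self.cout, self.k = cin, cout, k
        self.pad = k // 2
        self.w = Param(_he_init(rng, (cout, cin * k * k), cin * k * k), "conv.w")
        self.b = Param(np.zeros(cout), "conv.b")
        self._cache: tuple | None = None

    @property
    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {c}")
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        cols = _im2col(xp, self.k)
        y = np.matmul(self.w.value, cols)  # (n, cout, h*w) via broadcasting
        y += self.b.value[None, :, None]
        self._cache = (cols, xp.shape, (h, w))
        return y.reshape(n, self.cout, h, w)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, xp_shape, (h, w) = self._cache
        n = dy.shape[0]
        dyf = dy.reshape(n, self.cout, h * w)
        self.w.grad += np.tensordot(dyf, cols, axes=([0, 2], [0, 2]))
        self.b.grad += dyf.sum(axis=(0, 2))
        dcols = np.matmul(self.w.value.T, dyf)
        dxp = _col2im(dcols, xp_shape, self.k)
        p = self.pad
        return dxp[:, :, p : p + h, p : p + w]


class ReLU:
    params: list[Param] = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool2x2:
    """2x2 max pooling, stride 2; input H and W must be even."""

    params: list[Param] = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("MaxPool2x2 requires even spatial dims")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        self._argmax = xr.argmax(axis=-1)
        self._inshape = (n, c, h, w)
        return np.take_along_axis(xr, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._inshape
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(dxr, self._argmax[..., None], dy[..., None], axis=-1)
        dxr = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dxr.reshape(n, c, h, w)


class Upsample2x:
    """Nearest-neighbour 2x spatial upsampling."""

    params: list[Param] = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Flatten:
    params: list[Param] = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Dense:
    def __init__(
        self,
        din: int,
        dout: int,
        *,
        rng: np.random.Generator | None = None,
        zero_init: bool = False,
    ) -> None:
        if zero_init:
            w = np.zeros((din, dout))
        else:
            assert rng is not None
            w = _he_init(rng, (din, dout), din)
        self.w = Param(w, "dense.w")
        self.b = Param(np.zeros(dout), "dense.b")

    @property
    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.w.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value.T


class Sequential:
    def __init__(self, layers: list) -> None:
        self.layers = layers

    @property
    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params]

    def forward(self, x: np.ndarray, *, upto: int | None = None) -> np.ndarray:
        for layer in self.layers[:upto]:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_xent(
    logits: np.ndarray, y: np.ndarray, weight: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over rows and its gradient w.r.t. logits.

    logits: (N, K); y: (N,) integer labels; weight: optional (N,) sample
    weights (used to mask padded sequence frames).
    """
    n = logits.shape[0]
    p = softmax(logits, axis=1)
    if weight is None:
        weight = np.ones(n)
    wsum = weight.sum()
    if wsum <= 0:
        return 0.0, np.zeros_like(logits)
    logp = np.log(np.clip(p[np.arange(n), y], 1e-300, None))
    loss = float(-(weight * logp).sum() / wsum)
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    dlogits *= (weight / wsum)[:, None]
    return loss, dlogits
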