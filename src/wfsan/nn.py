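"""Minimal CPU neural-network primitives on numpy.

Reverse-mode layers with explicit caches: each layer exposes
``forward(x)`` and ``backward(dout)`` (returning the input gradient and
accumulating parameter gradients), plus ``params()``.  Shapes are
NCHW (batch, channels, height, width), float32 throughout.  Spatial
convolutions use zero 'same' padding so feature maps keep their size.

This is deliberately small: only what the wavelet-separation network
needs — dense and depthwise convolution, pixel shuffle, ReLU/Tanh/
hard-sigmoid, channel-wise pooling, concatenation — plus Adam with
global-norm gradient clipping.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32
"""Engine dtype; float32 by default, float64 for high-precision checks."""

__all__ = [
    "DTYPE",
    "Param",
    "Layer",
    "Conv2d",
    "DepthwiseConv2d",
    "ReLU",
    "Tanh",
    "HardSigmoid",
    "PixelShuffle",
    "Sequential",
    "hard_sigmoid",
    "global_norm",
    "clip_by_global_norm",
    "Adam",
]


class Param:
    """A trainable tensor with an accumulated gradient."""

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


def _he_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape)


def _glorot_uniform(
    rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int
) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _pad_same(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))


class Conv2d(Layer):
    """Dense 2-D convolution (cross-correlation), zero 'same' padding.

    Weight shape (out_ch, in_ch, k, k).  ``init`` selects He-uniform
    (ReLU paths) or Glorot-uniform (Tanh paths) fan-based scaling.
    """

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int,
        *,
        bias: bool = True,
        init: str = "he",
        rng: np.random.Generator | None = None,
        name: str = "conv",
    ) -> None:
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd")
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * kernel * kernel
        fan_out = out_ch * kernel * kernel
        shape = (out_ch, in_ch, kernel, kernel)
        if init == "he":
            w = _he_uniform(rng, shape, fan_in)
        elif init == "glorot":
            w = _glorot_uniform(rng, shape, fan_in, fan_out)
        else:
            raise ValueError(f"unknown init {init!r}")
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        self.W = Param(w, f"{name}.W")
        self.b = Param(np.zeros(out_ch), f"{name}.b") if bias else None
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.W] + ([self.b] if self.b is not None else [])

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {x.shape[1]}")
        b_, c, h, w = x.shape
        k, p = self.kernel, self.kernel // 2
        # channel-major layout with the padded grid kept flat: every
        # kernel offset is then a plain slice of one contiguous buffer,
        # so each offset costs a single (O × C)·(C × L) GEMM with no
        # im2col copy.  Positions whose window crosses a row or image
        # boundary land in the padded border region and are discarded.
        xpad = np.ascontiguousarray(
            _pad_same(np.asarray(x, dtype=DTYPE), p).transpose(1, 0, 2, 3)
        )  # (C, B, Hp, Wp)
        hp, wp = h + 2 * p, w + 2 * p
        n = b_ * hp * wp
        span = (k - 1) * wp + (k - 1)
        xflat = xpad.reshape(c, n)
        out_full = np.zeros((self.out_ch, n), dtype=DTYPE)
        acc = out_full[:, : n - span]
        for di in range(k):
            for dj in range(k):
                s = di * wp + dj
                acc += self.W.value[:, :, di, dj] @ xflat[:, s : s + n - span]
        out = out_full.reshape(self.out_ch, b_, hp, wp)[:, :, :h, :w]
        if self.b is not None:
            out = out + self.b.value[:, None, None, None]
        self._cache = (xflat, x.shape)
        return np.ascontiguousarray(out.transpose(1, 0, 2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xflat, xshape = self._cache
        b_, cin, h, w = xshape
        k, p = self.kernel, self.kernel // 2
        hp, wp = h + 2 * p, w + 2 * p
        n = b_ * hp * wp
        span = (k - 1) * wp + (k - 1)
        dout = np.asarray(dout, dtype=DTYPE)
        if self.b is not None:
            self.b.grad += dout.sum(axis=(0, 2, 3))
        # embed dout at the window-anchor positions of the padded grid
        dfull = np.zeros((self.out_ch, b_, hp, wp), dtype=DTYPE)
        dfull[:, :, :h, :w] = dout.transpose(1, 0, 2, 3)
        dflat = dfull.reshape(self.out_ch, n)
        dvalid = dflat[:, : n - span]
        for di in range(k):
            for dj in range(k):
                s = di * wp + dj
                self.W.grad[:, :, di, dj] += dvalid @ xflat[:, s : s + n - span].T
        # input gradient = convolution of dout with the flipped kernels
        dpad = np.zeros((self.out_ch, b_, hp, wp), dtype=DTYPE)
        dpad[:, :, p : p + h, p : p + w] = dfull[:, :, :h, :w]
        dpflat = dpad.reshape(self.out_ch, n)
        dx_full = np.zeros((cin, n), dtype=DTYPE)
        dacc = dx_full[:, : n - span]
        for ei in range(k):
            for ej in range(k):
                s = ei * wp + ej
                dacc += (
                    self.W.value[:, :, k - 1 - ei, k - 1 - ej].T
                    @ dpflat[:, s : s + n - span]
                )
        dx = dx_full.reshape(cin, b_, hp, wp)[:, :, :h, :w]
        return np.ascontiguousarray(dx.transpose(1, 0, 2, 3))


class DepthwiseConv2d(Layer):
    """Per-channel ("cheap") 2-D convolution; no channel mixing.

    Weight shape (C, k, k); bias-free by default — this is the linear
    operation φ of the ghost blocks.
    """

    def __init__(
        self,
        channels: int,
        kernel: int,
        *,
        bias: bool = False,
        init: str = "he",
        rng: np.random.Generator | None = None,
        name: str = "dwconv",
    ) -> None:
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd")
        rng = rng or np.random.default_rng(0)
        fan_in = kernel * kernel
        shape = (channels, kernel, kernel)
        if init == "he":
            w = _he_uniform(rng, shape, fan_in)
        else:
            w = _glorot_uniform(rng, shape, fan_in, fan_in)
        self.channels, self.kernel = channels, kernel
        self.W = Param(w, f"{name}.W")
        self.b = Param(np.zeros(channels), f"{name}.b") if bias else None
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.W] + ([self.b] if self.b is not None else [])

    @staticmethod
    def identity_kernel(channels: int, kernel: int) -> np.ndarray:
        """Centered-delta kernels: φ(F) == F.  Used to verify wiring."""
        w = np.zeros((channels, kernel, kernel), dtype=DTYPE)
        w[:, kernel // 2, kernel // 2] = 1.0
        return w

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {x.shape[1]}")
        b_, c, h, w = x.shape
        k, p = self.kernel, self.kernel // 2
        xpad = np.ascontiguousarray(
            _pad_same(np.asarray(x, dtype=DTYPE), p).transpose(1, 0, 2, 3)
        )
        hp, wp = h + 2 * p, w + 2 * p
        n = b_ * hp * wp
        span = (k - 1) * wp + (k - 1)
        xflat = xpad.reshape(c, n)
        out_full = np.zeros((c, n), dtype=DTYPE)
        acc = out_full[:, : n - span]
        for di in range(k):
            for dj in range(k):
                s = di * wp + dj
                acc += self.W.value[:, di, dj, None] * xflat[:, s : s + n - span]
        out = out_full.reshape(c, b_, hp, wp)[:, :, :h, :w]
        if self.b is not None:
            out = out + self.b.value[:, None, None, None]
        self._cache = (xflat, x.shape)
        return np.ascontiguousarray(out.transpose(1, 0, 2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xflat, xshape = self._cache
        b_, c, h, w = xshape
        k, p = self.kernel, self.kernel // 2
        hp, wp = h + 2 * p, w + 2 * p
        n = b_ * hp * wp
        span = (k - 1) * wp + (k - 1)
        dout = np.asarray(dout, dtype=DTYPE)
        if self.b is not None:
            self.b.grad += dout.sum(axis=(0, 2, 3))
        dfull = np.zeros((c, b_, hp, wp), dtype=DTYPE)
        dfull[:, :, :h, :w] = dout.transpose(1, 0, 2, 3)
        dflat = dfull.reshape(c, n)
        dvalid = dflat[:, : n - span]
        for di in range(k):
            for dj in range(k):
                s = di * wp + dj
                self.W.grad[:, di, dj] += np.einsum(
                    "cl,cl->c", dvalid, xflat[:, s : s + n - span], optimize=True
                )
        dpad = np.zeros((c, b_, hp, wp), dtype=DTYPE)
        dpad[:, :, p : p + h, p : p + w] = dfull[:, :, :h, :w]
        dpflat = dpad.reshape(c, n)
        dx_full = np.zeros((c, n), dtype=DTYPE)
        dacc = dx_full[:, : n - span]
        for ei in range(k):
            for ej in range(k):
                s = ei * wp + ej
                dacc += self.W.value[:, k - 1 - ei, k - 1 - ej, None] * dpflat[
                    :, s : s + n - span
                ]
        dx = dx_full.reshape(c, b_, hp, wp)[:, :, :h, :w]
        return np.ascontiguousarray(dx.transpose(1, 0, 2, 3))


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(DTYPE)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0.0).astype(DTYPE)


class Tanh(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = np.tanh(x).astype(DTYPE)
        return self._y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return (dout * (1.0 - self._y * self._y)).astype(DTYPE)


def hard_sigmoid(x: np.ndarray) -> np.ndarray:
    """Piecewise-linear sigmoid gate: clamp((x + 3) / 6, 0, 1)."""
    return np.clip((x + 3.0) / 6.0, 0.0, 1.0)


class HardSigmoid(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._open = (x > -3.0) & (x < 3.0)
        return hard_sigmoid(x).astype(DTYPE)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._open, dout / 6.0, 0.0).astype(DTYPE)


class PixelShuffle(Layer):
    """Periodic rearrangement (B, C·s², H, W) → (B, C, sH, sW).

    out[b, c, s·h + i, s·w + j] = in[b, c·s² + i·s + j, h, w] — a pure
    permutation of values (bijective), matching the sub-pixel
    convolution layout.
    """

    def __init__(self, scale: int) -> None:
        if scale < 2:
            raise ValueError("pixel shuffle scale must be >= 2")
        self.scale = scale

    def forward(self, x: np.ndarray) -> np.ndarray:
        s = self.scale
        b_, c_in, h, w = x.shape
        if c_in % (s * s) != 0:
            raise ValueError(f"channels {c_in} not divisible by scale^2={s * s}")
        c = c_in // (s * s)
        self._inshape = x.shape
        y = x.reshape(b_, c, s, s, h, w).transpose(0, 1, 4, 2, 5, 3)
        return np.ascontiguousarray(y.reshape(b_, c, h * s, w * s))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        s = self.scale
        b_, c_in, h, w = self._inshape
        c = c_in // (s * s)
        d = dout.reshape(b_, c, h, s, w, s).transpose(0, 1, 3, 5, 2, 4)
        return np.ascontiguousarray(d.reshape(b_, c_in, h, w))


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        self.layers = list(layers)

    def params(self) -> list[Param]:
        out: list[Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


def global_norm(params: list[Param]) -> float:
    total = 0.0
    for p in params:
        total += float(np.sum(p.grad.astype(np.float64) ** 2))
    return float(np.sqrt(total))


def clip_by_global_norm(params: list[Param], max_norm: float) -> float:
    """Scale all gradients so their joint L2 norm is at most ``max_norm``.

    Returns the pre-clip norm.
    """
    norm = global_norm(params)
    if norm > max_norm and norm > 0.0:
        scale = max_norm / norm
        for p in params:
            p.grad *= scale
    return norm


class Adam:
    """Adam optimizer (Kingma & Ba defaults β1=0.9, β2=0.999, ε=1e-8)."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1.0 - b1) * p.grad
            v *= b2
            v += (1.0 - b2) * p.grad * p.grad
            mhat = m / bias1
            vhat = v / bias2
            p.value -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(DTYPE)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
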