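"""Minimal CNN layer library with hand-written backpropagation on numpy.

Provides exactly the primitives the segmentation network needs: 2-D
convolution (im2col + BLAS matmul), 2x2/stride-2 transposed convolution,
batch normalization, ReLU, nearest-neighbor upsampling, channel softmax,
and the Adam optimizer.  Every layer caches what its backward pass needs
during ``forward`` and accumulates parameter gradients into ``Param.grad``.

All tensors are ``float32`` arrays in NCHW layout.  Forward passes are
deterministic; a fixed initialisation seed therefore makes whole-model
outputs bit-reproducible across runs on the same machine.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Param:
    """A trainable array plus its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.ascontiguousarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    """Base class: forward/backward with cached intermediates."""

    def params(self) -> list[Param]:
        return []

    def buffers(self) -> list[np.ndarray]:
        """Non-trainable state (e.g. BN running statistics)."""
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def he_normal(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Layer):
    """k x k convolution, zero padding, square stride.

    Weight layout ``(out_ch, in_ch, k, k)``.  Forward unfolds the input
    (``sliding_window_view``) and runs a single matmul; backward re-folds
    the column gradient with nine strided slice-adds (for k=3), avoiding
    any scatter loop over pixels.
    """

    def __init__(self, in_ch: int, out_ch: int, k: int = 3, stride: int = 1,
                 pad: int | None = None, bias: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.in_ch, self.out_ch, self.k, self.stride = in_ch, out_ch, k, stride
        self.pad = (k // 2) if pad is None else pad
        fan_in = in_ch * k * k
        self.weight = Param(he_normal(rng, (out_ch, in_ch, k, k), fan_in), "conv.w")
        self.bias = Param(np.zeros(out_ch), "conv.b") if bias else None
        self._cache = None

    def params(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def out_size(self, h: int, w: int) -> tuple[int, int]:
        k, s, p = self.k, self.stride, self.pad
        return (h + 2 * p - k) // s + 1, (w + 2 * p - k) // s + 1

    def macs(self, h: int, w: int) -> int:
        ho, wo = self.out_size(h, w)
        return self.k * self.k * self.in_ch * self.out_ch * ho * wo

    def _unfold(self, x: np.ndarray) -> tuple[np.ndarray, tuple]:
        n, c, h, w = x.shape
        p, k, s = self.pad, self.k, self.stride
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s]                      # (n, c, ho, wo, k, k)
        ho, wo = win.shape[2], win.shape[3]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5))
        return cols.reshape(n * ho * wo, c * k * k), (n, c, h, w, ho, wo)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        cols, geom = self._unfold(x)
        n, c, h, w, ho, wo = geom
        wmat = self.weight.value.reshape(self.out_ch, -1)
        y = cols @ wmat.T
        if self.bias is not None:
            y += self.bias.value
        self._cache = (cols, geom)
        return np.ascontiguousarray(
            y.reshape(n, ho, wo, self.out_ch).transpose(0, 3, 1, 2))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, (n, c, h, w, ho, wo) = self._cache
        k, s, p = self.k, self.stride, self.pad
        dyf = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(-1, self.out_ch)
        wmat = self.weight.value.reshape(self.out_ch, -1)
        self.weight.grad += (dyf.T @ cols).reshape(self.weight.value.shape)
        if self.bias is not None:
            self.bias.grad += dyf.sum(axis=0)
        dcols = (dyf @ wmat).reshape(n, ho, wo, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=DTYPE)
        for ky in range(k):
            for kx in range(k):
                dxp[:, :, ky:ky + s * ho:s, kx:kx + s * wo:s] += \
                    dcols[:, :, :, :, ky, kx].transpose(0, 3, 1, 2)
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class ConvTranspose2x(Layer):
    """2x2 transposed convolution with stride 2 (non-overlapping upsample).

    Weight layout ``(in_ch, out_ch, 2, 2)``; each input pixel paints a
    2x2 output patch, so forward/backward are plain reshaped matmuls.
    """

    def __init__(self, in_ch: int, out_ch: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.in_ch, self.out_ch = in_ch, out_ch
        self.weight = Param(he_normal(rng, (in_ch, out_ch, 2, 2), in_ch), "convT.w")
        self.bias = Param(np.zeros(out_ch), "convT.b") if bias else None
        self._cache = None

    def params(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def macs(self, h: int, w: int) -> int:
        return 4 * self.in_ch * self.out_ch * h * w

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        xf = np.ascontiguousarray(x.transpose(0, 2, 3, 1)).reshape(-1, c)
        y = xf @ self.weight.value.reshape(c, -1)       # (n*h*w, out*4)
        y = y.reshape(n, h, w, self.out_ch, 2, 2)
        y = np.ascontiguousarray(y.transpose(0, 3, 1, 4, 2, 5))
        y = y.reshape(n, self.out_ch, 2 * h, 2 * w)
        if self.bias is not None:
            y += self.bias.value[None, :, None, None]
        self._cache = (xf, (n, c, h, w))
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xf, (n, c, h, w) = self._cache
        dyr = dy.reshape(n, self.out_ch, h, 2, w, 2)
        dyf = np.ascontiguousarray(dyr.transpose(0, 2, 4, 1, 3, 5)).reshape(
            n * h * w, self.out_ch * 4)
        self.weight.grad += (xf.T @ dyf).reshape(self.weight.value.shape)
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=(0, 2, 3))
        dx = dyf @ self.weight.value.reshape(c, -1).T
        return np.ascontiguousarray(dx.reshape(n, h, w, c).transpose(0, 3, 1, 2))


class UpsampleNearest2x(Layer):
    """Parameter-free nearest-neighbor x2 upsampling."""

    def macs(self, h: int, w: int) -> int:
        return 0

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return dy.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5))


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, ch: int, eps: float = 1e-5, momentum: float = 0.1):
        self.ch, self.eps, self.momentum = ch, eps, momentum
        self.gamma = Param(np.ones(ch), "bn.gamma")
        self.beta = Param(np.zeros(ch), "bn.beta")
        self.running_mean = np.zeros(ch, dtype=DTYPE)
        self.running_var = np.ones(ch, dtype=DTYPE)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def buffers(self):
        return [self.running_mean, self.running_var]

    def macs(self, h: int, w: int) -> int:
        return 0

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std, train)
        return (self.gamma.value[None, :, None, None] * xhat
                + self.beta.value[None, :, None, None]).astype(DTYPE)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std, train = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None] * inv_std[None, :, None, None]
        if not train:
            return (dy * g).astype(DTYPE)
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        dxhat = dy * self.gamma.value[None, :, None, None]
        s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (inv_std[None, :, None, None]
                * (dxhat - s1 / m - xhat * s2 / m)).astype(DTYPE)


class ReLU(Layer):
    def macs(self, h: int, w: int) -> int:
        return 0

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(DTYPE)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0).astype(DTYPE)


class SoftmaxChannel(Layer):
    """Softmax over the channel axis; caches probabilities for backward."""

    def macs(self, h: int, w: int) -> int:
        return 0

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        z = x - x.max(axis=1, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=1, keepdims=True)
        self._p = p.astype(DTYPE)
        return self._p

    def backward(self, dp: np.ndarray) -> np.ndarray:
        p = self._p
        dot = (dp * p).sum(axis=1, keepdims=True)
        return (p * (dp - dot)).astype(DTYPE)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def buffers(self):
        return [b for l in self.layers for b in l.buffers()]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class Adam:
    """Adam with bias correction; ``beta1`` is the momentum of Table-2 lore."""

    def __init__(self, params: list[Param], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.beta1) * (p.grad - m)
            v += (1.0 - self.beta2) * (p.grad * p.grad - v)
            p.value -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)
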