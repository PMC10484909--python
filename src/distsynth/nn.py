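"""Minimal convolutional network layers with explicit backpropagation.

All model components in this package (the mask-conditioned generator, the
patch discriminators, the downstream U-Net and the fixed random feature
extractors) are built from the layers defined here.  Every layer implements
``forward(x, train)`` and ``backward(dout)``; parameters are held in
:class:`Param` objects whose ``grad`` buffers are filled by ``backward`` and
consumed by :class:`Adam`.

Arrays are ``float64`` NCHW throughout.  Convolutions use an im2col layout
built from stride-tricks views, so batch sizes and spatial extents are only
limited by memory.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param", "Module", "Sequential", "Conv2d", "ConvTranspose2d",
    "BatchNorm2d", "ReLU", "LeakyReLU", "Tanh", "Sigmoid", "Dropout",
    "ResidualBlock", "Adam", "RngBox",
]


class Param:
    """A learnable tensor plus its gradient buffer."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


class Module:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    # -- checkpoint helpers ------------------------------------------------
    def state(self) -> list[np.ndarray]:
        """All arrays needed to restore the module bit-exactly."""
        return [p.value for p in self.params()]

    def load_state(self, arrays: list[np.ndarray]) -> None:
        own = self.state()
        if len(own) != len(arrays):
            raise ValueError(f"state length mismatch: {len(own)} vs {len(arrays)}")
        for dst, src in zip(own, arrays):
            if dst.shape != np.asarray(src).shape:
                raise ValueError("state shape mismatch")
            dst[...] = src


class RngBox:
    """Shared mutable RNG handle so dropout layers inside a network draw from
    one replaceable stream."""

    def __init__(self, rng: np.random.Generator | None = None):
        self.rng = rng if rng is not None else np.random.default_rng(0)


def _im2col(xp: np.ndarray, k: int, stride: int):
    # xp already padded; returns view (N, C, Hout, Wout, k, k)
    v = sliding_window_view(xp, (k, k), axis=(2, 3))
    return v[:, :, ::stride, ::stride]


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 pad: int = 0, bias: bool = True, rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        fan_in = in_ch * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch, kernel, kernel))
        self.w = Param(w)
        self.b = Param(np.zeros(out_ch)) if bias else None
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self._cache = None

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x, train=False):
        k, s, p = self.kernel, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        cols = _im2col(xp, k, s)
        out = np.einsum("nchwkl,ockl->nohw", cols, self.w.value, optimize=True)
        if self.b is not None:
            out += self.b.value[None, :, None, None]
        self._cache = (x.shape, cols)
        return out

    def backward(self, dout):
        k, s, p = self.kernel, self.stride, self.pad
        x_shape, cols = self._cache
        self.w.grad += np.einsum("nohw,nchwkl->ockl", dout, cols, optimize=True)
        if self.b is not None:
            self.b.grad += dout.sum(axis=(0, 2, 3))
        n, c, h, w_ = x_shape
        hp, wp = h + 2 * p, w_ + 2 * p
        dxp = np.zeros((n, c, hp, wp))
        ho, wo = dout.shape[2], dout.shape[3]
        dcols = np.einsum("nohw,ockl->nchwkl", dout, self.w.value, optimize=True)
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki:ki + s * ho:s, kj:kj + s * wo:s] += dcols[:, :, :, :, ki, kj]
        return dxp[:, :, p:p + h, p:p + w_] if p else dxp


class ConvTranspose2d(Module):
    """Transposed convolution (fractionally-strided); the exact adjoint of
    :class:`Conv2d` with the same kernel/stride/pad, plus ``output_pad``."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 2,
                 pad: int = 1, output_pad: int = 1, bias: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        fan_in = in_ch * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(in_ch, out_ch, kernel, kernel))
        self.w = Param(w)
        self.b = Param(np.zeros(out_ch)) if bias else None
        self.kernel, self.stride, self.pad, self.output_pad = kernel, stride, pad, output_pad
        self._cache = None

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def out_size(self, h: int) -> int:
        return (h - 1) * self.stride - 2 * self.pad + self.kernel + self.output_pad

    def forward(self, x, train=False):
        k, s, p = self.kernel, self.stride, self.pad
        n, c, h, w_ = x.shape
        ho, wo = self.out_size(h), self.out_size(w_)
        full_h, full_w = (h - 1) * s + k, (w_ - 1) * s + k
        outp = np.zeros((n, self.w.value.shape[1], full_h, full_w))
        for ki in range(k):
            for kj in range(k):
                outp[:, :, ki:ki + s * h:s, kj:kj + s * w_:s] += np.einsum(
                    "nchw,co->nohw", x, self.w.value[:, :, ki, kj], optimize=True)
        out = outp[:, :, p:p + ho, p:p + wo]
        if out.shape[2] < ho or out.shape[3] < wo:  # output_pad beyond full extent
            out = np.pad(out, ((0, 0), (0, 0), (0, ho - out.shape[2]), (0, wo - out.shape[3])))
        if self.b is not None:
            out = out + self.b.value[None, :, None, None]
        self._cache = (x, (full_h, full_w), (ho, wo))
        return out

    def backward(self, dout):
        k, s, p = self.kernel, self.stride, self.pad
        x, (full_h, full_w), (ho, wo) = self._cache
        n, c, h, w_ = x.shape
        if self.b is not None:
            self.b.grad += dout.sum(axis=(0, 2, 3))
        dfull = np.zeros((n, dout.shape[1], full_h, full_w))
        eh = min(ho, full_h - p)
        ew = min(wo, full_w - p)
        dfull[:, :, p:p + eh, p:p + ew] = dout[:, :, :eh, :ew]
        dx = np.zeros_like(x)
        for ki in range(k):
            for kj in range(k):
                window = dfull[:, :, ki:ki + s * h:s, kj:kj + s * w_:s]
                dx += np.einsum("nohw,co->nchw", window, self.w.value[:, :, ki, kj],
                                optimize=True)
                self.w.grad[:, :, ki, kj] += np.einsum("nchw,nohw->co", x, window,
                                                       optimize=True)
        return dx


class BatchNorm2d(Module):
    def __init__(self, n_ch: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Param(np.ones(n_ch))
        self.beta = Param(np.zeros(n_ch))
        self.running_mean = np.zeros(n_ch)
        self.running_var = np.ones(n_ch)
        self.eps, self.momentum = eps, momentum
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def state(self):
        return [self.gamma.value, self.beta.value, self.running_mean, self.running_var]

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, train, x.shape)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, dout):
        xhat, inv, train, shape = self._cache
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None]
        if not train:
            return dout * g * inv[None, :, None, None]
        m = shape[0] * shape[2] * shape[3]
        dxhat = dout * g
        term = dxhat - dxhat.mean(axis=(0, 2, 3), keepdims=True) \
            - xhat * (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True) / m
        return term * inv[None, :, None, None]


class ReLU(Module):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dout):
        return np.where(self._mask, dout, self.slope * dout)


class Tanh(Module):
    def forward(self, x, train=False):
        self._out = np.tanh(x)
        return self._out

    def backward(self, dout):
        return dout * (1.0 - self._out ** 2)


class Sigmoid(Module):
    def forward(self, x, train=False):
        self._out = 1.0 / (1.0 + np.exp(-x))
        return self._out

    def backward(self, dout):
        return dout * self._out * (1.0 - self._out)


class Dropout(Module):
    """Inverted dropout drawing from a shared :class:`RngBox` stream.

    ``always_on`` keeps the layer stochastic outside training, which the
    generator uses as its noise source at sampling time.
    """

    def __init__(self, rate: float, rngbox: RngBox, always_on: bool = False):
        self.rate, self.rngbox, self.always_on = rate, rngbox, always_on
        self._mask = None

    def forward(self, x, train=False):
        if self.rate <= 0.0 or not (train or self.always_on):
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rngbox.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def state(self):
        return [a for l in self.layers for a in l.state()]

    def load_state(self, arrays):
        i = 0
        for l in self.layers:
            n = len(l.state())
            l.load_state(arrays[i:i + n])
            i += n

    def forward(self, x, train=False):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, dout):
        for l in reversed(self.layers):
            dout = l.backward(dout)
        return dout


class ResidualBlock(Module):
    """conv-bn-relu-[dropout]-conv-bn plus identity skip."""

    def __init__(self, n_ch: int, dropout_rate: float, rngbox: RngBox,
                 dropout_always_on: bool, rng: np.random.Generator):
        self.branch = Sequential(
            Conv2d(n_ch, n_ch, 3, 1, 1, rng=rng),
            BatchNorm2d(n_ch),
            ReLU(),
            Dropout(dropout_rate, rngbox, always_on=dropout_always_on),
            Conv2d(n_ch, n_ch, 3, 1, 1, rng=rng),
            BatchNorm2d(n_ch),
        )

    def params(self):
        return self.branch.params()

    def state(self):
        return self.branch.state()

    def load_state(self, arrays):
        self.branch.load_state(arrays)

    def forward(self, x, train=False):
        return x + self.branch.forward(x, train)

    def backward(self, dout):
        return dout + self.branch.backward(dout)


class Adam:
    """Adam with per-parameter moment buffers; beta1 defaults to the GAN
    convention 0.5 (pass 0.9 for ordinary supervised fits)."""

    def __init__(self, params: list[Param], lr: float = 2e-4, beta1: float = 0.5,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.b1) * (p.grad - m)
            v += (1.0 - self.b2) * (p.grad ** 2 - v)
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0
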