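from __future__ import annotations

from typing import Iterator

import numpy as np

from .core import Layer, Param

__all__ = [
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "ConvTranspose2x2",
    "BilinearUp2",
    "Linear",
    "Sigmoid",
    "SEBlock",
]


def _im2col(xp: np.ndarray, k: int, H: int, W: int) -> np.ndarray:
    # xp: padded input (N, C, H+k-1, W+k-1) for 'same' stride-1 conv
    N, C = xp.shape[:2]
    cols = np.empty((N, C, k, k, H, W), dtype=xp.dtype)
    for a in range(k):
        for b in range(k):
            cols[:, :, a, b] = xp[:, :, a : a + H, b : b + W]
    return cols.reshape(N, C * k * k, H * W)


def _col2im(gcols: np.ndarray, k: int, C: int, H: int, W: int) -> np.ndarray:
    N = gcols.shape[0]
    g = gcols.reshape(N, C, k, k, H, W)
    pad = k // 2
    gx = np.zeros((N, C, H + 2 * pad, W + 2 * pad), dtype=gcols.dtype)
    for a in range(k):
        for b in range(k):
            gx[:, :, a : a + H, b : b + W] += g[:, :, a, b]
    if pad:
        return gx[:, :, pad:-pad, pad:-pad]
    return gx


class Conv2d(Layer):
    """Stride-1 'same' convolution (odd kernel) via im2col."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator) -> None:
        if kernel % 2 != 1:
            raise ValueError("Conv2d supports odd kernels only")
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, kernel
        fan_in = in_ch * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        self.weight = Param(rng.normal(0.0, scale, size=(out_ch, fan_in)), "conv.w")
        self.bias = Param(np.zeros(out_ch), "conv.b")
        self._cache: tuple | None = None

    def params(self) -> Iterator[Param]:
        yield self.weight
        yield self.bias

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, C, H, W = x.shape
        pad = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        cols = _im2col(xp, self.k, H, W)
        out = np.einsum("oc,ncf->nof", self.weight.data, cols, optimize=True)
        out += self.bias.data[None, :, None]
        self._cache = (cols, (N, C, H, W))
        return out.reshape(N, self.out_ch, H, W)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        cols, (N, C, H, W) = self._cache
        go = grad_out.reshape(N, self.out_ch, H * W)
        self.weight.grad += np.einsum("nof,ncf->oc", go, cols, optimize=True)
        self.bias.grad += go.sum(axis=(0, 2))
        gcols = np.einsum("oc,nof->ncf", self.weight.data, go, optimize=True)
        return _col2im(gcols, self.k, C, H, W)


class BatchNorm2d(Layer):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        self.gamma = Param(np.ones(channels), "bn.gamma")
        self.beta = Param(np.zeros(channels), "bn.beta")
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        self._cache: tuple | None = None

    def params(self) -> Iterator[Param]:
        yield self.gamma
        yield self.beta

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) / std[None, :, None, None]
        self._cache = (xhat, std)
        return self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        xhat, std = self._cache
        axes = (0, 2, 3)
        self.gamma.grad += (grad_out * xhat).sum(axis=axes)
        self.beta.grad += grad_out.sum(axis=axes)
        if not self.training:
            return grad_out * (self.gamma.data / std)[None, :, None, None]
        m = grad_out.shape[0] * grad_out.shape[2] * grad_out.shape[3]
        g = grad_out * self.gamma.data[None, :, None, None]
        gm = g.mean(axis=axes, keepdims=True)
        gxm = (g * xhat).mean(axis=axes, keepdims=True)
        return (g - gm - xhat * gxm) / std[None, :, None, None]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return grad_out * self._mask


class Sigmoid(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        # overflow-safe in both tails
        self._out = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                             np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
        return self._out

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return grad_out * self._out * (1.0 - self._out)


class MaxPool2d(Layer):
    """2x2, stride 2."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, C, H, W = x.shape
        if H % 2 or W % 2:
            raise ValueError(f"MaxPool2d needs even spatial dims, got {H}x{W}")
        xr = x.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            N, C, H // 2, W // 2, 4
        )
        self._argmax = xr.argmax(axis=-1)
        self._shape = (N, C, H, W)
        return np.take_along_axis(xr, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        N, C, H, W = self._shape
        g4 = np.zeros((N, C, H // 2, W // 2, 4), dtype=grad_out.dtype)
        np.put_along_axis(g4, self._argmax[..., None], grad_out[..., None], axis=-1)
        return (
            g4.reshape(N, C, H // 2, W // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(N, C, H, W)
        )


class ConvTranspose2x2(Layer):
    """Kernel-2, stride-2 transposed convolution (non-overlapping blocks)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator) -> None:
        self.in_ch, self.out_ch = in_ch, out_ch
        scale = np.sqrt(2.0 / in_ch)
        self.weight = Param(rng.normal(0.0, scale, size=(in_ch, out_ch, 2, 2)), "upconv.w")
        self.bias = Param(np.zeros(out_ch), "upconv.b")

    def params(self) -> Iterator[Param]:
        yield self.weight
        yield self.bias

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        N, C, H, W = x.shape
        out = np.einsum("ncij,coab->noiajb", x, self.weight.data, optimize=True)
        out = out.reshape(N, self.out_ch, 2 * H, 2 * W)
        return out + self.bias.data[None, :, None, None]

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        N, O, H2, W2 = grad_out.shape
        g = grad_out.reshape(N, O, H2 // 2, 2, W2 // 2, 2)
        self.bias.grad += grad_out.sum(axis=(0, 2, 3))
        self.weight.grad += np.einsum("ncij,noiajb->coab", self._x, g, optimize=True)
        return np.einsum("noiajb,coab->ncij", g, self.weight.data, optimize=True)


class BilinearUp2(Layer):
    """Parameter-free 2x bilinear upsampling (half-pixel-center convention)."""

    def _indices(self, n_in: int):
        pos = (np.arange(2 * n_in) + 0.5) / 2.0 - 0.5
        lo = np.clip(np.floor(pos).astype(int), 0, n_in - 1)
        hi = np.clip(lo + 1, 0, n_in - 1)
        frac = np.clip(pos - np.floor(pos), 0.0, 1.0)
        frac[pos < 0] = 0.0
        return lo, hi, frac

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, C, H, W = x.shape
        rlo, rhi, rf = self._indices(H)
        clo, chi, cf = self._indices(W)
        self._cache = (x.shape, rlo, rhi, rf, clo, chi, cf)
        top = x[:, :, rlo, :] * (1 - rf)[None, None, :, None] + x[:, :, rhi, :] * rf[None, None, :, None]
        return (
            top[:, :, :, clo] * (1 - cf)[None, None, None, :]
            + top[:, :, :, chi] * cf[None, None, None, :]
        )

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        (N, C, H, W), rlo, rhi, rf, clo, chi, cf = self._cache
        gtop = np.zeros((N, C, 2 * H, W), dtype=grad_out.dtype)
        np.add.at(gtop, (slice(None), slice(None), slice(None), clo), grad_out * (1 - cf)[None, None, None, :])
        np.add.at(gtop, (slice(None), slice(None), slice(None), chi), grad_out * cf[None, None, None, :])
        gx = np.zeros((N, C, H, W), dtype=grad_out.dtype)
        np.add.at(gx, (slice(None), slice(None), rlo), gtop * (1 - rf)[None, None, :, None])
        np.add.at(gx, (slice(None), slice(None), rhi), gtop * rf[None, None, :, None])
        return gx


class Linear(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator) -> None:
        scale = np.sqrt(2.0 / in_dim)
        self.weight = Param(rng.normal(0.0, scale, size=(out_dim, in_dim)), "fc.w")
        self.bias = Param(np.zeros(out_dim), "fc.b")

    def params(self) -> Iterator[Param]:
        yield self.weight
        yield self.bias

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.weight.data.T + self.bias.data

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        self.weight.grad += grad_out.T @ self._x
        self.bias.grad += grad_out.sum(axis=0)
        return grad_out @ self.weight.data


class SEBlock(Layer):
    """Squeeze-and-excitation channel attention.

    Squeeze: global average pool per channel.  Excitation: a bottlenecked
    two-layer transform FC(C -> C/r) -> ReLU -> FC(C/r -> C) -> sigmoid
    whose output rescales each channel by a scalar in (0, 1).
    """

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator) -> None:
        if reduction < 1:
            raise ValueError("reduction must be >= 1")
        hidden = max(1, channels // reduction)
        self.channels = channels
        self.fc1 = Linear(channels, hidden, rng)
        self.relu = ReLU()
        self.fc2 = Linear(hidden, channels, rng)
        self.sigmoid = Sigmoid()

    def params(self) -> Iterator[Param]:
        yield from self.fc1.params()
        yield from self.fc2.params()

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] != self.channels:
            raise ValueError(f"SEBlock built for {self.channels} channels, got {x.shape[1]}")
        z = x.mean(axis=(2, 3))  # squeeze: (N, C)
        s = self.sigmoid(self.fc2(self.relu(self.fc1(z))))
        self._x, self._s = x, s
        return x * s[:, :, None, None]

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        x, s = self._x, self._s
        gs = (grad_out * x).sum(axis=(2, 3))  # (N, C)
        gz = self.fc1.backward(self.relu.backward(self.fc2.backward(self.sigmoid.backward(gs))))
        gx = grad_out * s[:, :, None, None]
        H, W = x.shape[2], x.shape[3]
        gx += gz[:, :, None, None] / (H * W)
        return gx
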