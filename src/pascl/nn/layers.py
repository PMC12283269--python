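"""Layers with explicit forward/backward passes, in plain numpy.

Convolutions run either as im2col + one BLAS matmul (cheap for few input
channels) or as FFT cross-correlation (cheaper when the im2col buffer
would be large); both give identical results and gradients up to float
rounding. Weights are initialised with uniform fan-in scaling
(U(-1/sqrt(fan_in), 1/sqrt(fan_in))) from a caller-supplied generator,
which keeps whole-model initialisation reproducible from one seed.
Parameters and activations are single precision, which is ample for these
small networks.
"""

from __future__ import annotations

import numpy as np
import scipy.fft as sfft
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "MaxPool2d",
    "ReLU",
    "Flatten",
    "Linear",
    "Sequential",
]


DTYPE = np.float32


class Param:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)


def _fan_in_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(DTYPE)


class Layer:
    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []


class Conv2d(Layer):
    """2-D cross-correlation with odd square kernels and 'same' zero padding.

    ``method`` selects the compute path: ``"im2col"``, ``"fft"`` or
    ``"auto"`` (FFT once the im2col patch width in_channels*k*k is large).
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, method: str = "auto"):
        if kernel_size % 2 != 1:
            raise ValueError("kernel size must be odd for same-padding")
        if method not in ("auto", "im2col", "fft"):
            raise ValueError("method must be 'auto', 'im2col' or 'fft'")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.k = kernel_size
        fan_in = in_channels * kernel_size * kernel_size
        self.W = Param(
            _fan_in_uniform(rng, (out_channels, in_channels, kernel_size, kernel_size), fan_in)
        )
        self.b = Param(_fan_in_uniform(rng, (out_channels,), fan_in))
        if method == "auto":
            method = "fft" if fan_in >= 64 else "im2col"
        self.method = method
        self._cols_cache: np.ndarray | None = None
        self._xf_cache: np.ndarray | None = None

    def _cols(self, xp: np.ndarray, H: int, W: int) -> np.ndarray:
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))  # (B,C,H,W,k,k)
        return win.transpose(0, 2, 3, 1, 4, 5).reshape(
            xp.shape[0] * H * W, self.in_channels * self.k * self.k
        )

    def _fft_shape(self, H: int, W: int) -> tuple[int, int]:
        p = self.k // 2
        return sfft.next_fast_len(H + 2 * p), sfft.next_fast_len(W + 2 * p)

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=DTYPE)
        B, C, H, W = x.shape
        if C != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {C}")
        p = self.k // 2
        self._hw = (H, W)
        if self.method == "fft":
            fh, fw = self._fft_shape(H, W)
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
            xf = sfft.rfft2(xp, s=(fh, fw))
            self._xf_cache = xf
            wf = sfft.rfft2(self.W.value, s=(fh, fw))
            out_f = np.einsum("bcxy,ocxy->boxy", xf, np.conj(wf))
            out = sfft.irfft2(out_f, s=(fh, fw))[:, :, :H, :W]
            return out + self.b.value[None, :, None, None]
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        cols = self._cols(xp, H, W)
        self._cols_cache = cols
        wmat = self.W.value.reshape(self.out_channels, -1)
        out = cols @ wmat.T + self.b.value
        return out.reshape(B, H, W, self.out_channels).transpose(0, 3, 1, 2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = np.asarray(grad, dtype=DTYPE)
        B, _, H, W = grad.shape
        p = self.k // 2
        if self.method == "fft":
            fh, fw = self._fft_shape(H, W)
            dy_f = sfft.rfft2(grad, s=(fh, fw))
            xf = self._xf_cache
            # dW = corr(x_padded, dy): spectrum X . conj(DY), crop to k x k
            dw_f = np.einsum("bcxy,boxy->ocxy", xf, np.conj(dy_f))
            self.W.grad += sfft.irfft2(dw_f, s=(fh, fw))[:, :, : self.k, : self.k]
            self.b.grad += grad.sum(axis=(0, 2, 3))
            # dx_padded = conv(dy, W): spectrum DY . W (wraparound-free by padding)
            dx_f = np.einsum("boxy,ocxy->bcxy", dy_f, sfft.rfft2(self.W.value, s=(fh, fw)))
            dxp = sfft.irfft2(dx_f, s=(fh, fw))
            return np.ascontiguousarray(dxp[:, :, p : p + H, p : p + W])
        gflat = np.ascontiguousarray(grad.transpose(0, 2, 3, 1)).reshape(
            B * H * W, self.out_channels
        )
        cols = self._cols_cache
        self.W.grad += (gflat.T @ cols).reshape(self.W.value.shape)
        self.b.grad += gflat.sum(axis=0)
        wmat = self.W.value.reshape(self.out_channels, -1)
        dcols = (gflat @ wmat).reshape(B, H, W, self.in_channels, self.k, self.k)
        dxp = np.zeros(
            (B, self.in_channels, H + 2 * p, W + 2 * p), dtype=DTYPE
        )
        for ki in range(self.k):
            for kj in range(self.k):
                dxp[:, :, ki : ki + H, kj : kj + W] += dcols[:, :, :, :, ki, kj].transpose(
                    0, 3, 1, 2
                )
        return dxp[:, :, p : p + H, p : p + W]

    def params(self) -> list[Param]:
        return [self.W, self.b]


class MaxPool2d(Layer):
    """Non-overlapping max pooling with floor division of the spatial dims."""

    def __init__(self, k: int):
        self.k = k

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, H, W = x.shape
        k = self.k
        H2, W2 = H // k, W // k
        self._x = x
        out = x[:, :, 0 : H2 * k : k, 0 : W2 * k : k].copy()
        for ki in range(k):
            for kj in range(k):
                if ki == 0 and kj == 0:
                    continue
                np.maximum(out, x[:, :, ki : H2 * k : k, kj : W2 * k : k], out=out)
        self._out = out
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        # subgradient: route to the first window position attaining the max
        x, out = self._x, self._out
        B, C, H, W = x.shape
        k = self.k
        H2, W2 = H // k, W // k
        grad = np.asarray(grad, dtype=DTYPE)
        dx = np.zeros((B, C, H, W), dtype=DTYPE)
        used = np.zeros(out.shape, dtype=bool)
        for ki in range(k):
            for kj in range(k):
                sl = x[:, :, ki : H2 * k : k, kj : W2 * k : k]
                m = (sl == out) & ~used
                np.copyto(dx[:, :, ki : H2 * k : k, kj : W2 * k : k], grad, where=m)
                used |= m
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


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        self.W = Param(_fan_in_uniform(rng, (out_features, in_features), in_features))
        self.b = Param(_fan_in_uniform(rng, (out_features,), in_features))

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = np.asarray(x, dtype=DTYPE)
        return self._x @ self.W.value.T + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = np.asarray(grad, dtype=DTYPE)
        self.W.grad += grad.T @ self._x
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value

    def params(self) -> list[Param]:
        return [self.W, self.b]


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]
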