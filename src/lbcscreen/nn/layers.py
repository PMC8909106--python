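from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core import Layer, Parameter


class Conv2d(Layer):
    """3x3-style strided convolution on NCHW tensors, im2col based."""

    def __init__(self, cin: int, cout: int, kernel: int = 3, stride: int = 1,
                 pad: int = 1, rng: np.random.Generator | None = None,
                 name: str = "conv") -> None:
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / (cin * kernel * kernel))  # He init for ReLU nets
        self.W = Parameter(rng.normal(0, std, (cout, cin, kernel, kernel)),
                           f"{name}.W", tag="conv")
        self.b = Parameter(np.zeros(cout), f"{name}.b", tag="conv")
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self._cache = None

    def parameters(self) -> list[Parameter]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        k, s, p = self.kernel, self.stride, self.pad
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        # (N, C, Ho, Wo, k, k) -> (N, Ho, Wo, C*k*k)
        ho, wo = win.shape[2], win.shape[3]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)
                                    ).reshape(n, ho, wo, c * k * k)
        wmat = self.W.value.reshape(self.W.value.shape[0], -1)
        out = cols @ wmat.T + self.b.value
        self._cache = (cols, x.shape, xp.shape)
        return np.ascontiguousarray(out.transpose(0, 3, 1, 2))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, xshape, xpshape = self._cache
        k, s, p = self.kernel, self.stride, self.pad
        n, c, h, w = xshape
        do = dout.transpose(0, 2, 3, 1)  # N,Ho,Wo,Cout
        ho, wo = do.shape[1], do.shape[2]
        wmat = self.W.value.reshape(self.W.value.shape[0], -1)
        self.W.grad += np.tensordot(do, cols, axes=([0, 1, 2], [0, 1, 2])
                                    ).reshape(self.W.value.shape)
        self.b.grad += do.sum(axis=(0, 1, 2))
        dcols = (do @ wmat).reshape(n, ho, wo, c, k, k)
        dcols = dcols.transpose(0, 3, 1, 2, 4, 5)  # N,C,Ho,Wo,k,k
        dxp = np.zeros(xpshape, dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += dcols[..., i, j]
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class BatchNorm2d(Layer):
    """Per-channel batch normalisation with trainable affine scale/shift.

    The scale/shift parameters carry tag ``norm_affine`` — the only backbone
    parameters updated under partial fine-tuning.  Running statistics are
    plain buffers, updated in training mode and used in eval mode.
    """

    def __init__(self, channels: int, eps: float = 1e-5,
                 momentum: float = 0.1, name: str = "bn") -> None:
        self.gamma = Parameter(np.ones(channels), f"{name}.gamma",
                               tag="norm_affine")
        self.beta = Parameter(np.zeros(channels), f"{name}.beta",
                              tag="norm_affine")
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.eps, self.momentum = eps, momentum
        self._cache = None

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        axes = (0, 2, 3)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean
                                 + m * mean).astype(np.float32)
            self.running_var = ((1 - m) * self.running_var
                                + m * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None, None]) * invstd[:, None, None]
        self._cache = (xhat, invstd, train)
        return (self.gamma.value[:, None, None] * xhat
                + self.beta.value[:, None, None])

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, invstd, train = self._cache
        axes = (0, 2, 3)
        self.gamma.grad += (dout * xhat).sum(axis=axes)
        self.beta.grad += dout.sum(axis=axes)
        dxhat = dout * self.gamma.value[:, None, None]
        if not train:
            return dxhat * invstd[:, None, None]
        n = dout.shape[0] * dout.shape[2] * dout.shape[3]
        term = (n * dxhat
                - dxhat.sum(axis=axes, keepdims=True)
                - xhat * (dxhat * xhat).sum(axis=axes, keepdims=True))
        return (invstd[:, None, None] / n) * term


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0.0)


class MaxPool2d(Layer):
    """Max pooling (no padding); output size floor((g-k)/s)+1."""

    def __init__(self, kernel: int, stride: int) -> None:
        self.kernel, self.stride = kernel, stride
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        k, s = self.kernel, self.stride
        win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        n, c, ho, wo = win.shape[:4]
        flat = win.reshape(n, c, ho, wo, k * k)
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        self._cache = (x.shape, idx)
        return np.ascontiguousarray(out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xshape, idx = self._cache
        k, s = self.kernel, self.stride
        n, c, ho, wo = idx.shape
        dx = np.zeros(xshape, dtype=np.float32)
        ni, ci, oi, oj = np.ix_(np.arange(n), np.arange(c),
                                np.arange(ho), np.arange(wo))
        rows = oi * s + idx // k
        cols = oj * s + idx % k
        np.add.at(dx, (np.broadcast_to(ni, idx.shape),
                       np.broadcast_to(ci, idx.shape), rows, cols), dout)
        return dx


class Linear(Layer):
    def __init__(self, fin: int, fout: int,
                 rng: np.random.Generator | None = None,
                 name: str = "linear", tag: str = "head") -> None:
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / (fin + fout))
        self.W = Parameter(rng.normal(0, std, (fout, fin)), f"{name}.W", tag)
        self.b = Parameter(np.zeros(fout), f"{name}.b", tag)
        self._x = None

    def parameters(self) -> list[Parameter]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.W.grad += dout.T @ self._x
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value
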