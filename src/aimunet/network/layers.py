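"""Minimal NumPy layer library with hand-written forward/backward passes.

Only what the segmentation network needs: stride-1 same-padding convolution
(im2col), 2x2/stride-2 transposed convolution, batch normalization, max
pooling (stride 2 for downsampling, stride 1 same-padding inside the
inception modules), channel concatenation, ReLU/sigmoid.  Tensors are NHWC
float32.  Each layer caches what its backward pass needs; a layer instance
therefore supports one in-flight forward at a time, which is all the
sequential trainer requires.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


@dataclass
class Param:
    name: str
    value: np.ndarray
    grad: np.ndarray

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    trainable: bool = False

    def params(self) -> List[Param]:
        return []

    def forward(self, *inputs: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> Sequence[np.ndarray]:
        raise NotImplementedError


def _glorot(rng: np.random.Generator, shape, fan_in, fan_out) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """Same-padded sliding windows of ``x`` (N,H,W,C) -> (N*H*W, kh*kw*C)."""
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (ph, kh - 1 - ph), (pw, kw - 1 - pw), (0, 0)))
    win = sliding_window_view(xp, (kh, kw), axis=(1, 2))  # N,H,W,C,kh,kw
    win = win.transpose(0, 1, 2, 4, 5, 3)  # N,H,W,kh,kw,C
    n, h, w = x.shape[:3]
    return np.ascontiguousarray(win).reshape(n * h * w, kh * kw * x.shape[3])


class Conv2D(Layer):
    """Stride-1 same-padding convolution with optional fused activation."""

    trainable = True

    def __init__(self, name: str, kh: int, kw: int, cin: int, cout: int,
                 activation: Optional[str], rng: np.random.Generator):
        self.name, self.kh, self.kw, self.cin, self.cout = name, kh, kw, cin, cout
        self.activation = activation
        fan_in, fan_out = kh * kw * cin, kh * kw * cout
        self.W = _glorot(rng, (kh, kw, cin, cout), fan_in, fan_out)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self) -> List[Param]:
        return [Param(f"{self.name}.W", self.W, self.dW), Param(f"{self.name}.b", self.b, self.db)]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, h, w, _ = x.shape
        cols = _im2col(x, self.kh, self.kw)
        y = cols @ self.W.reshape(-1, self.cout) + self.b
        y = y.reshape(n, h, w, self.cout)
        self._cols, self._in_shape = cols, x.shape
        if self.activation == "relu":
            y = np.maximum(y, 0.0)
            self._act_out = y
        elif self.activation == "sigmoid":
            y = 1.0 / (1.0 + np.exp(-y))
            self._act_out = y
        return y

    def backward(self, dy: np.ndarray) -> Sequence[np.ndarray]:
        if self.activation == "relu":
            dy = dy * (self._act_out > 0)
        elif self.activation == "sigmoid":
            s = self._act_out
            dy = dy * s * (1.0 - s)
        n, h, w, _ = dy.shape
        dy_mat = dy.reshape(-1, self.cout)
        self.dW += (self._cols.T @ dy_mat).reshape(self.W.shape)
        self.db += dy_mat.sum(axis=0)
        # dx = same-padding correlation of dy with the spatially flipped,
        # channel-transposed kernel
        Wt = self.W[::-1, ::-1].transpose(0, 1, 3, 2)  # kh,kw,cout,cin
        cols = _im2col(dy, self.kh, self.kw)
        dx = (cols @ Wt.reshape(-1, self.cin)).reshape(self._in_shape)
        return (dx,)


class ConvTranspose2x2(Layer):
    """2x2 kernel, stride-2 transposed convolution (exact spatial doubling)."""

    trainable = True

    def __init__(self, name: str, cin: int, cout: int, activation: Optional[str],
                 rng: np.random.Generator):
        self.name, self.cin, self.cout = name, cin, cout
        self.activation = activation
        self.W = _glorot(rng, (2, 2, cin, cout), 4 * cin, 4 * cout)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self) -> List[Param]:
        return [Param(f"{self.name}.W", self.W, self.dW), Param(f"{self.name}.b", self.b, self.db)]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, h, w, _ = x.shape
        self._x = x
        # windows do not overlap at stride 2, so no scatter-add is needed
        y = np.einsum("nhwc,ijco->nhiwjo", x, self.W, optimize=True)
        y = y.reshape(n, 2 * h, 2 * w, self.cout) + self.b
        if self.activation == "relu":
            y = np.maximum(y, 0.0)
            self._act_out = y
        return y

    def backward(self, dy: np.ndarray) -> Sequence[np.ndarray]:
        if self.activation == "relu":
            dy = dy * (self._act_out > 0)
        n, h2, w2, _ = dy.shape
        h, w = h2 // 2, w2 // 2
        dyb = dy.reshape(n, h, 2, w, 2, self.cout).transpose(0, 1, 3, 2, 4, 5)
        self.db += dy.reshape(-1, self.cout).sum(axis=0)
        self.dW += np.einsum("nhwc,nhwijo->ijco", self._x, dyb, optimize=True)
        dx = np.einsum("nhwijo,ijco->nhwc", dyb, self.W, optimize=True)
        return (dx,)


class BatchNorm(Layer):
    """Per-channel batch normalization.

    Momentum 0.9 (rather than the Keras 0.99 default) so running statistics
    track batch statistics within the short CPU-scale trainings this package
    runs; they are seeded from the first batch seen.
    """

    trainable = True

    def __init__(self, name: str, channels: int, eps: float = 1e-3, momentum: float = 0.9):
        self.name, self.eps, self.momentum = name, eps, momentum
        self._initialized = False
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def params(self) -> List[Param]:
        return [Param(f"{self.name}.gamma", self.gamma, self.dgamma),
                Param(f"{self.name}.beta", self.beta, self.dbeta)]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        axes = (0, 1, 2)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = 0.0 if not self._initialized else self.momentum
            self._initialized = True
            self.running_mean[...] = m * self.running_mean + (1 - m) * mean
            self.running_var[...] = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._xhat, self._inv, self._m = xhat, inv, x.shape[0] * x.shape[1] * x.shape[2]
        self._training = training
        return self.gamma * xhat + self.beta

    def backward(self, dy: np.ndarray) -> Sequence[np.ndarray]:
        axes = (0, 1, 2)
        xhat, inv, m = self._xhat, self._inv, self._m
        self.dgamma += (dy * xhat).sum(axis=axes)
        self.dbeta += dy.sum(axis=axes)
        if not self._training:
            return (dy * self.gamma * inv,)
        dxhat = dy * self.gamma
        dx = (inv / m) * (m * dxhat - dxhat.sum(axis=axes)
                          - xhat * (dxhat * xhat).sum(axis=axes))
        return (dx.astype(np.float32),)


class MaxPool2(Layer):
    """2x2, stride-2 max pooling (input dims assumed even)."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        xb = x.reshape(n, h // 2, 2, w // 2, 2, c)
        y = xb.max(axis=(2, 4))
        self._mask = xb == y[:, :, None, :, None, :]
        # break ties toward the first maximum so gradient mass is conserved
        flat = self._mask.reshape(n, h // 2, w // 2, 4, c)
        first = np.cumsum(flat, axis=3) == 1
        self._mask = (flat & first).reshape(xb.shape)
        self._shape = x.shape
        return y

    def backward(self, dy: np.ndarray) -> Sequence[np.ndarray]:
        dx = self._mask * dy[:, :, None, :, None, :]
        return (dx.reshape(self._shape).astype(np.float32),)


class MaxPoolSame(Layer):
    """k x k, stride-1, same-padding max pooling (shape preserving)."""

    def __init__(self, kernel: int):
        self.k = kernel

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)), constant_values=-np.inf)
        win = sliding_window_view(xp, (k, k), axis=(1, 2))  # N,H,W,C,k,k
        n, h, w, c = x.shape
        flat = win.reshape(n, h, w, c, k * k)
        self._arg = flat.argmax(axis=4)
        self._in_shape, self._pad = x.shape, p
        return flat.max(axis=4)

    def backward(self, dy: np.ndarray) -> Sequence[np.ndarray]:
        n, h, w, c = self._in_shape
        k, p = self.k, self._pad
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=np.float32)
        ii, jj = np.divmod(self._arg, k)
        ni, hi, wi, ci = np.indices((n, h, w, c), sparse=False)
        np.add.at(dxp, (ni, hi + ii, wi + jj, ci), dy)
        return (dxp[:, p:p + h, p:p + w, :],)


class Concat(Layer):
    """Channel-axis concatenation of an arbitrary number of inputs."""

    def forward(self, *inputs: np.ndarray, training: bool = False) -> np.ndarray:
        self._splits = np.cumsum([x.shape[-1] for x in inputs])[:-1]
        return np.concatenate(inputs, axis=-1)

    def backward(self, dy: np.ndarray) -> Sequence[np.ndarray]:
        return tuple(np.split(dy, self._splits, axis=-1))


class Upsample2(Layer):
    """Parameter-free nearest-neighbour 2x upsampling."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dy: np.ndarray) -> Sequence[np.ndarray]:
        n, h2, w2, c = dy.shape
        return (dy.reshape(n, h2 // 2, 2, w2 // 2, 2, c).sum(axis=(2, 4)),)


class Identity(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return x

    def backward(self, dy: np.ndarray) -> Sequence[np.ndarray]:
        return (dy,)
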