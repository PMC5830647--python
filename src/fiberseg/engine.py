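"""Minimal NumPy layers with hand-written backpropagation.

This is the computational substrate of the segmentation network: 2-D
convolution (arbitrary kernel, stride 1 or 2, zero padding), batch
normalization, ReLU, dropout, fixed bilinear x2 upsampling, softmax and the
Adam optimizer.  Convolutions are evaluated sample by sample through an
im2col buffer and three BLAS matrix products (forward, weight gradient,
input gradient), which keeps peak memory at one column buffer while giving
the GEMMs a large inner dimension.

Tensors are ``(N, C, H, W)`` arrays; float32 by default (float64 is used by
the finite-difference gradient tests).  Each layer caches what its backward
pass needs during ``forward``; ``backward`` consumes the gradient with
respect to its output and returns the gradient with respect to its input,
accumulating parameter gradients in ``Param.grad``.
"""

from __future__ import annotations

import numpy as np

from ._kernels import conv_backward_input, conv_backward_weight, conv_forward

__all__ = [
    "Param",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "Dropout",
    "Upsample2x",
    "softmax",
    "Adam",
]


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.asarray(data)
        self.grad = np.zeros_like(self.data)

    @property
    def size(self) -> int:
        return self.data.size


class Conv2d:
    """2-D convolution with 'same'-style zero padding.

    Padding is ``(k-1)//2`` before and ``k//2`` after along each axis, so
    stride 1 preserves the spatial shape for any kernel size (including the
    even 2x2 kernel used after upsampling) and stride 2 maps ``H`` to
    ``ceil(H/2)``.  Weights are He-initialized; bias is optional and off for
    every convolution except the classifier.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 bias: bool = False, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / (in_ch * kernel * kernel))
        self.weight = Param(rng.normal(0.0, scale,
                                       size=(out_ch, in_ch, kernel, kernel)).astype(dtype))
        self.bias = Param(np.zeros(out_ch, dtype=dtype)) if bias else None
        self.kernel = kernel
        self.stride = stride
        self.pad = ((kernel - 1) // 2, kernel // 2)
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, s = self.kernel, self.stride
        pb, pa = self.pad
        n, cin, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (pb, pa), (pb, pa))) if (pb or pa) else x
        ho = (h + pb + pa - k) // s + 1
        wo = (w + pb + pa - k) // s + 1
        out = np.zeros((n, self.weight.data.shape[0], ho, wo), dtype=x.dtype)
        conv_forward(xp, self.weight.data, out, s)
        if self.bias is not None:
            out += self.bias.data[None, :, None, None]
        self._cache = (xp, x.shape)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xp, x_shape = self._cache
        pb = self.pad[0]
        _, _, h, w = x_shape
        dout = np.ascontiguousarray(dout)
        conv_backward_weight(xp, self.weight.grad, dout, self.stride)
        dxp = np.zeros_like(xp)
        conv_backward_input(dxp, self.weight.data, dout, self.stride)
        if self.bias is not None:
            self.bias.grad += dout.sum(axis=(0, 2, 3))
        return dxp[:, :, pb:pb + h, pb:pb + w] if (self.pad[0] or self.pad[1]) else dxp


class BatchNorm2d:
    """Per-channel batch normalization with learned scale/shift.

    Running statistics follow ``running = m * running + (1 - m) * batch``
    where the momentum ``m`` is scheduled externally during training.
    """

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5,
                 dtype=np.float32):
        self.gamma = Param(np.ones(channels, dtype=dtype))
        self.beta = Param(np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum = momentum
        self.eps = eps
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = (m * self.running_mean + (1 - m) * mu).astype(x.dtype)
            self.running_var = (m * self.running_var + (1 - m) * var).astype(x.dtype)
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
        xhat = (x - mu.astype(x.dtype)[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std)
        return self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        n, _, h, w = dout.shape
        m = n * h * w
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma.data[None, :, None, None]
        s1 = dxhat.sum(axis=(0, 2, 3))[None, :, None, None]
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        return (inv_std[None, :, None, None] / m) * (m * dxhat - s1 - xhat * s2)


class ReLU:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Dropout:
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self._mask: np.ndarray | None = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool,
                rng: np.random.Generator | None = None) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        rng = rng or np.random.default_rng()
        keep = rng.random(x.shape, dtype=np.float32) >= self.rate
        self._mask = keep.astype(x.dtype) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask


def _up_axis(x: np.ndarray, axis: int) -> np.ndarray:
    """Bilinear x2 along one axis: out[2i] = .25 x[i-1] + .75 x[i],
    out[2i+1] = .75 x[i] + .25 x[i+1], with edge clamping."""
    x = np.moveaxis(x, axis, -1)
    prev = np.concatenate([x[..., :1], x[..., :-1]], axis=-1)
    nxt = np.concatenate([x[..., 1:], x[..., -1:]], axis=-1)
    out = np.empty(x.shape[:-1] + (2 * x.shape[-1],), dtype=x.dtype)
    out[..., 0::2] = 0.25 * prev + 0.75 * x
    out[..., 1::2] = 0.75 * x + 0.25 * nxt
    return np.moveaxis(out, -1, axis)


def _up_axis_adjoint(dy: np.ndarray, axis: int) -> np.ndarray:
    dy = np.moveaxis(dy, axis, -1)
    even = dy[..., 0::2]
    odd = dy[..., 1::2]
    dx = 0.75 * even + 0.75 * odd
    dx[..., :-1] += 0.25 * even[..., 1:]
    dx[..., 0] += 0.25 * even[..., 0]
    dx[..., 1:] += 0.25 * odd[..., :-1]
    dx[..., -1] += 0.25 * odd[..., -1]
    return np.moveaxis(dx, -1, axis)


class Upsample2x:
    """Fixed (parameter-free) separable bilinear upsampling by a factor of 2."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        return _up_axis(_up_axis(x, -2), -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return _up_axis_adjoint(_up_axis_adjoint(dout, -1), -2)


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class Adam:
    """Adam optimizer over a list of :class:`Param`."""

    def __init__(self, params: list[Param], beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * p.grad
            v[...] = b2 * v + (1 - b2) * p.grad ** 2
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= (lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.data.dtype)
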