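"""Minimal 3D neural-network layers with explicit forward/backward passes.

Tensors are float32 and laid out channel-first, ``(C, D, H, W)``, with an
implicit batch of one (component maps vary in size, so samples are processed
one at a time).  Each layer caches what its backward pass needs; calling
``backward`` before ``forward`` is a bug.

Convolutions are evaluated as matrix products on im2col patch matrices, which
keeps all heavy lifting inside BLAS.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base class: parameters and gradients are dicts of float32 arrays."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k in self.grads:
            self.grads[k][...] = 0.0


class Conv3d(Layer):
    """Stride-1 3D convolution with 'same' padding for odd kernels.

    Evaluated as one small GEMM per kernel offset on contiguous slices of the
    flattened zero-padded volume.  For an interior output voxel the flat
    offset ``Δd*Hp*Wp + Δh*Wp + Δw`` addresses exactly its 3D neighbour, so
    the only wrap-around artefacts land in the padding border, which is
    discarded (forward/``dx``) or multiplied by the zeroed border (``dW``).
    This avoids materialising im2col patch matrices entirely.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int, rng):
        super().__init__()
        self.cin, self.cout, self.k = in_channels, out_channels, kernel_size
        self.pad = (kernel_size - 1) // 2
        fan_in = in_channels * kernel_size ** 3
        std = np.sqrt(2.0 / fan_in)  # He initialisation for ReLU networks
        self.params["weight"] = rng.normal(0.0, std, (out_channels, in_channels) + (kernel_size,) * 3).astype(np.float32)
        self.params["bias"] = np.zeros(out_channels, dtype=np.float32)
        self.grads["weight"] = np.zeros_like(self.params["weight"])
        self.grads["bias"] = np.zeros_like(self.params["bias"])

    def _offsets(self, hp: int, wp: int):
        k, pad = self.k, self.pad
        for a in range(k):
            for b in range(k):
                for c in range(k):
                    yield a, b, c, ((a - pad) * hp + (b - pad)) * wp + (c - pad)

    def forward(self, x, training=False):
        weight, bias = self.params["weight"], self.params["bias"]
        self._spatial = x.shape[1:]
        if self.k == 1:
            xf = x.reshape(self.cin, -1)
            self._xp = xf
            y = weight.reshape(self.cout, self.cin) @ xf + bias[:, None]
            return y.reshape((self.cout,) + x.shape[1:])
        pad = self.pad
        xp = np.pad(x, ((0, 0),) + ((pad, pad),) * 3)
        self._xp = xp
        dp, hp, wp = xp.shape[1:]
        m = dp * hp * wp
        xpf = xp.reshape(self.cin, m)
        yb = np.zeros((self.cout, m), dtype=np.float32)
        for a, b, c, off in self._offsets(hp, wp):
            lo, hi = max(0, -off), m - max(0, off)
            yb[:, lo:hi] += weight[:, :, a, b, c] @ xpf[:, lo + off:hi + off]
        y = yb.reshape(self.cout, dp, hp, wp)[:, pad:dp - pad, pad:hp - pad, pad:wp - pad]
        return np.ascontiguousarray(y) + bias[:, None, None, None]

    def backward(self, dy):
        weight = self.params["weight"]
        if self.k == 1:
            dyf = dy.reshape(self.cout, -1)
            self.grads["weight"] += (dyf @ self._xp.T).reshape(weight.shape)
            self.grads["bias"] += dyf.sum(axis=1)
            dx = weight.reshape(self.cout, self.cin).T @ dyf
            return dx.reshape((self.cin,) + self._spatial)
        pad = self.pad
        xp = self._xp
        dp, hp, wp = xp.shape[1:]
        m = dp * hp * wp
        xpf = xp.reshape(self.cin, m)
        dyp = np.zeros_like(xp[:1]).repeat(self.cout, axis=0)
        dyp[:, pad:dp - pad, pad:hp - pad, pad:wp - pad] = dy
        dypf = dyp.reshape(self.cout, m)
        dxb = np.zeros((self.cin, m), dtype=np.float32)
        for a, b, c, off in self._offsets(hp, wp):
            lo, hi = max(0, -off), m - max(0, off)
            self.grads["weight"][:, :, a, b, c] += dypf[:, lo:hi] @ xpf[:, lo + off:hi + off].T
            dxb[:, lo + off:hi + off] += weight[:, :, a, b, c].T @ dypf[:, lo:hi]
        self.grads["bias"] += dy.sum(axis=(1, 2, 3))
        dx = dxb.reshape(self.cin, dp, hp, wp)[:, pad:dp - pad, pad:hp - pad, pad:wp - pad]
        return np.ascontiguousarray(dx)


class ConvTranspose3d(Layer):
    """Kernel-2, stride-2 transpose convolution (doubles every dimension)."""

    def __init__(self, in_channels: int, out_channels: int, rng):
        super().__init__()
        self.cin, self.cout = in_channels, out_channels
        fan_in = in_channels * 8
        std = np.sqrt(2.0 / fan_in)
        self.params["weight"] = rng.normal(0.0, std, (in_channels, out_channels, 2, 2, 2)).astype(np.float32)
        self.params["bias"] = np.zeros(out_channels, dtype=np.float32)
        self.grads["weight"] = np.zeros_like(self.params["weight"])
        self.grads["bias"] = np.zeros_like(self.params["bias"])

    def forward(self, x, training=False):
        self._x = x
        d, h, w = x.shape[1:]
        t = np.tensordot(x, self.params["weight"], axes=([0], [0]))
        # t: (D, H, W, cout, 2, 2, 2) -> interleave the 2-blocks
        y = t.transpose(3, 0, 4, 1, 5, 2, 6).reshape(self.cout, 2 * d, 2 * h, 2 * w)
        return y + self.params["bias"][:, None, None, None]

    def backward(self, dy):
        d, h, w = self._x.shape[1:]
        dyr = dy.reshape(self.cout, d, 2, h, 2, w, 2).transpose(0, 2, 4, 6, 1, 3, 5)
        # dyr: (cout, 2, 2, 2, D, H, W)
        # (cin, cout, 2, 2, 2) directly from the contraction over D, H, W
        self.grads["weight"] += np.tensordot(self._x, dyr, axes=([1, 2, 3], [4, 5, 6]))
        self.grads["bias"] += dy.sum(axis=(1, 2, 3))
        dx = np.tensordot(self.params["weight"], dyr, axes=([1, 2, 3, 4], [0, 1, 2, 3]))
        return dx.astype(np.float32)


class BatchNorm3d(Layer):
    """Per-channel normalisation over the spatial axes.

    The batch here is always a single component map of variable size, so the
    normalisation statistics are computed from the sample itself at both
    training and inference time (instance-normalisation behaviour).  Running
    batch statistics estimated from single-sample batches are a poor
    surrogate for test-time activations of unseen map sizes and are not kept.
    """

    def __init__(self, channels: int, eps: float = 1e-5, affine: bool = True):
        super().__init__()
        self.channels, self.eps, self.affine = channels, eps, affine
        if affine:
            self.params["gamma"] = np.ones(channels, dtype=np.float32)
            self.params["beta"] = np.zeros(channels, dtype=np.float32)
            self.grads["gamma"] = np.zeros(channels, dtype=np.float32)
            self.grads["beta"] = np.zeros(channels, dtype=np.float32)

    def forward(self, x, training=False):
        mean = x.mean(axis=(1, 2, 3))
        var = x.var(axis=(1, 2, 3))
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None, None, None]) * inv[:, None, None, None]
        self._cache = (xhat.astype(np.float32), inv.astype(np.float32))
        if self.affine:
            return (self.params["gamma"][:, None, None, None] * self._cache[0]
                    + self.params["beta"][:, None, None, None]).astype(np.float32)
        return self._cache[0]

    def backward(self, dy):
        xhat, inv = self._cache
        if self.affine:
            self.grads["gamma"] += (dy * xhat).sum(axis=(1, 2, 3))
            self.grads["beta"] += dy.sum(axis=(1, 2, 3))
            dxhat = dy * self.params["gamma"][:, None, None, None]
        else:
            dxhat = dy
        m1 = dxhat.mean(axis=(1, 2, 3))
        m2 = (dxhat * xhat).mean(axis=(1, 2, 3))
        dx = inv[:, None, None, None] * (
            dxhat - m1[:, None, None, None] - xhat * m2[:, None, None, None]
        )
        return dx.astype(np.float32)


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0).astype(np.float32)


class Dropout(Layer):
    """Inverted dropout; identity outside training mode."""

    def __init__(self, rate: float, rng):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate, self.rng = rate, rng

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return (x * self._mask).astype(np.float32)

    def backward(self, dy):
        if self._mask is None:
            return dy
        return (dy * self._mask).astype(np.float32)


class MaxPool3d(Layer):
    """2x2x2 max pooling; dimensions must be even."""

    def forward(self, x, training=False):
        c, d, h, w = x.shape
        r = x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
        r = r.transpose(0, 1, 3, 5, 2, 4, 6).reshape(c, d // 2, h // 2, w // 2, 8)
        self._argmax = r.argmax(axis=-1)
        self._inshape = x.shape
        return np.take_along_axis(r, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        c, d, h, w = self._inshape
        out = np.zeros((c, d // 2, h // 2, w // 2, 8), dtype=np.float32)
        np.put_along_axis(out, self._argmax[..., None], dy[..., None], axis=-1)
        out = out.reshape(c, d // 2, h // 2, w // 2, 2, 2, 2)
        return out.transpose(0, 1, 4, 2, 5, 3, 6).reshape(c, d, h, w)


def softmax_channels(logits: np.ndarray) -> np.ndarray:
    """Softmax over the channel (class) axis of a (3, D, H, W) logit tensor."""
    z = logits - logits.max(axis=0, keepdims=True)
    e = np.exp(z)
    return (e / e.sum(axis=0, keepdims=True)).astype(np.float32)
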