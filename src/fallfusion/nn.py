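"""A small NumPy neural-network engine: the layers, losses and optimizer the
four-stream classifier is built from.

Design notes
------------
* Feature maps are NHWC (channels last): batch normalization then reduces
  over a contiguous reshape with no copy, and im2col gathers contiguous
  channel runs, which is what keeps the pure-NumPy forward/backward passes
  fast enough to train on a single CPU.
* Convolutions and pooling use valid (no) padding; output sides follow
  ``floor((in - kernel) / stride) + 1``.
* Convolution is im2col: patches are gathered with stride tricks, flattened,
  and multiplied through BLAS. The backward pass scatters gradients back with
  a short loop over kernel offsets (at most kh*kw vectorized adds), which
  handles overlapping receptive fields correctly.
* Max-pool ties break toward the first (row-major) element of the window,
  deterministically.
* Everything is dtype-agnostic: float32 in production, float64 in the
  finite-difference gradient checks of the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "glorot_uniform",
    "Conv2d",
    "BatchNorm",
    "ReLU",
    "MaxPool2d",
    "GlobalAvgPool",
    "Linear",
    "softmax",
    "softmax_cross_entropy",
    "Adam",
]


class Param:
    """A learnable tensor with its gradient accumulator.

    ``decay`` marks parameters subject to L2 regularization (weight matrices;
    biases and batchnorm scale/shift are exempt).
    """

    __slots__ = ("value", "grad", "decay", "name")

    def __init__(self, value: np.ndarray, decay: bool = False, name: str = ""):
        self.value = value
        self.grad = np.zeros_like(value)
        self.decay = decay
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int, dtype):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def _out_side(n: int, k: int, s: int) -> int:
    return (n - k) // s + 1


def _patches(x: np.ndarray, kh: int, kw: int, sh: int, sw: int):
    """View of all kh x kw patches of an NHWC tensor; no copy.

    Returns shape ``(N, OH, OW, kh, kw, C)`` — channels stay innermost.
    """
    n, h, w, c = x.shape
    oh, ow = _out_side(h, kh, sh), _out_side(w, kw, sw)
    sn, srow, scol, sc = x.strides
    shape = (n, oh, ow, kh, kw, c)
    strides = (sn, srow * sh, scol * sw, srow, scol, sc)
    return np.lib.stride_tricks.as_strided(x, shape, strides), oh, ow


class Conv2d:
    """Valid-padding 2-D convolution over all input channels (NHWC).

    The network's nominal "3-D" kernels have depth equal to the incoming
    channel count, so each collapses to exactly this full-channel 2-D
    convolution.
    """

    def __init__(self, in_ch, out_ch, kernel, stride, rng, dtype=np.float32, name="conv"):
        kh, kw = kernel
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride = (kh, kw), stride
        fan_in = kh * kw * in_ch
        self.W = Param(
            glorot_uniform(rng, (out_ch, fan_in), fan_in, out_ch, dtype),
            decay=True,
            name=f"{name}.W",
        )
        self.b = Param(np.zeros(out_ch, dtype=dtype), name=f"{name}.b")
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        kh, kw = self.kernel
        sh, sw = self.stride
        pats, oh, ow = _patches(x, kh, kw, sh, sw)
        cols = np.ascontiguousarray(pats).reshape(-1, kh * kw * self.in_ch)
        out = cols @ self.W.value.T + self.b.value
        if train:
            self._cache = (cols, x.shape, oh, ow)
        return out.reshape(x.shape[0], oh, ow, self.out_ch)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, x_shape, oh, ow = self._cache
        n, h, w, c = x_shape
        kh, kw = self.kernel
        sh, sw = self.stride
        dmat = dout.reshape(-1, self.out_ch)
        self.W.grad += dmat.T @ cols
        self.b.grad += dmat.sum(axis=0)
        dcols = (dmat @ self.W.value).reshape(n, oh, ow, kh, kw, c)
        dx = np.zeros(x_shape, dtype=dout.dtype)
        for i in range(kh):
            for j in range(kw):
                dx[:, i : i + oh * sh : sh, j : j + ow * sw : sw, :] += dcols[:, :, :, i, j, :]
        return dx


class BatchNorm:
    """Batch normalization per channel over all leading axes.

    Works for NHWC feature maps and for (N, C) fully connected activations.
    Running statistics use ``running = momentum * running + (1-momentum) * batch``.
    """

    def __init__(self, num_features, momentum=0.9, eps=1e-5, dtype=np.float32, name="bn"):
        self.momentum, self.eps = momentum, eps
        self.gamma = Param(np.ones(num_features, dtype=dtype), name=f"{name}.gamma")
        self.beta = Param(np.zeros(num_features, dtype=dtype), name=f"{name}.beta")
        self.running_mean = np.zeros(num_features, dtype=dtype)
        self.running_var = np.ones(num_features, dtype=dtype)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        c = x.shape[-1]
        flat = x.reshape(-1, c)  # NHWC: free reshape
        if train:
            mean = flat.mean(axis=0)
            xhat = flat - mean
            var = np.einsum("ij,ij->j", xhat, xhat) / flat.shape[0]
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(self.running_mean.dtype)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(self.running_var.dtype)
            inv_std = 1.0 / np.sqrt(var + self.eps)
            xhat *= inv_std
            self._cache = (xhat, inv_std)
        else:
            mean, var = self.running_mean, self.running_var
            inv_std = 1.0 / np.sqrt(var + self.eps)
            xhat = (flat - mean) * inv_std
        out = xhat * self.gamma.value + self.beta.value
        return out.reshape(x.shape)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        c = dout.shape[-1]
        dflat = dout.reshape(-1, c)
        self.gamma.grad += (dflat * xhat).sum(axis=0)
        self.beta.grad += dflat.sum(axis=0)
        g = self.gamma.value * inv_std
        dx = g * (dflat - dflat.mean(axis=0) - xhat * (dflat * xhat).mean(axis=0))
        return dx.reshape(dout.shape)


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x, train: bool = True):
        out = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout):
        return dout * self._mask


class MaxPool2d:
    """Valid-padding max pooling over NHWC maps; windows may overlap."""

    def __init__(self, window, stride):
        self.window, self.stride = window, stride
        self._cache = None

    def params(self):
        return []

    def forward(self, x, train: bool = True):
        kh, kw = self.window
        sh, sw = self.stride
        pats, oh, ow = _patches(x, kh, kw, sh, sw)
        flat = np.ascontiguousarray(pats).reshape(x.shape[0], oh, ow, kh * kw, x.shape[-1])
        idx = flat.argmax(axis=3)
        out = np.take_along_axis(flat, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]
        if train:
            self._cache = (idx, x.shape, oh, ow)
        return out

    def backward(self, dout):
        idx, x_shape, oh, ow = self._cache
        kh, kw = self.window
        sh, sw = self.stride
        dx = np.zeros(x_shape, dtype=dout.dtype)
        for p in range(kh * kw):
            i, j = divmod(p, kw)
            contrib = dout * (idx == p)
            dx[:, i : i + oh * sh : sh, j : j + ow * sw : sw, :] += contrib
        return dx


class GlobalAvgPool:
    """Spatial mean per channel: (N, H, W, C) -> (N, C)."""

    def __init__(self):
        self._shape = None

    def params(self):
        return []

    def forward(self, x, train: bool = True):
        if train:
            self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dout):
        n, h, w, c = self._shape
        return np.broadcast_to(dout[:, None, None, :], self._shape) / (h * w)


class Linear:
    def __init__(self, in_features, out_features, rng, dtype=np.float32, name="fc"):
        self.W = Param(
            glorot_uniform(rng, (out_features, in_features), in_features, out_features, dtype),
            decay=True,
            name=f"{name}.W",
        )
        self.b = Param(np.zeros(out_features, dtype=dtype), name=f"{name}.b")
        self._x = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train: bool = True):
        if train:
            self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, dout):
        self.W.grad += dout.T @ self._x
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy over the batch and its gradient w.r.t. logits."""
    n = logits.shape[0]
    probs = softmax(logits)
    loss = -np.log(np.clip(probs[np.arange(n), labels], 1e-12, None)).mean()
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, dlogits / n


class Adam:
    """Adam with optional L2 regularization added to the gradients of
    decay-flagged parameters (classic L2, not decoupled weight decay)."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8, l2=0.0):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps, self.l2 = lr, beta1, beta2, eps, l2
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]
        self._t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0

    def step(self):
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1**self._t
        bc2 = 1 - b2**self._t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            if self.l2 and p.decay:
                g = g + self.l2 * p.value
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
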