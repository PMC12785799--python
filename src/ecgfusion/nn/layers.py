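"""NumPy layers with explicit forward/backward passes (NHWC layout).

Convolutions run as im2col + GEMM in float32; every layer caches what its
backward pass needs.  Parameters and gradients are exposed as flat dicts so
a single optimizer can walk the whole model.
"""

from __future__ import annotations

import ctypes
import ctypes.util

import numpy as np

DTYPE = np.float32


def _tune_allocator() -> None:
    """Keep large freed blocks on the heap instead of unmapping them.

    The training loop allocates and frees many multi-megabyte arrays per
    step; with glibc's default mmap threshold each one is returned to the
    kernel on free and re-faulted on the next step, which costs more than
    the arithmetic.  Raising M_MMAP_THRESHOLD/M_TRIM_THRESHOLD lets the
    allocator recycle those blocks.  Best-effort: silently skipped where
    glibc's mallopt is unavailable.
    """
    try:
        libc = ctypes.CDLL(ctypes.util.find_library("c"), use_errno=True)
        libc.mallopt(-3, 1 << 30)  # M_MMAP_THRESHOLD
        libc.mallopt(-1, 1 << 30)  # M_TRIM_THRESHOLD
    except (OSError, AttributeError, TypeError):
        pass


_tune_allocator()


def same_pads(size: int, k: int, stride: int) -> tuple[int, int]:
    """'same' padding amounts (begin, end) for one axis."""
    out = -(-size // stride)
    total = max((out - 1) * stride + k - size, 0)
    return total // 2, total - total // 2


class _ConvBuffers:
    """Reusable scratch arrays for one (input-shape, conv) pair.

    First-touch page faults dominate im2col cost if the patch matrix is
    reallocated every call, so buffers persist across batches.  The patch
    matrix is reused to hold the patch gradient during backward (the weight
    gradient is computed from it first).
    """

    def __init__(self, x_shape, kh, kw, stride, pads):
        n, h, w, c = x_shape
        (pt, pb), (pl, pr) = pads
        hp, wp = h + pt + pb, w + pl + pr
        self.oh = (hp - kh) // stride + 1
        self.ow = (wp - kw) // stride + 1
        self.xp = np.zeros((n, hp, wp, c), dtype=DTYPE)  # padding stays zero
        self.cols = np.empty((n, self.oh, self.ow, kh, kw, c), dtype=DTYPE)
        self.y = np.empty((n * self.oh * self.ow, 0), dtype=DTYPE)  # resized lazily


class Layer:
    name = "layer"

    def params(self) -> dict[str, np.ndarray]:
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}

    def n_params(self) -> int:
        return sum(p.size for p in self.param_arrays())

    def param_arrays(self) -> list[np.ndarray]:
        """All stored arrays, including non-trainable statistics."""
        return list(self.params().values())


class Conv2D(Layer):
    def __init__(self, in_ch, out_ch, kernel, stride=1, bias=True, name="conv", rng=None):
        rng = rng or np.random.default_rng(0)
        self.kh = self.kw = kernel
        self.stride = stride
        self.name = name
        fan_in = kernel * kernel * in_ch
        limit = np.sqrt(6.0 / fan_in)  # He-uniform
        self.W = rng.uniform(-limit, limit, (kernel, kernel, in_ch, out_ch)).astype(DTYPE)
        self.b = np.zeros(out_ch, dtype=DTYPE) if bias else None
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b) if bias else None
        self._cache = None
        self._bufs: dict[tuple, _ConvBuffers] = {}

    def params(self):
        p = {f"{self.name}.W": self.W}
        if self.b is not None:
            p[f"{self.name}.b"] = self.b
        return p

    def grads(self):
        g = {f"{self.name}.W": self.dW}
        if self.b is not None:
            g[f"{self.name}.b"] = self.db
        return g

    def _buffers(self, x_shape):
        key = tuple(x_shape)
        buf = self._bufs.get(key)
        if buf is None:
            n, h, w, c = x_shape
            pads = (same_pads(h, self.kh, self.stride), same_pads(w, self.kw, self.stride))
            buf = _ConvBuffers(x_shape, self.kh, self.kw, self.stride, pads)
            buf.pads = pads
            if len(self._bufs) > 3:
                self._bufs.clear()
            self._bufs[key] = buf
        return buf

    def forward(self, x, training=False):
        n, h, w, c = x.shape
        buf = self._buffers(x.shape)
        (pt, _), (pl, _) = buf.pads
        s = self.stride
        buf.xp.fill(0.0)  # backward reuses this buffer; padding must be re-zeroed
        buf.xp[:, pt : pt + h, pl : pl + w, :] = x
        oh, ow = buf.oh, buf.ow
        for i in range(self.kh):
            for j in range(self.kw):
                buf.cols[:, :, :, i, j, :] = buf.xp[:, i : i + s * oh : s, j : j + s * ow : s, :]
        cols2d = buf.cols.reshape(n * oh * ow, -1)
        out_ch = self.W.shape[-1]
        if buf.y.shape != (cols2d.shape[0], out_ch):
            buf.y = np.empty((cols2d.shape[0], out_ch), dtype=DTYPE)
        np.matmul(cols2d, self.W.reshape(-1, out_ch), out=buf.y)
        if self.b is not None:
            buf.y += self.b
        self._cache = (x.shape, buf)
        return buf.y.reshape(n, oh, ow, out_ch).copy()

    def backward(self, dy):
        x_shape, buf = self._cache
        n, h, w, c = x_shape
        oh, ow = buf.oh, buf.ow
        (pt, _), (pl, _) = buf.pads
        dym = np.ascontiguousarray(dy.reshape(-1, dy.shape[-1]))
        wmat = self.W.reshape(-1, self.W.shape[-1])
        cols2d = buf.cols.reshape(n * oh * ow, -1)
        self.dW[...] = (cols2d.T @ dym).reshape(self.W.shape)
        if self.b is not None:
            self.db[...] = dym.sum(axis=0)
        # reuse the patch buffer for the patch gradient (dW already taken)
        np.matmul(dym, wmat.T, out=cols2d)
        dcols = buf.cols
        buf.xp.fill(0.0)
        s = self.stride
        for i in range(self.kh):
            for j in range(self.kw):
                buf.xp[:, i : i + s * oh : s, j : j + s * ow : s, :] += dcols[:, :, :, i, j, :]
        self._cache = None
        return buf.xp[:, pt : pt + h, pl : pl + w, :].copy()


class BatchNorm(Layer):
    """Channel-wise batch normalization (four stored terms per channel)."""

    def __init__(self, channels, momentum=0.9, eps=1e-5, name="bn"):
        self.name = name
        self.gamma = np.ones(channels, dtype=DTYPE)
        self.beta = np.zeros(channels, dtype=DTYPE)
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self._cache = None

    def params(self):
        return {f"{self.name}.gamma": self.gamma, f"{self.name}.beta": self.beta}

    def grads(self):
        return {f"{self.name}.gamma": self.dgamma, f"{self.name}.beta": self.dbeta}

    def param_arrays(self):
        return [self.gamma, self.beta, self.running_mean, self.running_var]

    def forward(self, x, training=False):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean[...] = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var[...] = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(DTYPE)
        xhat = x - mean.astype(DTYPE)
        xhat *= inv
        self._cache = (xhat, inv, x.shape, axes, training)
        out = xhat * self.gamma
        out += self.beta
        return out

    def backward(self, dy):
        xhat, inv, shape, axes, training = self._cache
        m = np.prod([shape[a] for a in axes])
        self.dgamma[...] = np.einsum("...c,...c->c", dy, xhat, optimize=True)
        self.dbeta[...] = dy.sum(axis=axes)
        if not training:
            return dy * (self.gamma * inv)
        # dx = inv/m * (m*dxhat - sum(dxhat) - xhat * sum(dxhat*xhat)),
        # with dxhat = dy * gamma; reuse xhat in place to limit temporaries
        s1 = self.dbeta * self.gamma
        s2 = self.dgamma * self.gamma
        dx = xhat
        dx *= -s2
        dx -= s1
        dx += (m * self.gamma) * dy
        dx *= inv / m
        self._cache = None
        return dx


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class GlobalAveragePool(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dy):
        n, h, w, c = self._shape
        return np.broadcast_to(dy[:, None, None, :] / (h * w), self._shape).astype(DTYPE)


class Dropout(Layer):
    def __init__(self, rate=0.5, rng=None):
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x, training=False):
        if not training or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return (x * self._mask).astype(DTYPE)

    def backward(self, dy):
        if self._mask is None:
            return dy
        return (dy * self._mask).astype(DTYPE)


class Dense(Layer):
    def __init__(self, in_dim, out_dim, name="dense", rng=None):
        rng = rng or np.random.default_rng(0)
        limit = np.sqrt(6.0 / (in_dim + out_dim))  # Glorot-uniform
        self.W = rng.uniform(-limit, limit, (in_dim, out_dim)).astype(DTYPE)
        self.b = np.zeros(out_dim, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.name = name

    def params(self):
        return {f"{self.name}.W": self.W, f"{self.name}.b": self.b}

    def grads(self):
        return {f"{self.name}.W": self.dW, f"{self.name}.b": self.db}

    def forward(self, x, training=False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW[...] = self._x.T @ dy
        self.db[...] = dy.sum(axis=0)
        return dy @ self.W.T


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60.0, 60.0)))


class SpatialAttention(Layer):
    """Mean/max channel pooling -> 7x7 conv -> sigmoid gate -> reweight.

    The gate conv sees 2 input channels and carries a bias, giving
    7*7*2 + 1 = 99 parameters.
    """

    def __init__(self, kernel=7, name="spatial_attention", rng=None):
        self.conv = Conv2D(2, 1, kernel, stride=1, bias=True, name=f"{name}.conv", rng=rng)
        self.name = name

    def params(self):
        return self.conv.params()

    def grads(self):
        return self.conv.grads()

    def param_arrays(self):
        return self.conv.param_arrays()

    def forward(self, x, training=False):
        mean_c = x.mean(axis=-1, keepdims=True)
        max_c = x.max(axis=-1, keepdims=True)
        pooled = np.concatenate([mean_c, max_c], axis=-1).astype(DTYPE)
        z = self.conv.forward(pooled, training)
        gate = _sigmoid(z).astype(DTYPE)
        self._cache = (x, gate, np.argmax(x, axis=-1))
        return (x * gate).astype(DTYPE)

    def backward(self, dy):
        x, gate, argmax = self._cache
        dx = dy * gate
        dgate = (dy * x).sum(axis=-1, keepdims=True)
        dz = (dgate * gate * (1.0 - gate)).astype(DTYPE)
        dpooled = self.conv.backward(dz)
        c = x.shape[-1]
        dx = dx + dpooled[..., 0:1] / c
        dmax = np.zeros_like(x)
        np.put_along_axis(dmax, argmax[..., None], dpooled[..., 1:2], axis=-1)
        self._cache = None
        return (dx + dmax).astype(DTYPE)


class PreActResBlock(Layer):
    """Pre-activation residual block: (BN-ReLU-conv3x3) x2 + shortcut.

    Convolutions carry no bias; a 1x1 projection (no bias) aligns the
    shortcut when shape or stride changes.  By the pre-activation
    convention, no activation follows the addition (``post_add_relu``
    restores the literal post-addition ReLU form).
    """

    def __init__(self, in_ch, out_ch, stride=1, post_add_relu=False, name="block", rng=None):
        self.bn1 = BatchNorm(in_ch, name=f"{name}.bn1")
        self.relu1 = ReLU()
        self.conv1 = Conv2D(in_ch, out_ch, 3, stride=stride, bias=False, name=f"{name}.conv1", rng=rng)
        self.bn2 = BatchNorm(out_ch, name=f"{name}.bn2")
        self.relu2 = ReLU()
        self.conv2 = Conv2D(out_ch, out_ch, 3, stride=1, bias=False, name=f"{name}.conv2", rng=rng)
        self.shortcut = None
        if stride != 1 or in_ch != out_ch:
            self.shortcut = Conv2D(in_ch, out_ch, 1, stride=stride, bias=False,
                                   name=f"{name}.shortcut", rng=rng)
        self.post_add_relu = post_add_relu
        self.in_ch, self.out_ch, self.stride = in_ch, out_ch, stride
        self.name = name

    def _sublayers(self):
        subs = [self.bn1, self.conv1, self.bn2, self.conv2]
        if self.shortcut is not None:
            subs.append(self.shortcut)
        return subs

    def params(self):
        out = {}
        for sub in self._sublayers():
            out.update(sub.params())
        return out

    def grads(self):
        out = {}
        for sub in self._sublayers():
            out.update(sub.grads())
        return out

    def param_arrays(self):
        return [a for sub in self._sublayers() for a in sub.param_arrays()]

    def forward(self, x, training=False):
        if x.shape[-1] != self.in_ch:
            raise ValueError(f"{self.name}: expected {self.in_ch} channels, got {x.shape[-1]}")
        h = self.bn1.forward(x, training)
        h = self.relu1.forward(h, training)
        h = self.conv1.forward(h, training)
        h = self.bn2.forward(h, training)
        h = self.relu2.forward(h, training)
        h = self.conv2.forward(h, training)
        sc = x if self.shortcut is None else self.shortcut.forward(x, training)
        y = h + sc
        if self.post_add_relu:
            self._post_mask = y > 0
            y = y * self._post_mask
        return y.astype(DTYPE)

    def backward(self, dy):
        if self.post_add_relu:
            dy = dy * self._post_mask
        dh = self.conv2.backward(dy)
        dh = self.relu2.backward(dh)
        dh = self.bn2.backward(dh)
        dh = self.conv1.backward(dh)
        dh = self.relu1.backward(dh)
        dx = self.bn1.backward(dh)
        dsc = dy if self.shortcut is None else self.shortcut.backward(dy)
        return (dx + dsc).astype(DTYPE)
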