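"""Layer primitives.

Tensors are NHWC float32.  Convolution weights use the (kh, kw, cin, cout)
layout; "same" padding follows the asymmetric convention of most graph
frameworks (pad_total = (ceil(n/s)-1)*s + k - n, extra pixel on the
bottom/right).  Every layer exposes ``params`` (name -> array, including
non-trainable batch-norm statistics so parameter totals match published
tables) and, where training is supported, caches forward activations and
fills ``grads`` in ``backward``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided


def _same_pads(n: int, k: int, s: int) -> tuple:
    out = -(-n // s)  # ceil
    total = max((out - 1) * s + k - n, 0)
    return total // 2, total - total // 2


def _pad_nhwc(x, ph, pw):
    if ph == (0, 0) and pw == (0, 0):
        return x
    return np.pad(x, ((0, 0), ph, pw, (0, 0)))


def _patches(x, kh, kw, sh, sw):
    """Strided view (N, OH, OW, kh, kw, C) of an already padded NHWC array."""
    n, h, w, c = x.shape
    oh = (h - kh) // sh + 1
    ow = (w - kw) // sw + 1
    sn, sh_, sw_, sc = x.strides
    return as_strided(
        x, (n, oh, ow, kh, kw, c),
        (sn, sh_ * sh, sw_ * sw, sh_, sw_, sc), writeable=False)


class Layer:
    """Base: stateless forward; trainable layers override params/backward."""

    trainable = True

    @property
    def params(self) -> dict:
        return {}

    @property
    def grads(self) -> dict:
        return getattr(self, "_grads", {})

    def forward(self, x, training=False):
        raise NotImplementedError

    def backward(self, grad):
        raise NotImplementedError(f"{type(self).__name__} has no backward")

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))


class Conv2D(Layer):
    def __init__(self, cin, cout, kernel, stride=1, padding="same",
                 use_bias=False, rng=None, name=""):
        kh, kw = (kernel, kernel) if np.isscalar(kernel) else kernel
        self.kh, self.kw, self.cin, self.cout = kh, kw, cin, cout
        self.stride = stride
        self.padding = padding
        self.use_bias = use_bias
        self.name = name
        rng = rng or np.random.default_rng(0)
        fan_in = kh * kw * cin
        self.w = rng.normal(0, np.sqrt(2.0 / fan_in),
                            (kh, kw, cin, cout)).astype(np.float32)
        self.b = np.zeros(cout, np.float32) if use_bias else None
        self._grads = {}

    @property
    def params(self):
        p = {"w": self.w}
        if self.use_bias:
            p["b"] = self.b
        return p

    def _pads(self, h, w):
        if self.padding == "same":
            return _same_pads(h, self.kh, self.stride), _same_pads(w, self.kw, self.stride)
        if self.padding == "valid":
            return (0, 0), (0, 0)
        raise ValueError(f"unknown padding {self.padding!r}")

    def forward(self, x, training=False):
        if x.shape[-1] != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {x.shape[-1]}")
        ph, pw = self._pads(x.shape[1], x.shape[2])
        xp = _pad_nhwc(x, ph, pw)
        pat = _patches(xp, self.kh, self.kw, self.stride, self.stride)
        n, oh, ow = pat.shape[:3]
        cols = pat.reshape(n * oh * ow, -1)
        out = cols @ self.w.reshape(-1, self.cout)
        if self.use_bias:
            out += self.b
        if training:
            self._cache = (cols, x.shape, ph, pw, (n, oh, ow))
        return out.reshape(n, oh, ow, self.cout)

    def backward(self, grad):
        cols, xshape, ph, pw, (n, oh, ow) = self._cache
        g = grad.reshape(n * oh * ow, self.cout)
        self._grads = {"w": (cols.T @ g).reshape(self.w.shape)}
        if self.use_bias:
            self._grads["b"] = g.sum(0)
        dcols = (g @ self.w.reshape(-1, self.cout).T).reshape(
            n, oh, ow, self.kh, self.kw, self.cin)
        hp = xshape[1] + sum(ph)
        wp = xshape[2] + sum(pw)
        dxp = np.zeros((n, hp, wp, self.cin), grad.dtype)
        s = self.stride
        for i in range(self.kh):
            for j in range(self.kw):
                dxp[:, i:i + oh * s:s, j:j + ow * s:s, :] += dcols[:, :, :, i, j, :]
        return dxp[:, ph[0]:hp - ph[1], pw[0]:wp - pw[1], :]


class DepthwiseConv2D(Layer):
    def __init__(self, cin, kernel=3, stride=1, padding="same",
                 use_bias=False, rng=None, name=""):
        kh, kw = (kernel, kernel) if np.isscalar(kernel) else kernel
        self.kh, self.kw, self.cin = kh, kw, cin
        self.stride = stride
        self.padding = padding
        self.use_bias = use_bias
        self.name = name
        rng = rng or np.random.default_rng(0)
        self.w = rng.normal(0, np.sqrt(2.0 / (kh * kw)),
                            (kh, kw, cin)).astype(np.float32)
        self.b = np.zeros(cin, np.float32) if use_bias else None
        self._grads = {}

    @property
    def params(self):
        p = {"w": self.w}
        if self.use_bias:
            p["b"] = self.b
        return p

    def forward(self, x, training=False):
        if self.padding == "same":
            ph = _same_pads(x.shape[1], self.kh, self.stride)
            pw = _same_pads(x.shape[2], self.kw, self.stride)
        else:
            ph = pw = (0, 0)
        xp = _pad_nhwc(x, ph, pw)
        pat = _patches(xp, self.kh, self.kw, self.stride, self.stride)
        out = np.einsum("nhwijc,ijc->nhwc", pat, self.w, optimize=True)
        if self.use_bias:
            out += self.b
        if training:
            self._cache = (pat, x.shape, ph, pw)
        return np.ascontiguousarray(out)

    def backward(self, grad):
        pat, xshape, ph, pw = self._cache
        self._grads = {"w": np.einsum("nhwijc,nhwc->ijc", pat, grad, optimize=True)}
        if self.use_bias:
            self._grads["b"] = grad.sum((0, 1, 2))
        n, oh, ow = grad.shape[:3]
        hp = xshape[1] + sum(ph)
        wp = xshape[2] + sum(pw)
        dxp = np.zeros((n, hp, wp, self.cin), grad.dtype)
        s = self.stride
        for i in range(self.kh):
            for j in range(self.kw):
                dxp[:, i:i + oh * s:s, j:j + ow * s:s, :] += grad * self.w[i, j]
        return dxp[:, ph[0]:hp - ph[1], pw[0]:wp - pw[1], :]


class BatchNorm(Layer):
    """Batch normalization over the channel axis.

    ``scale=False`` omits the gamma parameter (as some published
    architectures do); the moving mean/variance always count toward the
    parameter total, matching how frameworks report "No. of Weights".
    """

    def __init__(self, c, scale=True, eps=1e-3, momentum=0.9, name=""):
        self.c = c
        self.scale = scale
        self.eps = eps
        self.momentum = momentum
        self.name = name
        self.gamma = np.ones(c, np.float32) if scale else None
        self.beta = np.zeros(c, np.float32)
        self.moving_mean = np.zeros(c, np.float32)
        self.moving_var = np.ones(c, np.float32)
        self._grads = {}

    @property
    def params(self):
        p = {}
        if self.scale:
            p["gamma"] = self.gamma
        p.update(beta=self.beta, moving_mean=self.moving_mean,
                 moving_var=self.moving_var)
        return p

    def forward(self, x, training=False):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axes)
            var = x.var(axes)
            self.moving_mean[:] = (self.momentum * self.moving_mean
                                   + (1 - self.momentum) * mean)
            self.moving_var[:] = (self.momentum * self.moving_var
                                  + (1 - self.momentum) * var)
        else:
            mean, var = self.moving_mean, self.moving_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        if training:
            self._cache = (xhat, inv, x.shape, axes)
        out = xhat * self.gamma + self.beta if self.scale else xhat + self.beta
        return out

    def backward(self, grad):
        xhat, inv, shape, axes = self._cache
        m = np.prod([shape[a] for a in axes])
        self._grads = {"beta": grad.sum(axes)}
        g = self.gamma if self.scale else 1.0
        if self.scale:
            self._grads["gamma"] = (grad * xhat).sum(axes)
        dxhat = grad * g
        dx = (inv / m) * (m * dxhat - dxhat.sum(axes)
                          - xhat * (dxhat * xhat).sum(axes))
        return dx


class ReLU(Layer):
    trainable = False

    def forward(self, x, training=False):
        if training:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, grad):
        return grad * self._mask


class MaxPool2D(Layer):
    trainable = False

    def __init__(self, pool=2, stride=None, padding="valid"):
        self.pool = pool
        self.stride = stride or pool
        self.padding = padding

    def forward(self, x, training=False):
        k, s = self.pool, self.stride
        if self.padding == "same":
            ph = _same_pads(x.shape[1], k, s)
            pw = _same_pads(x.shape[2], k, s)
            xp = np.pad(x, ((0, 0), ph, pw, (0, 0)),
                        constant_values=-np.inf)
        else:
            ph = pw = (0, 0)
            xp = x
        pat = _patches(xp, k, k, s, s)
        n, oh, ow = pat.shape[:3]
        flat = pat.reshape(n, oh, ow, k * k, -1)
        out = flat.max(3)
        if training:
            self._cache = (flat.argmax(3), x.shape, ph, pw, (n, oh, ow))
        return np.ascontiguousarray(out)

    def backward(self, grad):
        amax, xshape, ph, pw, (n, oh, ow) = self._cache
        k, s = self.pool, self.stride
        c = xshape[3]
        hp, wp = xshape[1] + sum(ph), xshape[2] + sum(pw)
        dxp = np.zeros((n, hp, wp, c), grad.dtype)
        ii, jj = np.divmod(amax, k)
        ni, hi, wi, ci = np.indices((n, oh, ow, c))
        np.add.at(dxp, (ni, hi * s + ii, wi * s + jj, ci), grad)
        return dxp[:, ph[0]:hp - ph[1], pw[0]:wp - pw[1], :]


class AvgPool2D(Layer):
    """Average pooling; with "same" padding the mean is over valid (unpadded)
    elements only."""

    trainable = False

    def __init__(self, pool=3, stride=1, padding="same"):
        self.pool = pool
        self.stride = stride
        self.padding = padding

    def forward(self, x, training=False):
        k, s = self.pool, self.stride
        if self.padding == "same":
            ph = _same_pads(x.shape[1], k, s)
            pw = _same_pads(x.shape[2], k, s)
        else:
            ph = pw = (0, 0)
        xp = _pad_nhwc(x, ph, pw)
        pat = _patches(xp, k, k, s, s)
        num = pat.sum((3, 4))
        ones = np.ones(x.shape[1:3] + (1,), np.float32)[None]
        onesp = _pad_nhwc(ones, ph, pw)
        cnt = _patches(onesp, k, k, s, s).sum((3, 4))
        return np.ascontiguousarray(num / cnt)


class GlobalAvgPool(Layer):
    """Spatial global average pooling: (N,H,W,C) -> (N,C)."""

    trainable = False

    def forward(self, x, training=False):
        if training:
            self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, grad):
        n, h, w, c = self._shape
        return np.ascontiguousarray(
            np.broadcast_to(grad[:, None, None, :] / (h * w), (n, h, w, c)))


class Dense(Layer):
    def __init__(self, cin, cout, rng=None, name=""):
        rng = rng or np.random.default_rng(0)
        self.w = rng.normal(0, np.sqrt(2.0 / cin), (cin, cout)).astype(np.float32)
        self.b = np.zeros(cout, np.float32)
        self.name = name
        self._grads = {}

    @property
    def params(self):
        return {"w": self.w, "b": self.b}

    def forward(self, x, training=False):
        if training:
            self._x = x
        return x @ self.w + self.b

    def backward(self, grad):
        self._grads = {"w": self._x.T @ grad, "b": grad.sum(0)}
        return grad @ self.w.T


class Concat(Layer):
    """Channel-axis concatenation of parallel branch outputs (forward only)."""

    trainable = False

    def forward(self, xs, training=False):
        return np.concatenate(xs, axis=-1)
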