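"""Minimal NumPy neural-network layers with hand-written backpropagation.

Only what the ConvMixer needs: strided patch-embedding convolution, depthwise
and pointwise convolutions, batch normalization, exact (erf-based) GELU,
global average pooling, a linear head and softmax cross-entropy.  Every layer
caches what its backward pass needs during ``forward`` and accumulates
gradients into ``Param.grad``; correctness is verified against finite
differences in the test suite.

Array layout is NCHW throughout.  Layers keep persistent output/cache buffers
(keyed by shape and dtype) and overwrite them on every call: SGD training
revisits identical batch shapes thousands of times, and reusing warm memory
instead of faulting in fresh pages dominates throughput on a single core.
The returned arrays are therefore only valid until the layer's next call.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

__all__ = [
    "Param",
    "GELU",
    "BatchNorm2d",
    "PatchEmbed",
    "DepthwiseConv2d",
    "PointwiseConv2d",
    "GlobalAvgPool",
    "Linear",
    "softmax",
    "cross_entropy",
    "SGDMomentum",
    "glorot_uniform",
]

# Plain Python floats: NumPy-scalar constants would silently promote
# float32 activations to float64 and double the memory traffic.
_SQRT2 = float(np.sqrt(2.0))
_INV_SQRT_2PI = float(1.0 / np.sqrt(2.0 * np.pi))


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int, dtype):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class _Buffered:
    """Mixin providing shape-keyed persistent scratch buffers."""

    def _buf(self, name: str, shape, dtype) -> np.ndarray:
        store = self.__dict__.setdefault("_bufs", {})
        key = (name, tuple(shape), np.dtype(dtype))
        arr = store.get(key)
        if arr is None:
            arr = np.empty(shape, dtype=dtype)
            store[key] = arr
        return arr

    def parameters(self):
        return []


class GELU(_Buffered):
    """Exact Gaussian error linear unit: ``x * Phi(x)``."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        cdf = self._buf("cdf", x.shape, x.dtype)
        np.multiply(x, 1.0 / _SQRT2, out=cdf)
        erf(cdf, out=cdf)
        cdf += 1.0
        cdf *= 0.5
        out = self._buf("out", x.shape, x.dtype)
        np.multiply(x, cdf, out=out)
        if training:
            self._x = x
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._x
        cdf = self._bufs[("cdf", x.shape, x.dtype)]
        dx = self._buf("dx", x.shape, x.dtype)
        # dx = dout * (cdf + x * phi(x))
        np.multiply(x, x, out=dx)
        dx *= -0.5
        np.exp(dx, out=dx)
        dx *= _INV_SQRT_2PI
        dx *= x
        dx += cdf
        dx *= dout
        return dx


class BatchNorm2d(_Buffered):
    """Per-channel batch normalization over (N, H, W)."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1, dtype=np.float32):
        self.gamma = Param(np.ones(channels, dtype=dtype))
        self.beta = Param(np.zeros(channels, dtype=dtype))
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self._cache = None
        self._collect = None  # population-statistics accumulators when set

    def begin_collect(self) -> None:
        """Start accumulating population statistics (see ``end_collect``)."""
        self._collect = {"n": 0, "s1": 0.0, "s2": 0.0}

    def end_collect(self) -> None:
        """Replace running stats with population statistics.

        Mirrors the common trainer behavior of finalizing batch-norm moments
        over the whole training set after the last update, which matters when
        the number of minibatches is far too small for the exponential moving
        average to converge.
        """
        acc = self._collect
        if acc and acc["n"] > 0:
            mean = acc["s1"] / acc["n"]
            var = acc["s2"] / acc["n"] - mean**2
            self.running_mean = mean.astype(self.running_mean.dtype)
            self.running_var = np.maximum(var, 0.0).astype(self.running_var.dtype)
        self._collect = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            if self._collect is not None:
                m = x.shape[0] * x.shape[2] * x.shape[3]
                self._collect["n"] += m
                self._collect["s1"] += mu.astype(np.float64) * m
                self._collect["s2"] += (var + mu * mu).astype(np.float64) * m
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mu).astype(
                self.running_mean.dtype
            )
            self.running_var = ((1 - m) * self.running_var + m * var).astype(
                self.running_var.dtype
            )
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = self._buf("xhat", x.shape, x.dtype)
        np.subtract(x, mu[None, :, None, None].astype(x.dtype), out=xhat)
        xhat *= inv_std[None, :, None, None].astype(x.dtype)
        out = self._buf("out", x.shape, x.dtype)
        np.multiply(xhat, self.gamma.value[None, :, None, None], out=out)
        out += self.beta.value[None, :, None, None]
        if training:
            self._cache = (xhat, inv_std.astype(x.dtype))
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        n = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.gamma.grad += np.einsum("nchw,nchw->c", dout, xhat)
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        g4 = self.gamma.value[None, :, None, None]
        dxhat = self._buf("dxhat", dout.shape, dout.dtype)
        np.multiply(dout, g4, out=dxhat)
        s1 = dxhat.sum(axis=(0, 2, 3))[None, :, None, None]
        s2 = np.einsum("nchw,nchw->c", dxhat, xhat)[None, :, None, None]
        # dx = inv_std/n * (n*dxhat - s1 - xhat*s2), built in place
        dx = self._buf("dx", dout.shape, dout.dtype)
        np.multiply(xhat, s2.astype(dout.dtype), out=dx)
        dx += s1.astype(dout.dtype)
        dxhat *= float(n)
        dxhat -= dx
        dxhat *= (inv_std / n)[None, :, None, None]
        return dxhat


    def parameters(self):
        return [self.gamma, self.beta]

class PatchEmbed(_Buffered):
    """Valid convolution with kernel = stride = patch size.

    Splits the image into non-overlapping p x p patches (any remainder at the
    right/bottom edge is cropped, matching a valid strided convolution) and
    projects each patch to ``hidden_dim`` channels.
    """

    def __init__(self, in_ch: int, hidden_dim: int, patch: int, rng: np.random.Generator, dtype=np.float32):
        fan_in = in_ch * patch * patch
        self.W = Param(glorot_uniform(rng, (fan_in, hidden_dim), fan_in, hidden_dim, dtype))
        self.b = Param(np.zeros(hidden_dim, dtype=dtype))
        self.patch = patch
        self.in_ch = in_ch
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        p = self.patch
        n, c, h, w = x.shape
        hp, wp = h // p, w // p
        f = c * p * p
        cols = self._buf("cols", (n, hp, wp, f), x.dtype)
        cols[...] = (
            x[:, :, : hp * p, : wp * p]
            .reshape(n, c, hp, p, wp, p)
            .transpose(0, 2, 4, 1, 3, 5)
            .reshape(n, hp, wp, f)
        )
        proj = self._buf("proj", (n, hp, wp, self.W.value.shape[1]), x.dtype)
        np.matmul(cols, self.W.value, out=proj)
        proj += self.b.value
        out = self._buf("out", (n, proj.shape[3], hp, wp), x.dtype)
        out[...] = proj.transpose(0, 3, 1, 2)
        if training:
            self._cache = (cols, x.shape)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, xshape = self._cache
        p = self.patch
        n, c, h, w = xshape
        hp, wp = h // p, w // p
        f = c * p * p
        hid = dout.shape[1]
        d2 = self._buf("d2", (n, hp, wp, hid), dout.dtype)
        d2[...] = dout.transpose(0, 2, 3, 1)
        self.W.grad += cols.reshape(-1, f).T @ d2.reshape(-1, hid)
        self.b.grad += d2.sum(axis=(0, 1, 2))
        dcols = self._buf("dcols", (n, hp, wp, f), dout.dtype)
        np.matmul(d2, self.W.value.T, out=dcols)
        dx = self._buf("dx", xshape, dout.dtype)
        if (hp * p, wp * p) != (h, w):
            dx.fill(0.0)
        dx[:, :, : hp * p, : wp * p] = (
            dcols.reshape(n, hp, wp, c, p, p)
            .transpose(0, 3, 1, 4, 2, 5)
            .reshape(n, c, hp * p, wp * p)
        )
        return dx


    def parameters(self):
        return [self.W, self.b]

class DepthwiseConv2d(_Buffered):
    """Per-channel (grouped, groups = channels) convolution with same padding."""

    def __init__(self, channels: int, kernel: int, rng: np.random.Generator, dtype=np.float32):
        if kernel % 2 != 1:
            raise ValueError("depthwise kernel size must be odd for same padding")
        fan = kernel * kernel
        self.W = Param(glorot_uniform(rng, (channels, kernel, kernel), fan, fan, dtype))
        self.b = Param(np.zeros(channels, dtype=dtype))
        self.kernel = kernel
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        k = self.kernel
        pad = k // 2
        n, c, h, w = x.shape
        xp = self._buf("xp", (n, c, h + 2 * pad, w + 2 * pad), x.dtype)
        xp.fill(0.0)
        xp[:, :, pad : pad + h, pad : pad + w] = x
        out = self._buf("out", x.shape, x.dtype)
        out[...] = self.b.value[None, :, None, None]
        wv = self.W.value
        tmp = self._buf("tmp", x.shape, x.dtype)
        for i in range(k):
            for j in range(k):
                np.multiply(
                    xp[:, :, i : i + h, j : j + w], wv[:, i, j][None, :, None, None], out=tmp
                )
                out += tmp
        if training:
            self._cache = (xp, x.shape)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xp, xshape = self._cache
        k = self.kernel
        pad = k // 2
        n, c, h, w = xshape
        self.b.grad += dout.sum(axis=(0, 2, 3))
        dxp = self._buf("dxp", xp.shape, dout.dtype)
        dxp.fill(0.0)
        wv = self.W.value
        tmp = self._buf("btmp", dout.shape, dout.dtype)
        for i in range(k):
            for j in range(k):
                self.W.grad[:, i, j] += np.einsum(
                    "nchw,nchw->c", dout, xp[:, :, i : i + h, j : j + w]
                )
                np.multiply(dout, wv[:, i, j][None, :, None, None], out=tmp)
                dxp[:, :, i : i + h, j : j + w] += tmp
        dx = self._buf("dx", xshape, dout.dtype)
        dx[...] = dxp[:, :, pad : pad + h, pad : pad + w]
        return dx


    def parameters(self):
        return [self.W, self.b]

class PointwiseConv2d(_Buffered):
    """1x1 convolution: channel mixing at every spatial location."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator, dtype=np.float32):
        self.W = Param(glorot_uniform(rng, (in_ch, out_ch), in_ch, out_ch, dtype))
        self.b = Param(np.zeros(out_ch, dtype=dtype))
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        o = self.W.value.shape[1]
        xr = x.reshape(n, c, h * w)
        out = self._buf("out", (n, o, h * w), x.dtype)
        np.matmul(self.W.value.T[None], xr, out=out)
        out += self.b.value[None, :, None]
        if training:
            self._cache = (xr, x.shape)
        return out.reshape(n, o, h, w)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xr, xshape = self._cache
        n, c, h, w = xshape
        d2 = dout.reshape(n, -1, h * w)
        self.W.grad += np.tensordot(xr, d2, axes=([0, 2], [0, 2]))
        self.b.grad += d2.sum(axis=(0, 2))
        dx = self._buf("dx", (n, c, h * w), dout.dtype)
        np.matmul(self.W.value[None], d2, out=dx)
        return dx.reshape(xshape)


    def parameters(self):
        return [self.W, self.b]

class GlobalAvgPool(_Buffered):
    """Average over the spatial grid, producing one value per channel."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dx = self._buf("dx", self._shape, dout.dtype)
        dx[...] = dout[:, :, None, None]
        dx /= h * w
        return dx


class Linear(_Buffered):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, dtype=np.float32):
        self.W = Param(glorot_uniform(rng, (in_dim, out_dim), in_dim, out_dim, dtype))
        self.b = Param(np.zeros(out_dim, dtype=dtype))
        self._x = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value.T


    def parameters(self):
        return [self.W, self.b]

def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, y_idx: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits)
    eps = np.finfo(p.dtype).tiny
    loss = float(-np.mean(np.log(p[np.arange(n), y_idx] + eps)))
    dlogits = p.copy()
    dlogits[np.arange(n), y_idx] -= 1.0
    return loss, dlogits / n


class SGDMomentum:
    """Classic momentum SGD: ``v = momentum*v - lr*grad; w += v``."""

    def __init__(self, params: list[Param], lr: float, momentum: float = 0.9):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.velocity = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        for p, v in zip(self.params, self.velocity):
            v *= self.momentum
            v -= self.lr * p.grad
            p.value += v
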