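"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ndarray and records the operation that produced
it; :meth:`Tensor.backward` walks the tape in reverse topological order and
accumulates gradients.  Broadcasting follows numpy semantics (gradients are
summed back to the operand shape).  Only the operations needed by the
light-field reconstruction network are implemented.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    # -- graph plumbing -----------------------------------------------------

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, visited = [], set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in visited:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, g):
        g = _unbroadcast(np.asarray(g), self.data.shape)
        self.grad = g if self.grad is None else self.grad + g

    def zero_grad(self):
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)

    # -- arithmetic ---------------------------------------------------------

    @staticmethod
    def _coerce(x):
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))

    def __add__(self, other):
        other = Tensor._coerce(other)
        def bw(g):
            self._accum(g)
            other._accum(g)
        return Tensor._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accum(-g)
        return Tensor._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        other = Tensor._coerce(other)
        def bw(g):
            self._accum(g * other.data)
            other._accum(g * self.data)
        return Tensor._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._coerce(other)
        def bw(g):
            self._accum(g / other.data)
            other._accum(-g * self.data / other.data ** 2)
        return Tensor._make(self.data / other.data, (self, other), bw)

    def __rtruediv__(self, other):
        return Tensor._coerce(other) / self

    def __pow__(self, p: float):
        def bw(g):
            self._accum(g * p * np.power(self.data, p - 1))
        return Tensor._make(np.power(self.data, p), (self,), bw)

    def __matmul__(self, other):
        other = Tensor._coerce(other)
        def bw(g):
            self._accum(g @ other.data.swapaxes(-1, -2))
            other._accum(self.data.swapaxes(-1, -2) @ g)
        return Tensor._make(self.data @ other.data, (self, other), bw)

    # -- elementwise --------------------------------------------------------

    def relu(self):
        mask = self.data > 0
        def bw(g):
            self._accum(g * mask)
        return Tensor._make(self.data * mask, (self,), bw)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        def bw(g):
            self._accum(g * s * (1 - s))
        return Tensor._make(s, (self,), bw)

    def tanh(self):
        t = np.tanh(self.data)
        def bw(g):
            self._accum(g * (1 - t ** 2))
        return Tensor._make(t, (self,), bw)

    def log(self):
        def bw(g):
            self._accum(g / self.data)
        return Tensor._make(np.log(self.data), (self,), bw)

    def exp(self):
        e = np.exp(self.data)
        def bw(g):
            self._accum(g * e)
        return Tensor._make(e, (self,), bw)

    def sqrt(self):
        r = np.sqrt(self.data)
        def bw(g):
            self._accum(g * 0.5 / np.maximum(r, 1e-300))
        return Tensor._make(r, (self,), bw)

    def abs(self):
        s = np.sign(self.data)
        def bw(g):
            self._accum(g * s)
        return Tensor._make(np.abs(self.data), (self,), bw)

    def clamp_min(self, lo: float):
        """Lower clamp; gradient is zero where the clamp is active."""
        mask = self.data > lo
        def bw(g):
            self._accum(g * mask)
        return Tensor._make(np.maximum(self.data, lo), (self,), bw)

    # -- reductions / reshaping --------------------------------------------

    def sum(self, axis=None, keepdims=False):
        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape))
        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims),
                            (self,), bw)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        orig = self.data.shape
        def bw(g):
            self._accum(g.reshape(orig))
        return Tensor._make(self.data.reshape(*shape), (self,), bw)

    def transpose(self, axes):
        inv = np.argsort(axes)
        def bw(g):
            self._accum(g.transpose(inv))
        return Tensor._make(self.data.transpose(axes), (self,), bw)

    def __getitem__(self, idx):
        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)
        return Tensor._make(self.data[idx], (self,), bw)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]
    def bw(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            t._accum(p)
    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis),
                        tuple(tensors), bw)


# ---------------------------------------------------------------- conv ops


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    b, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (h + 2 * pad - kh) // stride + 1
    ow = (w + 2 * pad - kw) // stride + 1
    s0, s1, s2, s3 = xp.strides
    cols = np.lib.stride_tricks.as_strided(
        xp, (b, c, kh, kw, oh, ow),
        (s0, s1, s2, s3, s2 * stride, s3 * stride), writeable=False)
    return cols, oh, ow, xp.shape


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           pad: int = 1) -> Tensor:
    """2D convolution (cross-correlation), NCHW layout, square stride/pad."""
    kh, kw = w.data.shape[2:]
    cols, oh, ow, pshape = _im2col(x.data, kh, kw, stride, pad)
    out = np.einsum("ockl,bcklhw->bohw", w.data, cols, optimize=True)
    if b is not None:
        out = out + b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)

    def bw(g):
        if w.requires_grad:
            w._accum(np.einsum("bohw,bcklhw->ockl", g, cols, optimize=True))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcols = np.einsum("ockl,bohw->bcklhw", w.data, g, optimize=True)
            dxp = np.zeros(pshape)
            for a in range(kh):
                for bb in range(kw):
                    dxp[:, :, a:a + stride * oh:stride,
                        bb:bb + stride * ow:stride] += dcols[:, :, a, bb]
            h, ww_ = x.data.shape[2:]
            x._accum(dxp[:, :, pad:pad + h, pad:pad + ww_])

    return Tensor._make(out, parents, bw)


def depthwise_conv2d_fixed(x: Tensor, kernel: np.ndarray, pad: str = "valid") -> Tensor:
    """Correlate every channel of ``x`` with the same fixed 2D kernel
    (no gradient to the kernel).  Used for windowed image statistics."""
    kh, kw = kernel.shape
    p = 0 if pad == "valid" else kh // 2
    cols, oh, ow, pshape = _im2col(x.data, kh, kw, 1, p)
    out = np.einsum("kl,bcklhw->bchw", kernel, cols, optimize=True)

    def bw(g):
        if x.requires_grad:
            dcols = np.einsum("kl,bchw->bcklhw", kernel, g, optimize=True)
            dxp = np.zeros(pshape)
            for a in range(kh):
                for bb in range(kw):
                    dxp[:, :, a:a + oh, bb:bb + ow] += dcols[:, :, a, bb]
            h, w_ = x.data.shape[2:]
            x._accum(dxp[:, :, p:p + h, p:p + w_])

    return Tensor._make(out, (x,), bw)


def avg_pool2d(x: Tensor, k: int = 2) -> Tensor:
    b, c, h, w = x.data.shape
    oh, ow = h // k, w // k
    xc = x.data[:, :, :oh * k, :ow * k]
    out = xc.reshape(b, c, oh, k, ow, k).mean(axis=(3, 5))

    def bw(g):
        gx = np.zeros_like(x.data)
        gexp = np.repeat(np.repeat(g, k, axis=2), k, axis=3) / (k * k)
        gx[:, :, :oh * k, :ow * k] = gexp
        x._accum(gx)

    return Tensor._make(out, (x,), bw)


def pixel_shuffle(x: Tensor, r: int) -> Tensor:
    """Rearrange (B, C·r², H, W) → (B, C, H·r, W·r) (sub-pixel upsampling)."""
    b, cr2, h, w = x.data.shape
    if cr2 % (r * r):
        raise ValueError(f"channels {cr2} not divisible by r²={r * r}")
    c = cr2 // (r * r)
    out = (x.data.reshape(b, c, r, r, h, w)
           .transpose(0, 1, 4, 2, 5, 3)
           .reshape(b, c, h * r, w * r))

    def bw(g):
        gi = (g.reshape(b, c, h, r, w, r)
              .transpose(0, 1, 3, 5, 2, 4)
              .reshape(b, cr2, h, w))
        x._accum(gi)

    return Tensor._make(out, (x,), bw)


def _resize_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Bicubic (Catmull-Rom-style, a=-0.5) interpolation matrix with edge
    clamping; rows sum to 1."""
    a = -0.5
    def kern(t):
        t = np.abs(t)
        return np.where(
            t <= 1, (a + 2) * t ** 3 - (a + 3) * t ** 2 + 1,
            np.where(t < 2, a * t ** 3 - 5 * a * t ** 2 + 8 * a * t - 4 * a, 0.0))
    scale = n_in / n_out
    mat = np.zeros((n_out, n_in))
    for o in range(n_out):
        src = (o + 0.5) * scale - 0.5
        base = int(np.floor(src))
        for k in range(-1, 3):
            idx = min(max(base + k, 0), n_in - 1)
            mat[o, idx] += kern(src - (base + k))
    mat /= mat.sum(axis=1, keepdims=True)
    return mat


_RESIZE_CACHE: dict = {}


def resize_bicubic(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Separable bicubic resize as two fixed linear maps (exact adjoint)."""
    b, c, h, w = x.data.shape
    key_r, key_c = (h, out_h), (w, out_w)
    if key_r not in _RESIZE_CACHE:
        _RESIZE_CACHE[key_r] = _resize_matrix(h, out_h)
    if key_c not in _RESIZE_CACHE:
        _RESIZE_CACHE[key_c] = _resize_matrix(w, out_w)
    R, C = _RESIZE_CACHE[key_r], _RESIZE_CACHE[key_c]
    out = np.einsum("oh,bchw,pw->bcop", R, x.data, C, optimize=True)

    def bw(g):
        x._accum(np.einsum("oh,bcop,pw->bchw", R, g, C, optimize=True))

    return Tensor._make(out, (x,), bw)


def global_avg_pool(x: Tensor) -> Tensor:
    return x.mean(axis=(2, 3))
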