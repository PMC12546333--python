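"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package's networks are small enough that a dynamic tape over numpy is
adequate: each :class:`Tensor` wraps an ndarray, records its parents and a
closure that routes the incoming gradient to them, and ``backward`` walks the
tape in reverse topological order.  Convolution and max-pooling are primitives
with hand-written adjoints (kernel-loop im2col / col2im); everything else is
composed from elementwise and reduction primitives.
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np

_grad_enabled = True
_mac_log: list | None = None


@contextlib.contextmanager
def count_macs():
    """Log the multiply-accumulate count of every convolution executed inside
    the context.  Yields a list of (batch, macs_total) entries; used as the
    hook-based cross-check of the analytic profiler."""
    global _mac_log
    prev = _mac_log
    _mac_log = []
    try:
        yield _mac_log
    finally:
        _mac_log = prev


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the context (inference, target building)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def is_grad_enabled() -> bool:
    return _grad_enabled


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents: Sequence["Tensor"] = (), backward_fn=None):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and _grad_enabled
        self._parents: tuple[Tensor, ...] = tuple(parents) if self.requires_grad else ()
        self._backward = backward_fn if self.requires_grad else None

    # ---------------------------------------------------------------- basics
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def item(self):
        return self.data.item()

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient only valid for scalars")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- operators
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(astensor(other), -1.0))

    def __rsub__(self, other):
        return add(astensor(other), mul(self, -1.0))

    def __truediv__(self, other):
        other = astensor(other)
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return mul(astensor(other), power(self, -1.0))

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return take(self, idx)

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean_(self, axis=axis, keepdims=keepdims)

    def max(self, axis=None, keepdims=False):
        return max_(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        return transpose(self, axes)


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (the adjoint of numpy broadcasting)."""
    if g.shape == shape:
        return g
    nd = g.ndim - len(shape)
    if nd > 0:
        g = g.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def _make(data, parents, backward_fn):
    req = _grad_enabled and any(p.requires_grad for p in parents)
    return Tensor(data, requires_grad=req, parents=[p for p in parents if p.requires_grad], backward_fn=backward_fn if req else None)


# ------------------------------------------------------------------ binary ops
def add(a, b):
    a, b = astensor(a), astensor(b)
    out_data = a.data + b.data

    def bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), bw)


def mul(a, b):
    a, b = astensor(a), astensor(b)
    out_data = a.data * b.data

    def bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), bw)


def maximum(a, b):
    a, b = astensor(a), astensor(b)
    out_data = np.maximum(a.data, b.data)

    def bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * (a.data >= b.data), a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * (a.data < b.data), b.data.shape))

    return _make(out_data, (a, b), bw)


def minimum(a, b):
    a, b = astensor(a), astensor(b)
    out_data = np.minimum(a.data, b.data)

    def bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * (a.data <= b.data), a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * (a.data > b.data), b.data.shape))

    return _make(out_data, (a, b), bw)


def matmul(a, b):
    a, b = astensor(a), astensor(b)
    out_data = a.data @ b.data

    def bw(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accumulate(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accumulate(_unbroadcast(gb, b.data.shape))

    return _make(out_data, (a, b), bw)


# ----------------------------------------------------------------- unary ops
def power(a, p: float):
    a = astensor(a)
    out_data = a.data ** p

    def bw(g):
        a._accumulate(g * p * a.data ** (p - 1.0))

    return _make(out_data, (a,), bw)


def exp(a):
    a = astensor(a)
    out_data = np.exp(a.data)

    def bw(g):
        a._accumulate(g * out_data)

    return _make(out_data, (a,), bw)


def log(a):
    a = astensor(a)
    out_data = np.log(a.data)

    def bw(g):
        a._accumulate(g / a.data)

    return _make(out_data, (a,), bw)


def sqrt(a):
    a = astensor(a)
    out_data = np.sqrt(a.data)

    def bw(g):
        a._accumulate(g * 0.5 / np.maximum(out_data, 1e-12))

    return _make(out_data, (a,), bw)


def sigmoid(a):
    a = astensor(a)
    s = 1.0 / (1.0 + np.exp(-np.clip(a.data, -60, 60)))

    def bw(g):
        a._accumulate(g * s * (1.0 - s))

    return _make(s, (a,), bw)


def silu(a):
    a = astensor(a)
    s = 1.0 / (1.0 + np.exp(-np.clip(a.data, -60, 60)))
    out_data = a.data * s

    def bw(g):
        a._accumulate(g * (s * (1.0 + a.data * (1.0 - s))))

    return _make(out_data, (a,), bw)


def relu(a):
    a = astensor(a)
    out_data = np.maximum(a.data, 0.0)

    def bw(g):
        a._accumulate(g * (a.data > 0))

    return _make(out_data, (a,), bw)


def atan(a):
    a = astensor(a)
    out_data = np.arctan(a.data)

    def bw(g):
        a._accumulate(g / (1.0 + a.data ** 2))

    return _make(out_data, (a,), bw)


def clamp(a, lo=None, hi=None):
    a = astensor(a)
    out_data = np.clip(a.data, lo, hi)
    mask = np.ones_like(a.data, dtype=bool)
    if lo is not None:
        mask &= a.data >= lo
    if hi is not None:
        mask &= a.data <= hi

    def bw(g):
        a._accumulate(g * mask)

    return _make(out_data, (a,), bw)


# ---------------------------------------------------------------- reductions
def sum_(a, axis=None, keepdims=False):
    a = astensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def bw(g):
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.data.shape))
        else:
            if not keepdims:
                ax = axis if isinstance(axis, tuple) else (axis,)
                ax = tuple(i % a.data.ndim for i in ax)
                g = np.expand_dims(g, ax)
            a._accumulate(np.broadcast_to(g, a.data.shape))

    return _make(out_data, (a,), bw)


def mean_(a, axis=None, keepdims=False):
    a = astensor(a)
    if axis is None:
        n = a.data.size
    else:
        ax = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.data.shape[i] for i in ax]))
    return mul(sum_(a, axis=axis, keepdims=keepdims), 1.0 / n)


def max_(a, axis=None, keepdims=False):
    a = astensor(a)
    out_data = a.data.max(axis=axis, keepdims=keepdims)

    def bw(g):
        expanded = out_data
        gg = g
        if axis is not None and not keepdims:
            ax = axis if isinstance(axis, tuple) else (axis,)
            ax = tuple(i % a.data.ndim for i in ax)
            expanded = np.expand_dims(out_data, ax)
            gg = np.expand_dims(g, ax)
        mask = a.data == expanded
        # split the gradient between ties
        cnt = mask.sum(axis=axis, keepdims=True) if axis is not None else mask.sum()
        a._accumulate(mask * gg / cnt)

    return _make(out_data, (a,), bw)


# -------------------------------------------------------------- shape plumbing
def reshape(a, shape):
    a = astensor(a)
    out_data = a.data.reshape(shape)

    def bw(g):
        a._accumulate(g.reshape(a.data.shape))

    return _make(out_data, (a,), bw)


def transpose(a, axes):
    a = astensor(a)
    out_data = a.data.transpose(axes)
    inv = np.argsort(axes)

    def bw(g):
        a._accumulate(g.transpose(inv))

    return _make(out_data, (a,), bw)


def concat(tensors: Iterable[Tensor], axis: int = 0):
    ts = [astensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return _make(out_data, ts, bw)


def take(a, idx):
    """Indexing (basic or integer-array); adjoint scatter-adds into the source."""
    a = astensor(a)
    out_data = a.data[idx]

    def bw(g):
        buf = np.zeros_like(a.data)
        np.add.at(buf, idx, g)
        a._accumulate(buf)

    return _make(out_data, (a,), bw)


# ------------------------------------------------------------------- conv ops
def _dilated_slices(k: int, dil: int, stride: int, out_len: int):
    return [slice(i * dil, i * dil + (out_len - 1) * stride + 1, stride) for i in range(k)]


def conv2d(x, w, b=None, stride: int = 1, padding: int = 0, dilation: int = 1, groups: int = 1):
    """2-D convolution, NCHW, square kernel.  Kernel-loop im2col with analytic adjoint."""
    x, w = astensor(x), astensor(w)
    n, cin, h, wd = x.data.shape
    cout, cin_g, k, _ = w.data.shape
    if cin % groups or cout % groups or cin_g != cin // groups:
        raise ValueError("channel/group mismatch")
    hp, wp = h + 2 * padding, wd + 2 * padding
    oh = (hp - dilation * (k - 1) - 1) // stride + 1
    ow = (wp - dilation * (k - 1) - 1) // stride + 1
    if padding:
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    else:
        xp = x.data
    rows = _dilated_slices(k, dilation, stride, oh)
    cols = _dilated_slices(k, dilation, stride, ow)
    col = np.empty((n, cin, k, k, oh, ow), dtype=x.data.dtype)
    for i in range(k):
        for j in range(k):
            col[:, :, i, j] = xp[:, :, rows[i], cols[j]]
    # (n, g, cin_g*k*k, oh*ow) x (g, cout_g, cin_g*k*k)
    colg = col.reshape(n, groups, cin_g * k * k, oh * ow)
    wg = w.data.reshape(groups, cout // groups, cin_g * k * k)
    out = np.einsum("ngcl,goc->ngol", colg, wg, optimize=True)
    out = out.reshape(n, cout, oh, ow)
    if _mac_log is not None:
        _mac_log.append((n, n * oh * ow * cout * (cin // groups) * k * k))
    if b is not None:
        b = astensor(b)
        out = out + b.data.reshape(1, cout, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def bw(g):
        gg = g.reshape(n, groups, cout // groups, oh * ow)
        if w.requires_grad:
            gw = np.einsum("ngol,ngcl->goc", gg, colg, optimize=True)
            w._accumulate(gw.reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gcol = np.einsum("goc,ngol->ngcl", wg, gg, optimize=True)
            gcol = gcol.reshape(n, cin, k, k, oh, ow)
            gxp = np.zeros((n, cin, hp, wp), dtype=x.data.dtype)
            for i in range(k):
                for j in range(k):
                    gxp[:, :, rows[i], cols[j]] += gcol[:, :, i, j]
            if padding:
                gxp = gxp[:, :, padding:hp - padding, padding:wp - padding]
            x._accumulate(gxp)

    return _make(out, parents, bw)


def maxpool2d_same(x, k: int):
    """Stride-1, 'same'-padded max pooling (the SPP pyramid primitive); odd k."""
    x = astensor(x)
    if k % 2 == 0:
        raise ValueError("kernel must be odd")
    n, c, h, w = x.data.shape
    p = k // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf)
    stack = np.empty((k * k, n, c, h, w), dtype=x.data.dtype)
    for i in range(k):
        for j in range(k):
            stack[i * k + j] = xp[:, :, i:i + h, j:j + w]
    arg = stack.argmax(axis=0)
    out = np.take_along_axis(stack, arg[None], axis=0)[0]

    def bw(g):
        gxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=x.data.dtype)
        for i in range(k):
            for j in range(k):
                m = arg == i * k + j
                gxp[:, :, i:i + h, j:j + w] += g * m
        x._accumulate(gxp[:, :, p:p + h, p:p + w])

    return _make(out, (x,), bw)


def upsample_nearest(x, scale: int = 2):
    x = astensor(x)
    out_data = x.data.repeat(scale, axis=2).repeat(scale, axis=3)
    n, c, h, w = x.data.shape

    def bw(g):
        g = g.reshape(n, c, h, scale, w, scale).sum(axis=(3, 5))
        x._accumulate(g)

    return _make(out_data, (x,), bw)
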