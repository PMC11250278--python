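"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The engine provides exactly the operator set the counting network needs:
broadcasting arithmetic, matmul, softmax, 2-D convolution (im2col), adaptive
average pooling, nearest-neighbour upsampling, and the usual pointwise
nonlinearities.  Gradients are accumulated by topological traversal of the
recorded graph.  Arrays are float32 by default; float64 inputs are preserved
end-to-end, which the finite-difference gradient checks in the test-suite
rely on.
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph recording (inference mode: less memory, same numbers)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _as_float(data):
    arr = np.asarray(data)
    if arr.dtype not in (np.float32, np.float64):
        arr = arr.astype(np.float32)
    return arr


class Tensor:
    """A NumPy array plus an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = _as_float(data)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents: tuple = ()
        self._backward = None

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        flag = ", grad" if self.requires_grad else ""
        return f"Tensor(shape={self.data.shape}{flag})"

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    # -- autodiff ------------------------------------------------------------
    def backward(self, grad=None):
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; the graph can be hundreds of ops deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar ------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(_wrap(other), -1.0))

    def __rsub__(self, other):
        return add(_wrap(other), mul(self, -1.0))

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(_wrap(other), self)

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, key):
        return getitem(self, key)

    def sum(self, axis=None, keepdims=False):
        return tensor_sum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tensor_mean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        return transpose(self, axes)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _acc(t: Tensor, g: np.ndarray):
    if not t.requires_grad:
        return
    g = np.asarray(g, dtype=t.data.dtype)
    if t.grad is None:
        t.grad = g.copy()
    else:
        t.grad += g


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce gradient ``g`` back onto the broadcast-input ``shape``."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, (gs, ss) in enumerate(zip(g.shape, shape)):
        if ss == 1 and gs != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# arithmetic
# ---------------------------------------------------------------------------

def add(a, b):
    a, b = _wrap(a), _wrap(b)

    def bw(g):
        _acc(a, _unbroadcast(g, a.shape))
        _acc(b, _unbroadcast(g, b.shape))

    return _make(a.data + b.data, (a, b), bw)


def mul(a, b):
    a, b = _wrap(a), _wrap(b)

    def bw(g):
        _acc(a, _unbroadcast(g * b.data, a.shape))
        _acc(b, _unbroadcast(g * a.data, b.shape))

    return _make(a.data * b.data, (a, b), bw)


def div(a, b):
    a, b = _wrap(a), _wrap(b)

    def bw(g):
        _acc(a, _unbroadcast(g / b.data, a.shape))
        _acc(b, _unbroadcast(-g * a.data / (b.data * b.data), b.shape))

    return _make(a.data / b.data, (a, b), bw)


def power(a, p: float):
    a = _wrap(a)
    p = float(p)

    def bw(g):
        _acc(a, g * p * a.data ** (p - 1.0))

    return _make(a.data ** p, (a,), bw)


def exp(a):
    a = _wrap(a)
    out_data = np.exp(a.data)

    def bw(g):
        _acc(a, g * out_data)

    return _make(out_data, (a,), bw)


def log(a):
    a = _wrap(a)

    def bw(g):
        _acc(a, g / a.data)

    return _make(np.log(a.data), (a,), bw)


def sqrt(a):
    a = _wrap(a)
    out_data = np.sqrt(a.data)

    def bw(g):
        _acc(a, g * 0.5 / out_data)

    return _make(out_data, (a,), bw)


def absolute(a):
    a = _wrap(a)

    def bw(g):
        _acc(a, g * np.sign(a.data))

    return _make(np.abs(a.data), (a,), bw)


def clip(a, lo: float, hi: float):
    a = _wrap(a)
    mask = (a.data >= lo) & (a.data <= hi)

    def bw(g):
        _acc(a, g * mask)

    return _make(np.clip(a.data, lo, hi), (a,), bw)


def tanh(a):
    a = _wrap(a)
    out_data = np.tanh(a.data)

    def bw(g):
        _acc(a, g * (1.0 - out_data * out_data))

    return _make(out_data, (a,), bw)


def sigmoid(a):
    a = _wrap(a)
    out_data = np.where(a.data >= 0,
                        1.0 / (1.0 + np.exp(-np.abs(a.data))),
                        np.exp(-np.abs(a.data)) / (1.0 + np.exp(-np.abs(a.data))))

    def bw(g):
        _acc(a, g * out_data * (1.0 - out_data))

    return _make(out_data, (a,), bw)


def relu(a):
    a = _wrap(a)
    mask = a.data > 0

    def bw(g):
        _acc(a, g * mask)

    return _make(a.data * mask, (a,), bw)


def silu(a):
    """x * sigmoid(x) (the activation inside CBS blocks)."""
    a = _wrap(a)
    s = np.where(a.data >= 0,
                 1.0 / (1.0 + np.exp(-np.abs(a.data))),
                 np.exp(-np.abs(a.data)) / (1.0 + np.exp(-np.abs(a.data))))
    out_data = a.data * s

    def bw(g):
        _acc(a, g * (s * (1.0 + a.data * (1.0 - s))))

    return _make(out_data, (a,), bw)


def gelu(a):
    """Gaussian error linear unit, tanh approximation (transformer FFN)."""
    a = _wrap(a)
    c = np.sqrt(2.0 / np.pi).astype(a.data.dtype) if a.data.dtype == np.float32 else np.sqrt(2.0 / np.pi)
    u = c * (a.data + 0.044715 * a.data ** 3)
    t = np.tanh(u)
    out_data = 0.5 * a.data * (1.0 + t)

    def bw(g):
        du = c * (1.0 + 3 * 0.044715 * a.data ** 2)
        _acc(a, g * (0.5 * (1.0 + t) + 0.5 * a.data * (1.0 - t * t) * du))

    return _make(out_data, (a,), bw)


# ---------------------------------------------------------------------------
# reductions and shape ops
# ---------------------------------------------------------------------------

def _norm_axes(axis, ndim):
    if axis is None:
        return tuple(range(ndim))
    if isinstance(axis, int):
        axis = (axis,)
    return tuple(a % ndim for a in axis)


def tensor_sum(a, axis=None, keepdims=False):
    a = _wrap(a)
    axes = _norm_axes(axis, a.ndim)
    out_data = a.data.sum(axis=axes, keepdims=keepdims)

    def bw(g):
        if not keepdims:
            for ax in sorted(axes):
                g = np.expand_dims(g, ax)
        _acc(a, np.broadcast_to(g, a.shape))

    return _make(out_data, (a,), bw)


def tensor_mean(a, axis=None, keepdims=False):
    a = _wrap(a)
    axes = _norm_axes(axis, a.ndim)
    n = int(np.prod([a.shape[ax] for ax in axes]))
    return mul(tensor_sum(a, axis=axes, keepdims=keepdims), 1.0 / n)


def reshape(a, shape):
    a = _wrap(a)

    def bw(g):
        _acc(a, g.reshape(a.shape))

    return _make(a.data.reshape(shape), (a,), bw)


def transpose(a, axes):
    a = _wrap(a)
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))

    def bw(g):
        _acc(a, g.transpose(inv))

    return _make(a.data.transpose(axes), (a,), bw)


def getitem(a, key):
    a = _wrap(a)

    def bw(g):
        z = np.zeros(a.shape, dtype=a.data.dtype)
        np.add.at(z, key, g)
        _acc(a, z)

    return _make(a.data[key], (a,), bw)


def concat(tensors: Iterable[Tensor], axis: int = 0):
    tensors = [_wrap(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(int(lo), int(hi))
            _acc(t, g[tuple(sl)])

    return _make(np.concatenate([t.data for t in tensors], axis=axis), tensors, bw)


def matmul(a, b):
    a, b = _wrap(a), _wrap(b)

    def bw(g):
        ga = np.matmul(g, b.data.swapaxes(-1, -2))
        gb = np.matmul(a.data.swapaxes(-1, -2), g)
        _acc(a, _unbroadcast(ga, a.shape))
        _acc(b, _unbroadcast(gb, b.shape))

    return _make(np.matmul(a.data, b.data), (a, b), bw)


def softmax(a, axis: int = -1):
    a = _wrap(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def bw(g):
        dot = (g * out_data).sum(axis=axis, keepdims=True)
        _acc(a, out_data * (g - dot))

    return _make(out_data, (a,), bw)


# ---------------------------------------------------------------------------
# spatial ops (NCHW)
# ---------------------------------------------------------------------------

def conv2d(x, w, b=None, stride: int = 1, padding: int = 0, dilation: int = 1):
    """2-D cross-correlation via im2col.

    x: (N, Cin, H, W);  w: (Cout, Cin, kh, kw);  b: (Cout,) or None.
    """
    x, w = _wrap(x), _wrap(w)
    if b is not None:
        b = _wrap(b)
    N, C, H, W = x.shape
    Cout, Cin, kh, kw = w.shape
    if Cin != C:
        raise ValueError(f"conv2d channel mismatch: input {C}, weight expects {Cin}")
    Hp, Wp = H + 2 * padding, W + 2 * padding
    oh = (Hp - dilation * (kh - 1) - 1) // stride + 1
    ow = (Wp - dilation * (kw - 1) - 1) // stride + 1
    if oh <= 0 or ow <= 0:
        raise ValueError("conv2d: kernel larger than (padded) input")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    ii = (np.arange(kh) * dilation)[:, None] + (np.arange(oh) * stride)[None, :]  # (kh, oh)
    jj = (np.arange(kw) * dilation)[:, None] + (np.arange(ow) * stride)[None, :]  # (kw, ow)
    cols = xp[:, :, ii[:, None, :, None], jj[None, :, None, :]]  # (N,C,kh,kw,oh,ow)
    cols2 = cols.reshape(N, C * kh * kw, oh * ow)
    w2 = w.data.reshape(Cout, C * kh * kw)
    out_data = np.matmul(w2, cols2).reshape(N, Cout, oh, ow)
    if b is not None:
        out_data = out_data + b.data.reshape(1, Cout, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def bw(g):
        g2 = g.reshape(N, Cout, oh * ow)
        if w.requires_grad:
            gw = np.matmul(g2, cols2.transpose(0, 2, 1)).sum(axis=0)
            _acc(w, gw.reshape(w.shape))
        if b is not None and b.requires_grad:
            _acc(b, g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gcols = np.matmul(w2.T, g2).reshape(N, C, kh, kw, oh, ow)
            gxp = np.zeros_like(xp)
            np.add.at(gxp, (slice(None), slice(None),
                            ii[:, None, :, None], jj[None, :, None, :]), gcols)
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding]
            _acc(x, gxp)

    return _make(out_data, parents, bw)


def adaptive_avg_pool2d(x, out_hw):
    """Average-pool to an (oh, ow) grid with near-equal bins."""
    x = _wrap(x)
    N, C, H, W = x.shape
    oh, ow = out_hw
    hb = [(int(np.floor(i * H / oh)), int(np.ceil((i + 1) * H / oh))) for i in range(oh)]
    wb = [(int(np.floor(j * W / ow)), int(np.ceil((j + 1) * W / ow))) for j in range(ow)]
    out_data = np.empty((N, C, oh, ow), dtype=x.data.dtype)
    for i, (h0, h1) in enumerate(hb):
        for j, (w0, w1) in enumerate(wb):
            out_data[:, :, i, j] = x.data[:, :, h0:h1, w0:w1].mean(axis=(2, 3))

    def bw(g):
        gx = np.zeros_like(x.data)
        for i, (h0, h1) in enumerate(hb):
            for j, (w0, w1) in enumerate(wb):
                area = (h1 - h0) * (w1 - w0)
                gx[:, :, h0:h1, w0:w1] += g[:, :, i:i + 1, j:j + 1] / area
        _acc(x, gx)

    return _make(out_data, (x,), bw)


def upsample_nearest(x, scale: int):
    x = _wrap(x)
    s = int(scale)
    N, C, H, W = x.shape
    out_data = x.data.repeat(s, axis=2).repeat(s, axis=3)

    def bw(g):
        _acc(x, g.reshape(N, C, H, s, W, s).sum(axis=(3, 5)))

    return _make(out_data, (x,), bw)
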