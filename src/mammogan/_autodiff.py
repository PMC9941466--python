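"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports higher-order gradients: every backward rule is itself expressed in
terms of the primitives below, so a gradient computed with ``create_graph=True``
can be differentiated again.  This is what makes the R1 gradient penalty of the
adversarial trainer (a derivative of a derivative) computable without an
external deep-learning framework.

Only the operations the generator / discriminator / projector actually need are
implemented; everything runs in float32 for speed.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph recording within the block."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _asarray(x) -> np.ndarray:
    a = np.asarray(x)
    if a.dtype != np.float32:
        a = a.astype(np.float32)
    return a


class Tensor:
    """A numpy array plus the bookkeeping needed for reverse-mode autodiff."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[Tensor], Sequence[Tensor | None]] | None = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad or p._parents for p in parents):
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(_ensure(other), -1.0))

    def __rsub__(self, other):
        return add(_ensure(other), mul(self, -1.0))

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _ensure(other)
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return mul(_ensure(other), power(self, -1.0))

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        return transpose(self, axes if axes else None)

    # -- backward entry point (bound below) -----------------------------------
    def backward(self):  # pragma: no cover - replaced after grad_of is defined
        raise NotImplementedError


def _ensure(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _topo(root: Tensor) -> list[Tensor]:
    order: list[Tensor] = []
    seen: set[int] = set()
    stack = [(root, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            if id(p) not in seen:
                stack.append((p, False))
    return order


def grad_of(output: Tensor, inputs: Sequence[Tensor], create_graph: bool = False) -> list[Tensor]:
    """Gradients of scalar ``output`` w.r.t. ``inputs``, returned as Tensors."""
    if output.data.size != 1:
        raise ValueError("grad_of() requires a scalar output")
    wanted = {id(t) for t in inputs}
    gmap: dict[int, Tensor] = {id(output): Tensor(np.ones_like(output.data))}
    keep: dict[int, Tensor] = {}
    ctx = contextlib.nullcontext() if create_graph else no_grad()
    with ctx:
        for node in reversed(_topo(output)):
            g = gmap.pop(id(node), None)
            if g is None:
                continue
            if id(node) in wanted:
                keep[id(node)] = g
            if node._backward is None:
                continue
            for p, pg in zip(node._parents, node._backward(g)):
                if pg is None:
                    continue
                if id(p) in gmap:
                    gmap[id(p)] = add(gmap[id(p)], pg)
                else:
                    gmap[id(p)] = pg
    out = []
    for t in inputs:
        g = keep.get(id(t))
        if g is None:
            g = Tensor(np.zeros_like(t.data))
        out.append(g)
    return out


# fix Tensor.backward to use grad_of-style accumulation
def _backward_impl(self: Tensor):
    if self.data.size != 1:
        raise ValueError("backward() requires a scalar output")
    gmap: dict[int, Tensor] = {id(self): Tensor(np.ones_like(self.data))}
    with no_grad():
        for node in reversed(_topo(self)):
            g = gmap.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g.data if node.grad is None else node.grad + g.data
            if node._backward is None:
                continue
            for p, pg in zip(node._parents, node._backward(g)):
                if pg is None:
                    continue
                if id(p) in gmap:
                    gmap[id(p)] = add(gmap[id(p)], pg)
                else:
                    gmap[id(p)] = pg


Tensor.backward = _backward_impl  # type: ignore[assignment]


# -- broadcasting helpers ------------------------------------------------------
def _unbroadcast(g: Tensor, shape: tuple[int, ...]) -> Tensor:
    """Sum ``g`` down to ``shape`` (adjoint of numpy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = tsum(g, axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    if g.shape != shape:
        g = reshape(g, shape)
    return g


def broadcast_to(a: Tensor, shape) -> Tensor:
    a = _ensure(a)
    shape = tuple(shape)
    out_data = np.broadcast_to(a.data, shape)

    def bw(g):
        return (_unbroadcast(g, a.shape),)

    return Tensor._make(np.ascontiguousarray(out_data), (a,), bw)


# -- elementwise primitives ----------------------------------------------------
def add(a, b) -> Tensor:
    a, b = _ensure(a), _ensure(b)
    out = Tensor._make(a.data + b.data, (a, b), None)
    if out._parents:
        out._backward = lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape))
    return out


def mul(a, b) -> Tensor:
    a, b = _ensure(a), _ensure(b)
    out = Tensor._make(a.data * b.data, (a, b), None)
    if out._parents:
        out._backward = lambda g: (
            _unbroadcast(mul(g, b), a.shape),
            _unbroadcast(mul(g, a), b.shape),
        )
    return out


def power(a, p: float) -> Tensor:
    a = _ensure(a)
    p = float(p)
    out = Tensor._make(a.data**p, (a,), None)
    if out._parents:
        out._backward = lambda g: (mul(g, mul(power(a, p - 1.0), p)),)
    return out


def sqrt(a) -> Tensor:
    return power(a, 0.5)


def rsqrt(a) -> Tensor:
    return power(a, -0.5)


def exp(a) -> Tensor:
    a = _ensure(a)
    out = Tensor._make(np.exp(a.data), (a,), None)
    if out._parents:
        out._backward = lambda g: (mul(g, out),)
    return out


def log(a) -> Tensor:
    a = _ensure(a)
    out = Tensor._make(np.log(a.data), (a,), None)
    if out._parents:
        out._backward = lambda g: (mul(g, power(a, -1.0)),)
    return out


def tanh(a) -> Tensor:
    a = _ensure(a)
    out = Tensor._make(np.tanh(a.data), (a,), None)
    if out._parents:
        out._backward = lambda g: (mul(g, add(1.0, mul(mul(out, out), -1.0))),)
    return out


def sigmoid(a) -> Tensor:
    a = _ensure(a)
    with np.errstate(over="ignore"):
        s = 1.0 / (1.0 + np.exp(-a.data))
    out = Tensor._make(s, (a,), None)
    if out._parents:
        out._backward = lambda g: (mul(g, mul(out, add(1.0, mul(out, -1.0)))),)
    return out


def softplus(a) -> Tensor:
    """log(1 + exp(a)), numerically stable."""
    a = _ensure(a)
    data = np.logaddexp(0.0, a.data)
    out = Tensor._make(data, (a,), None)
    if out._parents:
        out._backward = lambda g: (mul(g, sigmoid(a)),)
    return out


def leaky_relu(a, slope: float = 0.2) -> Tensor:
    a = _ensure(a)
    factor = np.where(a.data > 0, np.float32(1.0), np.float32(slope))
    out = Tensor._make(a.data * factor, (a,), None)
    if out._parents:
        fac = Tensor(factor)
        out._backward = lambda g: (mul(g, fac),)
    return out


# -- reductions / shape --------------------------------------------------------
def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = _ensure(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims, dtype=np.float32)

    def bw(g):
        gd = g
        if axis is not None and not keepdims:
            ax = axis if isinstance(axis, tuple) else (axis,)
            ax = tuple(x % a.ndim for x in ax)
            shp = tuple(1 if i in ax else s for i, s in enumerate(a.shape))
            gd = reshape(gd, shp)
        elif axis is None and not keepdims:
            gd = reshape(gd, (1,) * a.ndim)
        return (broadcast_to(gd, a.shape),)

    return Tensor._make(out_data, (a,), bw)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = _ensure(a)
    if axis is None:
        n = a.data.size
    else:
        ax = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.shape[x % a.ndim] for x in ax]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def reshape(a, shape) -> Tensor:
    a = _ensure(a)
    shape = tuple(shape)
    out = Tensor._make(a.data.reshape(shape), (a,), None)
    if out._parents:
        out._backward = lambda g: (reshape(g, a.shape),)
    return out


def transpose(a, axes=None) -> Tensor:
    a = _ensure(a)
    if axes is None:
        axes = tuple(reversed(range(a.ndim)))
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))
    out = Tensor._make(np.ascontiguousarray(a.data.transpose(axes)), (a,), None)
    if out._parents:
        out._backward = lambda g: (transpose(g, inv),)
    return out


def matmul(a, b) -> Tensor:
    """2-D or batched (3-D x 3-D, 3-D x 2-D) matrix product."""
    a, b = _ensure(a), _ensure(b)
    out = Tensor._make(np.matmul(a.data, b.data), (a, b), None)
    if out._parents:

        def bw(g):
            bt = transpose(b, (0, 2, 1)) if b.ndim == 3 else transpose(b)
            at = transpose(a, (0, 2, 1)) if a.ndim == 3 else transpose(a)
            ga = matmul(g, bt)
            gb = matmul(at, g)
            return (_unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape))

        out._backward = bw
    return out


# -- convolution plumbing ------------------------------------------------------
def _im2col_np(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    b, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (b, c, ho, wo, k, k)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(b, ho * wo, c * k * k)
    return np.ascontiguousarray(cols)


def _col2im_np(
    cols: np.ndarray, xshape: tuple[int, ...], k: int, stride: int, pad: int
) -> np.ndarray:
    b, c, h, w = xshape
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    cols = cols.reshape(b, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    out = np.zeros((b, c, h + 2 * pad, w + 2 * pad), dtype=np.float32)
    for i in range(k):
        for j in range(k):
            out[:, :, i : i + ho * stride : stride, j : j + wo * stride : stride] += cols[
                :, :, :, :, i, j
            ]
    if pad:
        out = out[:, :, pad : pad + h, pad : pad + w]
    return np.ascontiguousarray(out)


def im2col(x: Tensor, k: int, stride: int = 1, pad: int = 0) -> Tensor:
    x = _ensure(x)
    xshape = x.shape
    out = Tensor._make(_im2col_np(x.data, k, stride, pad), (x,), None)
    if out._parents:
        out._backward = lambda g: (col2im(g, xshape, k, stride, pad),)
    return out


def col2im(cols: Tensor, xshape, k: int, stride: int = 1, pad: int = 0) -> Tensor:
    cols = _ensure(cols)
    xshape = tuple(xshape)
    out = Tensor._make(_col2im_np(cols.data, xshape, k, stride, pad), (cols,), None)
    if out._parents:
        out._backward = lambda g: (im2col(g, k, stride, pad),)
    return out


def conv2d(x: Tensor, w: Tensor, stride: int = 1, pad: int = 0) -> Tensor:
    """Cross-correlation of (B,Cin,H,W) with (Cout,Cin,k,k)."""
    b = x.shape[0]
    cout, cin, k, _ = w.shape
    ho = (x.shape[2] + 2 * pad - k) // stride + 1
    wo = (x.shape[3] + 2 * pad - k) // stride + 1
    cols = im2col(x, k, stride, pad)  # (B, L, Cin*k*k)
    wmat = transpose(reshape(w, (cout, cin * k * k)))  # (Cin*k*k, Cout)
    out = matmul(cols, wmat)  # (B, L, Cout)
    out = transpose(out, (0, 2, 1))
    return reshape(out, (b, cout, ho, wo))


def batched_conv2d(x: Tensor, w: Tensor, stride: int = 1, pad: int = 0) -> Tensor:
    """Per-sample weights: x (B,Cin,H,W), w (B,Cout,Cin,k,k)."""
    b = x.shape[0]
    cout, cin, k = w.shape[1], w.shape[2], w.shape[3]
    ho = (x.shape[2] + 2 * pad - k) // stride + 1
    wo = (x.shape[3] + 2 * pad - k) // stride + 1
    cols = im2col(x, k, stride, pad)  # (B, L, Cin*k*k)
    wmat = transpose(reshape(w, (b, cout, cin * k * k)), (0, 2, 1))  # (B, CinKK, Cout)
    out = matmul(cols, wmat)  # (B, L, Cout)
    out = transpose(out, (0, 2, 1))
    return reshape(out, (b, cout, ho, wo))


def avg_pool2(x: Tensor) -> Tensor:
    """2x2 average pooling of (B,C,H,W)."""
    b, c, h, w = x.shape
    y = reshape(x, (b, c, h // 2, 2, w // 2, 2))
    return tmean(y, axis=(3, 5))


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling of (B,C,H,W)."""
    b, c, h, w = x.shape
    y = reshape(x, (b, c, h, 1, w, 1))
    y = broadcast_to(y, (b, c, h, 2, w, 2))
    return reshape(y, (b, c, 2 * h, 2 * w))


# -- optimiser -----------------------------------------------------------------
class Adam:
    """Adam on a list of parameter Tensors (grads read from ``.grad``)."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3, betas=(0.0, 0.99), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1.0 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
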