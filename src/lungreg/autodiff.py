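"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The registration losses, the trilinear warping and the displacement-regression
network all need gradients with respect to dense displacement fields and
convolution weights.  This module provides exactly the primitives those
computations are composed of: broadcasting arithmetic, reductions, slicing and
concatenation, gather (fancy integer indexing), piecewise selection, and the
3D convolution/pooling operators of the network.

Gradients are accumulated by a topological backward sweep over the recorded
computation graph.  Everything is float64; the intended problem sizes are
desk-scale volumes (<= 64^3), where NumPy vectorization is entirely adequate.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "as_tensor", "concatenate", "where", "gather3", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("value", "grad", "_parents", "_vjp", "requires_grad")

    def __init__(self, value, parents: tuple = (), vjp: Callable | None = None,
                 requires_grad: bool | None = None):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._parents = parents
        self._vjp = vjp
        if requires_grad is None:
            requires_grad = any(p.requires_grad for p in parents)
        self.requires_grad = requires_grad

    # -- introspection -----------------------------------------------------
    @property
    def shape(self):
        return self.value.shape

    @property
    def ndim(self):
        return self.value.ndim

    def item(self) -> float:
        return float(self.value)

    def __repr__(self):
        return f"Tensor(shape={self.value.shape}, requires_grad={self.requires_grad})"

    # -- graph construction ------------------------------------------------
    def _op(self, value, parents, vjp):
        return Tensor(value, parents=parents, vjp=vjp)

    def __add__(self, other):
        o = as_tensor(other)
        return Tensor(self.value + o.value, (self, o),
                      lambda g: (_unbroadcast(g, self.shape), _unbroadcast(g, o.shape)))

    __radd__ = __add__

    def __sub__(self, other):
        o = as_tensor(other)
        return Tensor(self.value - o.value, (self, o),
                      lambda g: (_unbroadcast(g, self.shape), _unbroadcast(-g, o.shape)))

    def __rsub__(self, other):
        return as_tensor(other) - self

    def __mul__(self, other):
        o = as_tensor(other)
        return Tensor(self.value * o.value, (self, o),
                      lambda g: (_unbroadcast(g * o.value, self.shape),
                                 _unbroadcast(g * self.value, o.shape)))

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = as_tensor(other)
        return Tensor(self.value / o.value, (self, o),
                      lambda g: (_unbroadcast(g / o.value, self.shape),
                                 _unbroadcast(-g * self.value / o.value ** 2, o.shape)))

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __neg__(self):
        return Tensor(-self.value, (self,), lambda g: (-g,))

    def __pow__(self, p):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents are supported")
        return Tensor(self.value ** p, (self,),
                      lambda g: (g * p * self.value ** (p - 1),))

    def log(self):
        return Tensor(np.log(self.value), (self,), lambda g: (g / self.value,))

    def sqrt(self):
        out = np.sqrt(self.value)
        return Tensor(out, (self,), lambda g: (g * 0.5 / out,))

    def relu(self):
        mask = self.value > 0
        return Tensor(np.where(mask, self.value, 0.0), (self,),
                      lambda g: (g * mask,))

    def clip(self, lo, hi):
        """Clamp values; gradient is passed only where unclipped."""
        inside = (self.value >= lo) & (self.value <= hi)
        return Tensor(np.clip(self.value, lo, hi), (self,),
                      lambda g: (g * inside,))

    def sum(self, axis=None, keepdims: bool = False):
        def vjp(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            gg = g
            if not keepdims:
                gg = np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.shape).copy(),)
        return Tensor(self.value.sum(axis=axis, keepdims=keepdims), (self,), vjp)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.value.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return Tensor(self.value.reshape(shape), (self,),
                      lambda g: (g.reshape(self.shape),))

    def transpose(self, axes):
        inv = np.argsort(axes)
        return Tensor(self.value.transpose(axes), (self,),
                      lambda g: (g.transpose(inv),))

    def __getitem__(self, idx):
        def vjp(g):
            gx = np.zeros(self.shape)
            np.add.at(gx, idx, g)
            return (gx,)
        return Tensor(self.value[idx], (self,), vjp)

    # -- backward ----------------------------------------------------------
    def backward(self, seed: np.ndarray | None = None):
        if seed is None:
            if self.value.size != 1:
                raise ValueError("backward() without seed requires a scalar output")
            seed = np.ones_like(self.value)
        # iterative topological order
        order: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in visited or not node.requires_grad:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in visited:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(seed, dtype=np.float64)}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            node.grad = g if node.grad is None else node.grad + g
            if node._vjp is None:
                continue
            pgrads = node._vjp(g)
            for p, pg in zip(node._parents, pgrads):
                if pg is None or not p.requires_grad:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg


def as_tensor(x) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(x, requires_grad=False)


def concatenate(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def vjp(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(np.concatenate([t.value for t in tensors], axis=axis),
                  tuple(tensors), vjp)


def where(cond: np.ndarray, a, b) -> Tensor:
    """Select elementwise; `cond` is a constant boolean array."""
    cond = np.asarray(cond, dtype=bool)
    ta, tb = as_tensor(a), as_tensor(b)
    return Tensor(np.where(cond, ta.value, tb.value), (ta, tb),
                  lambda g: (_unbroadcast(np.where(cond, g, 0.0), ta.shape),
                             _unbroadcast(np.where(cond, 0.0, g), tb.shape)))


def gather3(x: Tensor, ii: np.ndarray, jj: np.ndarray, kk: np.ndarray) -> Tensor:
    """x[ii, jj, kk] for a 3D tensor and constant integer index arrays.

    Backward scatters with bincount on raveled indices (much faster than
    np.add.at for the dense index sets produced by warping)."""
    x = as_tensor(x)
    d, h, w = x.shape
    flat = ((ii * h + jj) * w + kk).ravel()

    def vjp(g):
        gx = np.bincount(flat, weights=np.asarray(g, dtype=np.float64).ravel(),
                         minlength=d * h * w)
        return (gx.reshape(d, h, w),)

    return Tensor(x.value.ravel()[flat].reshape(ii.shape), (x,), vjp)


# ---------------------------------------------------------------------------
# network primitives (channels-first: [C, D, H, W])
# ---------------------------------------------------------------------------

def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """3x3x3 convolution, stride 1, zero padding 1.  w: [C_out, C_in, 3,3,3]."""
    x, w = as_tensor(x), as_tensor(w)
    xp = np.pad(x.value, ((0, 0), (1, 1), (1, 1), (1, 1)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3, 3), axis=(1, 2, 3))
    out = np.einsum("cdhwijk,ocijk->odhw", win, w.value, optimize=True)
    parents = [x, w]
    if b is not None:
        b = as_tensor(b)
        out = out + b.value[:, None, None, None]
        parents.append(b)

    def vjp(g):
        gw = np.einsum("cdhwijk,odhw->ocijk", win, g, optimize=True)
        gp = np.pad(g, ((0, 0), (1, 1), (1, 1), (1, 1)))
        gwin = np.lib.stride_tricks.sliding_window_view(gp, (3, 3, 3), axis=(1, 2, 3))
        wf = w.value[:, :, ::-1, ::-1, ::-1]
        gx = np.einsum("odhwijk,ocijk->cdhw", gwin, wf, optimize=True)
        out = [gx, gw]
        if b is not None:
            out.append(g.sum(axis=(1, 2, 3)))
        return tuple(out)

    return Tensor(out, tuple(parents), vjp)


def conv1x1(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Pointwise convolution.  w: [C_out, C_in]."""
    x, w = as_tensor(x), as_tensor(w)
    out = np.einsum("cdhw,oc->odhw", x.value, w.value, optimize=True)
    parents = [x, w]
    if b is not None:
        b = as_tensor(b)
        out = out + b.value[:, None, None, None]
        parents.append(b)

    def vjp(g):
        gx = np.einsum("odhw,oc->cdhw", g, w.value, optimize=True)
        gw = np.einsum("odhw,cdhw->oc", g, x.value, optimize=True)
        out = [gx, gw]
        if b is not None:
            out.append(g.sum(axis=(1, 2, 3)))
        return tuple(out)

    return Tensor(out, tuple(parents), vjp)


def avg_pool2(x: Tensor) -> Tensor:
    """2x2x2 average pooling with stride 2 (shape must be even)."""
    x = as_tensor(x)
    c, d, h, w = x.shape
    v = x.value.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
    out = v.mean(axis=(2, 4, 6))

    def vjp(g):
        gx = np.broadcast_to(g[:, :, None, :, None, :, None] / 8.0,
                             (c, d // 2, 2, h // 2, 2, w // 2, 2))
        return (gx.reshape(c, d, h, w).copy(),)

    return Tensor(out, (x,), vjp)


def conv_transpose2(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """2x2x2 transposed convolution, stride 2.  w: [C_in, C_out, 2,2,2]."""
    x, w = as_tensor(x), as_tensor(w)
    cin, d, h, wd = x.shape
    cout = w.shape[1]
    out7 = np.einsum("cdhw,coijk->odihjwk", x.value, w.value, optimize=True)
    out = out7.reshape(cout, 2 * d, 2 * h, 2 * wd)
    parents = [x, w]
    if b is not None:
        b = as_tensor(b)
        out = out + b.value[:, None, None, None]
        parents.append(b)

    def vjp(g):
        g7 = g.reshape(cout, d, 2, h, 2, wd, 2)
        gx = np.einsum("odihjwk,coijk->cdhw", g7, w.value, optimize=True)
        gw = np.einsum("cdhw,odihjwk->coijk", x.value, g7, optimize=True)
        out = [gx, gw]
        if b is not None:
            out.append(g.sum(axis=(1, 2, 3)))
        return tuple(out)

    return Tensor(out, tuple(parents), vjp)


def instance_norm(x: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-channel normalization over the spatial axes (no affine parameters)."""
    mu = x.mean(axis=(1, 2, 3), keepdims=True)
    centered = x - mu
    var = (centered * centered).mean(axis=(1, 2, 3), keepdims=True)
    return centered / (var + eps).sqrt()


class Adam:
    """Adaptive-moment gradient descent over a list of parameter Tensors."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros(p.shape) for p in self.params]
        self.v = [np.zeros(p.shape) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.value = p.value - self.lr * mhat / (np.sqrt(vhat) + self.eps)
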