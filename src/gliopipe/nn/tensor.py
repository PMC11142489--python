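"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small engine for the desk-scale 3D networks in this
package: tensors record their parents and a backward closure, and
``Tensor.backward`` walks the graph in reverse topological order.
Supported primitives cover exactly what the segmentation, attention and
curriculum branches need — elementwise arithmetic, matmul, reductions
(sum / mean / max), reshape/concat, 3D convolution via im2col, factor
pooling, nearest-neighbor upsampling and the usual activations.

Gradients accumulate in ``Tensor.grad`` as float64 arrays.  Broadcasting
follows numpy; gradients of broadcast operands are summed back to the
operand's shape.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "concat",
    "conv3d",
    "avg_pool3d",
    "upsample_nearest3d",
    "softmax",
    "cross_entropy_logits",
    "instance_norm3d",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a gradient over the axes that numpy broadcasting expanded."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: tuple["Tensor", ...] = (),
        _backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = _backward

    # -- graph plumbing ----------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep
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
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(-g * self.data / other.data**2, other.data.shape))

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        out._backward = bw
        return out

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape):
        src = self.data.shape
        out = Tensor(self.data.reshape(*shape), _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g.reshape(src))
        return out

    def transpose(self, *axes):
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(*axes), _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g.transpose(*inv))
        return out

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis, keepdims: bool = False):
        """Max over axes; ties share the gradient equally."""
        val = self.data.max(axis=axis, keepdims=True)
        out_data = val if keepdims else np.squeeze(val, axis=axis)
        out = Tensor(out_data, _parents=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            mask = (self.data == val).astype(np.float64)
            mask /= mask.sum(axis=axis, keepdims=True)
            self._accumulate(mask * g)

        out._backward = bw
        return out

    # -- activations -------------------------------------------------------

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g * mask)
        return out

    def leaky_relu(self, alpha: float = 0.01):
        slope = np.where(self.data > 0, 1.0, alpha)
        out = Tensor(self.data * slope, _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g * slope)
        return out

    def sqrt(self):
        s = np.sqrt(self.data)
        out = Tensor(s, _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g * 0.5 / s)
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = Tensor(s, _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g * s * (1.0 - s))
        return out

    def log(self, floor: float = 0.0):
        """Natural log; with ``floor`` > 0, inputs are clamped from below
        (gradient zero where the clamp is active)."""
        x = np.maximum(self.data, floor) if floor > 0 else self.data
        out = Tensor(np.log(x), _parents=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            grad = g / x
            if floor > 0:
                grad = grad * (self.data >= floor)
            self._accumulate(grad)

        out._backward = bw
        return out


# ---------------------------------------------------------------------------
# structural ops


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    tensors = list(tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)

    out._backward = bw
    return out


_COL_INDEX_CACHE: dict[tuple, np.ndarray] = {}


def _col_indices(c, dp, hp, wp, k, s, do, ho, wo) -> np.ndarray:
    """Flat indices into the padded (C,Dp,Hp,Wp) array for each im2col cell."""
    key = (c, dp, hp, wp, k, s, do, ho, wo)
    idx = _COL_INDEX_CACHE.get(key)
    if idx is None:
        d0 = np.arange(do) * s
        h0 = np.arange(ho) * s
        w0 = np.arange(wo) * s
        kd, kh, kw = np.meshgrid(np.arange(k), np.arange(k), np.arange(k), indexing="ij")
        cc = np.arange(c)
        # positions: (do,ho,wo) x cells: (c,k,k,k)
        dd = d0[:, None, None, None, None, None, None] + kd[None, None, None, None]
        hh = h0[None, :, None, None, None, None, None] + kh[None, None, None, None]
        ww = w0[None, None, :, None, None, None, None] + kw[None, None, None, None]
        flat = ((cc[None, None, None, :, None, None, None] * dp + dd) * hp + hh) * wp + ww
        idx = flat.reshape(do * ho * wo, c * k * k * k)
        if len(_COL_INDEX_CACHE) > 32:
            _COL_INDEX_CACHE.clear()
        _COL_INDEX_CACHE[key] = idx
    return idx


def conv3d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, padding: int = 0) -> Tensor:
    """3D convolution (cross-correlation) with cubic kernels.

    ``x``: (B, C, D, H, W); ``w``: (O, C, k, k, k); ``b``: (O,) or None.
    """
    B, C, D, H, W = x.data.shape
    O, Cw, k, _, _ = w.data.shape
    if Cw != C:
        raise ValueError(f"conv3d channel mismatch: input {C}, weight {Cw}")
    p, s = padding, stride
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p), (p, p))) if p else x.data
    Dp, Hp, Wp = xp.shape[2:]
    Do, Ho, Wo = (Dp - k) // s + 1, (Hp - k) // s + 1, (Wp - k) // s + 1
    win = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))[:, :, ::s, ::s, ::s]
    # (B, C, Do, Ho, Wo, k,k,k) -> (B, P, C*k^3)
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 4, 1, 5, 6, 7)).reshape(B, Do * Ho * Wo, C * k**3)
    wm = w.data.reshape(O, C * k**3)
    out_data = cols @ wm.T
    if b is not None:
        out_data = out_data + b.data
    out_data = out_data.transpose(0, 2, 1).reshape(B, O, Do, Ho, Wo)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, _parents=parents)

    def bw(g):
        gcols = g.reshape(B, O, Do * Ho * Wo).transpose(0, 2, 1)  # (B,P,O)
        if w.requires_grad:
            gw = gcols.reshape(B * Do * Ho * Wo, O).T @ cols.reshape(B * Do * Ho * Wo, C * k**3)
            w._accumulate(gw.reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accumulate(gcols.sum(axis=(0, 1)))
        if x.requires_grad:
            gx_cols = gcols @ wm  # (B,P,C*k^3)
            idx = _col_indices(C, Dp, Hp, Wp, k, s, Do, Ho, Wo)
            gxp = np.zeros((B, C * Dp * Hp * Wp))
            for bi in range(B):
                np.add.at(gxp[bi], idx.ravel(), gx_cols[bi].ravel())
            gxp = gxp.reshape(B, C, Dp, Hp, Wp)
            if p:
                gxp = gxp[:, :, p:-p, p:-p, p:-p]
            x._accumulate(gxp)

    out._backward = bw
    return out


def avg_pool3d(x: Tensor, factor: int) -> Tensor:
    """Non-overlapping average pooling by an integer factor (shape must divide)."""
    B, C, D, H, W = x.data.shape
    f = factor
    if D % f or H % f or W % f:
        raise ValueError(f"avg_pool3d: spatial shape {(D, H, W)} not divisible by {f}")
    r = x.data.reshape(B, C, D // f, f, H // f, f, W // f, f)
    out = Tensor(r.mean(axis=(3, 5, 7)), _parents=(x,))

    def bw(g):
        if x.requires_grad:
            g = g[:, :, :, None, :, None, :, None] / f**3
            x._accumulate(np.broadcast_to(g, (B, C, D // f, f, H // f, f, W // f, f)).reshape(B, C, D, H, W))

    out._backward = bw
    return out


def upsample_nearest3d(x: Tensor, factor: int = 2) -> Tensor:
    f = factor
    data = x.data.repeat(f, axis=2).repeat(f, axis=3).repeat(f, axis=4)
    out = Tensor(data, _parents=(x,))
    B, C, D, H, W = x.data.shape

    def bw(g):
        if x.requires_grad:
            g = g.reshape(B, C, D, f, H, f, W, f).sum(axis=(3, 5, 7))
            x._accumulate(g)

    out._backward = bw
    return out


def instance_norm3d(x: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize each (batch, channel) slice to zero mean / unit variance
    over its spatial extent.  Composed from differentiable primitives."""
    mu = x.mean(axis=(2, 3, 4), keepdims=True)
    d = x - mu
    var = (d * d).mean(axis=(2, 3, 4), keepdims=True)
    return d / (var + eps).sqrt()


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(p, _parents=(x,))

    def bw(g):
        if x.requires_grad:
            x._accumulate(p * (g - (g * p).sum(axis=axis, keepdims=True)))

    out._backward = bw
    return out


def cross_entropy_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer ``targets`` given (B, K) logits."""
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    B = logits.data.shape[0]
    loss = -logp[np.arange(B), targets].mean()
    out = Tensor(loss, _parents=(logits,))

    def bw(g):
        if logits.requires_grad:
            p = np.exp(logp)
            p[np.arange(B), targets] -= 1.0
            logits._accumulate(float(g) * p / B)

    out._backward = bw
    return out
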