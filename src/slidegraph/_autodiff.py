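"""Minimal reverse-mode automatic differentiation on numpy arrays.

Provides the `Tensor` class plus the differentiable primitives needed by the
patch encoder, the graph-convolution/pooling/transformer classifier and the
gradient-weighted attention maps: elementwise arithmetic with broadcasting,
matmul (including stacked/batched), reshape/transpose/slicing/concat,
reductions, relu/gelu/exp/log/sqrt, row softmax, layer normalisation and an
im2col primitive for small convolutions.

All gradients are checked against central finite differences in the test
suite. float64 throughout: desk-scale models are tiny, so exactness and
reproducibility win over speed.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["Tensor", "concat", "im2col"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "retains_grad")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward
        self.retains_grad = False

    # -- bookkeeping ------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def retain_grad(self):
        self.retains_grad = True
        return self

    def zero_grad(self):
        self.grad = None

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph construction helpers ---------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))

    def _make(self, data, parents, backward) -> "Tensor":
        req = any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req)
        if req:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- elementwise arithmetic -------------------------------------------

    def __add__(self, other):
        other = self._lift(other)

        def backward(g, out):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g, out: (-g,))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def backward(g, out):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)

        def backward(g, out):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return self._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, exponent: float):
        e = float(exponent)

        def backward(g, out):
            return (g * e * self.data ** (e - 1.0),)

        return self._make(self.data**e, (self,), backward)

    # -- linear algebra ----------------------------------------------------

    def __matmul__(self, other):
        other = self._lift(other)

        def backward(g, out):
            a, b = self.data, other.data
            if a.ndim == 1 and b.ndim == 1:
                ga, gb = g * b, g * a
            elif a.ndim == 1:
                ga = g @ np.swapaxes(b, -1, -2)
                gb = np.outer(a, g) if b.ndim == 2 else a[:, None] * g[..., None, :]
            elif b.ndim == 1:
                ga = g[..., None] * b
                gb = np.swapaxes(a, -1, -2) @ g
            else:
                ga = g @ np.swapaxes(b, -1, -2)
                gb = np.swapaxes(a, -1, -2) @ g
            return (_unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape))

        return self._make(self.data @ other.data, (self, other), backward)

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)

        def backward(g, out):
            return (g.transpose(inv),)

        return self._make(self.data.transpose(axes), (self,), backward)

    @property
    def T(self):
        return self.transpose()

    def swapaxes(self, a: int, b: int):
        axes = list(range(self.ndim))
        axes[a], axes[b] = axes[b], axes[a]
        return self.transpose(*axes)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def backward(g, out):
            return (g.reshape(old),)

        return self._make(self.data.reshape(shape), (self,), backward)

    def __getitem__(self, idx):
        def backward(g, out):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        return self._make(self.data[idx], (self,), backward)

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def backward(g, out):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.shape).copy(),)

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities ----------------------------------------------------

    def relu(self):
        mask = self.data > 0

        def backward(g, out):
            return (g * mask,)

        return self._make(self.data * mask, (self,), backward)

    def gelu(self):
        # tanh approximation of the Gaussian error linear unit
        c = math.sqrt(2.0 / math.pi)
        x = self.data
        inner = c * (x + 0.044715 * x**3)
        t = np.tanh(inner)

        def backward(g, out):
            dinner = c * (1.0 + 3 * 0.044715 * x**2)
            dydx = 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t**2) * dinner
            return (g * dydx,)

        return self._make(0.5 * x * (1.0 + t), (self,), backward)

    def exp(self):
        val = np.exp(self.data)

        def backward(g, out):
            return (g * val,)

        return self._make(val, (self,), backward)

    def log(self):
        def backward(g, out):
            return (g / self.data,)

        return self._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        val = np.sqrt(self.data)

        def backward(g, out):
            return (g * 0.5 / val,)

        return self._make(val, (self,), backward)

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)

        def backward(g, out):
            dot = (g * y).sum(axis=axis, keepdims=True)
            return (y * (g - dot),)

        return self._make(y, (self,), backward)

    def layer_norm(self, eps: float = 1e-5):
        """Normalise the last axis to zero mean / unit variance (no affine)."""
        x = self.data
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (x - mu) * inv
        n = x.shape[-1]

        def backward(g, out):
            gm = g.mean(axis=-1, keepdims=True)
            gxm = (g * xhat).mean(axis=-1, keepdims=True)
            return (inv * (g - gm - xhat * gxm),)

        return self._make(xhat, (self,), backward)

    # -- backprop ----------------------------------------------------------

    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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

        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None or node.retains_grad:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is not None:
                for parent, pg in zip(node._parents, node._backward(g, node)):
                    if not parent.requires_grad or pg is None:
                        continue
                    key = id(parent)
                    grads[key] = pg if key not in grads else grads[key] + pg


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    """Differentiable concatenation along `axis`."""
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g, out):
        return tuple(np.split(g, splits, axis=axis))

    data = np.concatenate([t.data for t in tensors], axis=axis)
    req = any(t.requires_grad for t in tensors)
    out = Tensor(data, requires_grad=req)
    if req:
        out._parents = tuple(tensors)
        out._backward = backward
    return out


def im2col(x: Tensor, kh: int, kw: int, stride: int = 1) -> Tensor:
    """Extract sliding (kh, kw) windows from an NCHW tensor.

    Returns shape (B, Ho*Wo, C*kh*kw), ready for a matmul with flattened
    convolution kernels. The backward pass scatter-adds window gradients
    back onto the input.
    """
    B, C, H, W = x.shape
    Ho = (H - kh) // stride + 1
    Wo = (W - kw) // stride + 1
    cols = np.empty((B, C, kh, kw, Ho, Wo), dtype=np.float64)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = x.data[:, :, i : i + stride * Ho : stride, j : j + stride * Wo : stride]
    out_data = cols.transpose(0, 4, 5, 1, 2, 3).reshape(B, Ho * Wo, C * kh * kw)

    def backward(g, out):
        gc = g.reshape(B, Ho, Wo, C, kh, kw).transpose(0, 3, 4, 5, 1, 2)
        gx = np.zeros((B, C, H, W), dtype=np.float64)
        for i in range(kh):
            for j in range(kw):
                gx[:, :, i : i + stride * Ho : stride, j : j + stride * Wo : stride] += gc[:, :, i, j]
        return (gx,)

    req = x.requires_grad
    out = Tensor(out_data, requires_grad=req)
    if req:
        out._parents = (x,)
        out._backward = backward
    return out
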