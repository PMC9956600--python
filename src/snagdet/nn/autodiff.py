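"""Minimal vectorized reverse-mode automatic differentiation over numpy.

The detector in this package (windowed attention backbone, balanced pyramid
neck, RPN and RoI heads) is trained end-to-end on CPU, so the engine favours
a small number of array-level primitives — matmul, softmax, reductions,
indexing — each with a hand-written vector-Jacobian product, over a large
scalar op set.  Graphs are built eagerly; ``Tensor.backward`` runs a
topological sweep accumulating gradients into ``.grad`` of every tensor with
``requires_grad``.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf as _erf

__all__ = ["Tensor", "concat", "stack", "where"]

_SQRT2 = np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple = ()

    # ---- construction helpers -------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    # ---- introspection ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # ---- arithmetic ------------------------------------------------------
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

    def __pow__(self, p: float):
        assert np.isscalar(p)

        def backward(g, out):
            return (g * p * self.data ** (p - 1),)

        return self._make(self.data**p, (self,), backward)

    def __matmul__(self, other):
        other = self._lift(other)

        def backward(g, out):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            return (_unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape))

        return self._make(self.data @ other.data, (self, other), backward)

    # ---- elementwise functions ------------------------------------------
    def exp(self):
        def backward(g, out):
            return (g * out.data,)

        return self._make(np.exp(self.data), (self,), backward)

    def log(self):
        def backward(g, out):
            return (g / self.data,)

        return self._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        def backward(g, out):
            return (g * 0.5 / out.data,)

        return self._make(np.sqrt(self.data), (self,), backward)

    def abs(self):
        def backward(g, out):
            return (g * np.sign(self.data),)

        return self._make(np.abs(self.data), (self,), backward)

    def relu(self):
        def backward(g, out):
            return (g * (self.data > 0),)

        return self._make(np.maximum(self.data, 0.0), (self,), backward)

    def gelu(self):
        """Exact GELU x·Φ(x) with the analytic derivative Φ(x) + x·φ(x)."""
        x = self.data
        cdf = 0.5 * (1.0 + _erf(x / _SQRT2))

        def backward(g, out):
            pdf = _INV_SQRT_2PI * np.exp(-0.5 * x * x)
            return (g * (cdf + x * pdf),)

        return self._make(x * cdf, (self,), backward)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g, out):
            return (g * s * (1.0 - s),)

        return self._make(s, (self,), backward)

    # ---- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def backward(g, out):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            ax = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                g = np.expand_dims(g, ax)
            return (np.broadcast_to(g, self.shape).copy(),)

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        """Maximum along one axis; gradient flows to the (first) argmax."""
        idx = np.argmax(self.data, axis=axis)
        out_data = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis)
        if not keepdims:
            out_data = np.squeeze(out_data, axis)

        def backward(g, out):
            gi = np.zeros_like(self.data)
            ge = g if keepdims else np.expand_dims(g, axis)
            np.put_along_axis(gi, np.expand_dims(idx, axis), ge, axis)
            return (gi,)

        return self._make(out_data, (self,), backward)

    # ---- softmax family --------------------------------------------------
    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)

        def backward(g, out):
            return (s * (g - (g * s).sum(axis=axis, keepdims=True)),)

        return self._make(s, (self,), backward)

    def log_softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        ls = z - lse

        def backward(g, out):
            return (g - np.exp(ls) * g.sum(axis=axis, keepdims=True),)

        return self._make(ls, (self,), backward)

    # ---- shape ops -------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def backward(g, out):
            return (g.reshape(self.shape),)

        return self._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g, out):
            return (g.transpose(inv),)

        return self._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, key):
        def backward(g, out):
            gi = np.zeros_like(self.data)
            np.add.at(gi, key, g)
            return (gi,)

        return self._make(self.data[key], (self,), backward)

    def roll(self, shift, axis):
        def backward(g, out):
            neg = tuple(-s for s in shift) if isinstance(shift, tuple) else -shift
            return (np.roll(g, neg, axis=axis),)

        return self._make(np.roll(self.data, shift, axis=axis), (self,), backward)

    def pad(self, pad_width):
        """Zero padding; ``pad_width`` as for ``np.pad``."""
        sl = tuple(slice(b, s + b) for (b, _a), s in zip(pad_width, self.shape))

        def backward(g, out):
            return (g[sl],)

        return self._make(np.pad(self.data, pad_width), (self,), backward)

    # ---- autodiff driver -------------------------------------------------
    def backward(self):
        assert self.size == 1, "backward() needs a scalar loss"
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited or not node.requires_grad:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                stack.append((p, False))

        grads: dict[int, np.ndarray] = {id(self): np.ones_like(self.data)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is not None:
                for parent, pg in zip(node._prev, node._backward(g, node)):
                    if not parent.requires_grad or pg is None:
                        continue
                    if id(parent) in grads:
                        grads[id(parent)] = grads[id(parent)] + pg
                    else:
                        grads[id(parent)] = pg
            else:  # leaf (parameter or input marked requires_grad)
                node.grad = g if node.grad is None else node.grad + g


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offs = np.cumsum([0] + sizes)

    def backward(g, out):
        return tuple(
            np.take(g, np.arange(offs[i], offs[i + 1]), axis=axis)
            for i in range(len(tensors))
        )

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, backward
    )


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]

    def backward(g, out):
        moved = np.moveaxis(g, axis, 0)
        return tuple(moved[i] for i in range(len(tensors)))

    return Tensor._make(np.stack([t.data for t in tensors], axis=axis), tensors, backward)


def where(cond: np.ndarray, a, b) -> Tensor:
    """Elementwise select with a *constant* boolean condition."""
    a, b = Tensor._lift(a), Tensor._lift(b)

    def backward(g, out):
        return (
            _unbroadcast(np.where(cond, g, 0.0), a.shape),
            _unbroadcast(np.where(cond, 0.0, g), b.shape),
        )

    return Tensor._make(np.where(cond, a.data, b.data), (a, b), backward)
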