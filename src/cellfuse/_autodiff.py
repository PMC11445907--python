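"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operations the fusion trainer needs: affine maps,
ReLU, row-softmax, elementwise exp/log/sqrt, sums, concatenation and a
clamped floor.  A :class:`Tensor` wraps an ndarray; calling
:meth:`Tensor.backward` on a scalar result accumulates gradients into
every reachable tensor with ``requires_grad=True``.  Gradients are
checked against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "softmax_rows", "relu", "exp", "log", "sqrt", "clamp_min", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum a gradient over the axes that NumPy broadcasting expanded."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def _wrap(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=float)
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self.grad = None
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- graph traversal ---------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        ordered, seen = [], set()
        stack = [(self, False)]
        while stack:
            node, children_done = stack.pop()
            if children_done:
                ordered.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(ordered):
            if node._backward is None or node.grad is None:
                continue
            for parent, g in zip(node._parents, node._backward(node.grad)):
                if parent.requires_grad and g is not None:
                    parent.grad = g if parent.grad is None else parent.grad + g

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        a, b = self, _wrap(other)
        out = Tensor(a.data + b.data, parents=(a, b))
        out._backward = lambda g: (_unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape))
        return out

    __radd__ = __add__

    def __sub__(self, other):
        a, b = self, _wrap(other)
        out = Tensor(a.data - b.data, parents=(a, b))
        out._backward = lambda g: (_unbroadcast(g, a.data.shape), _unbroadcast(-g, b.data.shape))
        return out

    def __rsub__(self, other):
        return _wrap(other) - self

    def __mul__(self, other):
        a, b = self, _wrap(other)
        out = Tensor(a.data * b.data, parents=(a, b))
        out._backward = lambda g: (
            _unbroadcast(g * b.data, a.data.shape),
            _unbroadcast(g * a.data, b.data.shape),
        )
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        a, b = self, _wrap(other)
        out = Tensor(a.data / b.data, parents=(a, b))
        out._backward = lambda g: (
            _unbroadcast(g / b.data, a.data.shape),
            _unbroadcast(-g * a.data / (b.data**2), b.data.shape),
        )
        return out

    def __rtruediv__(self, other):
        return _wrap(other) / self

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: (-g,)
        return out

    def __matmul__(self, other):
        a, b = self, _wrap(other)
        out = Tensor(a.data @ b.data, parents=(a, b))
        out._backward = lambda g: (g @ b.data.T, a.data.T @ g)
        return out

    @property
    def T(self) -> "Tensor":
        out = Tensor(self.data.T, parents=(self,))
        out._backward = lambda g: (g.T,)
        return out

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        src = self
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def back(g):
            if axis is None:
                return (np.broadcast_to(g, src.data.shape).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, src.data.shape).copy(),)

        out._backward = back
        return out

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)


# -- elementwise functions -------------------------------------------------


def relu(x: Tensor) -> Tensor:
    x = _wrap(x)
    out = Tensor(np.maximum(x.data, 0.0), parents=(x,))
    out._backward = lambda g: (g * (x.data > 0),)
    return out


def exp(x: Tensor) -> Tensor:
    x = _wrap(x)
    out = Tensor(np.exp(x.data), parents=(x,))
    out._backward = lambda g: (g * out.data,)
    return out


def log(x: Tensor) -> Tensor:
    x = _wrap(x)
    out = Tensor(np.log(x.data), parents=(x,))
    out._backward = lambda g: (g / x.data,)
    return out


def sqrt(x: Tensor) -> Tensor:
    x = _wrap(x)
    out = Tensor(np.sqrt(x.data), parents=(x,))
    out._backward = lambda g: (g * 0.5 / np.maximum(out.data, 1e-300),)
    return out


def clamp_min(x: Tensor, floor: float) -> Tensor:
    """max(x, floor); the gradient passes only where x > floor."""
    x = _wrap(x)
    out = Tensor(np.maximum(x.data, floor), parents=(x,))
    out._backward = lambda g: (g * (x.data > floor),)
    return out


def softmax_rows(x: Tensor) -> Tensor:
    """Numerically stable softmax along the last axis."""
    x = _wrap(x)
    shifted = x.data - x.data.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    y = e / e.sum(axis=-1, keepdims=True)
    out = Tensor(y, parents=(x,))
    out._backward = lambda g: (y * (g - (g * y).sum(axis=-1, keepdims=True)),)
    return out


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        return tuple(np.split(g, splits, axis=axis))

    out._backward = back
    return out


# -- optimizer ---------------------------------------------------------------


class Adam:
    """Adam with optional global gradient-norm clipping."""

    def __init__(self, params, lr: float = 5e-4, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8, clip_norm: float = 5.0):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        grads = [p.grad if p.grad is not None else np.zeros_like(p.data) for p in self.params]
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((g * g).sum()) for g in grads))
            if total > self.clip_norm:
                grads = [g * (self.clip_norm / total) for g in grads]
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
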