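"""A small reverse-mode automatic-differentiation engine over numpy arrays.

This is the numerical core used to train the denoising network: a tape of
`Tensor` nodes recording elementwise arithmetic (with broadcasting), matrix
products, reductions, row gathering / segment summation (the two primitives
graph message passing needs), and the smooth nonlinearities used by the
layers.  Gradients propagate by topological traversal of the tape.

The engine is deliberately minimal — float64 only, no views, no in-place
mutation of tracked arrays — which keeps every backward rule a few lines and
easy to audit against finite differences (see the unit tests).
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = ["Tensor", "concat", "gather_rows", "segment_sum", "bmm", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, inverting numpy broadcasting."""
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
    """A node in the autodiff tape wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")
    __array_priority__ = 100  # numpy defers binary ops to Tensor

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _node(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- elementwise arithmetic ----------------------------------------------
    def __add__(self, other):
        other = Tensor._lift(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return Tensor._node(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._node(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out_data = self.data * other.data

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return Tensor._node(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        out_data = self.data / other.data

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return Tensor._node(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, p: float):
        out_data = self.data**p

        def backward(g):
            return (g * p * self.data ** (p - 1),)

        return Tensor._node(out_data, (self,), backward)

    def __matmul__(self, other):
        other = Tensor._lift(other)
        out_data = self.data @ other.data

        def backward(g):
            return (g @ other.data.T, self.data.T @ g)

        return Tensor._node(out_data, (self, other), backward)

    # -- nonlinearities --------------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._node(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return Tensor._node(np.log(self.data), (self,), lambda g: (g / self.data,))

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return Tensor._node(out_data, (self,), lambda g: (g * 0.5 / out_data,))

    def tanh(self):
        out_data = np.tanh(self.data)
        return Tensor._node(out_data, (self,), lambda g: (g * (1 - out_data**2),))

    def sigmoid(self):
        out_data = expit(self.data)  # overflow-safe logistic
        return Tensor._node(
            out_data, (self,), lambda g: (g * out_data * (1 - out_data),)
        )

    def silu(self):
        s = expit(self.data)
        out_data = self.data * s

        def backward(g):
            return (g * (s * (1 + self.data * (1 - s))),)

        return Tensor._node(out_data, (self,), backward)

    # -- reductions and shaping -----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        return Tensor._node(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out_data = self.data.reshape(*shape)
        return Tensor._node(out_data, (self,), lambda g: (g.reshape(self.shape),))

    # -- autodiff driver --------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: tapes can exceed the recursion limit
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

        for node in topo:
            node.grad = np.zeros_like(node.data)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if parent.requires_grad:
                    if parent.grad is None:
                        parent.grad = np.zeros_like(parent.data)
                    parent.grad = parent.grad + g


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._node(out_data, tuple(tensors), backward)


def bmm(a: Tensor, b) -> Tensor:
    """Batched matrix product (B, n, k) @ (B, k, m) -> (B, n, m).

    Leading batch dimensions broadcast as in numpy matmul; gradients are
    summed back down to each operand's shape.
    """
    a = Tensor._lift(a)
    b = Tensor._lift(b)
    out_data = a.data @ b.data

    def backward(g):
        return (
            _unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.shape),
            _unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.shape),
        )

    return Tensor._node(out_data, (a, b), backward)


def gather_rows(x: Tensor, idx: np.ndarray) -> Tensor:
    """Select rows x[idx]; the backward pass scatter-adds into the source."""
    idx = np.asarray(idx)
    out_data = x.data[idx]

    def backward(g):
        gx = np.zeros_like(x.data)
        np.add.at(gx, idx, g)
        return (gx,)

    return Tensor._node(out_data, (x,), backward)


def segment_sum(x: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of x into `num_segments` buckets (message aggregation)."""
    segment_ids = np.asarray(segment_ids)
    out_data = np.zeros((num_segments,) + x.data.shape[1:])
    np.add.at(out_data, segment_ids, x.data)

    def backward(g):
        return (g[segment_ids],)

    return Tensor._node(out_data, (x,), backward)


class Adam:
    """Adam optimizer over a flat list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
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
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            m_hat = self.m[i] / (1 - self.b1**self.t)
            v_hat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
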