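"""Minimal reverse-mode automatic differentiation over numpy arrays.

Internal engine backing the graph encoder's training loop.  It implements
exactly the primitives the model needs (dense matmul, broadcasting
elementwise arithmetic, relu/exp/log/sigmoid/softplus, axis reductions,
concatenation, row gathering) with a topologically ordered backward pass and
an Adam optimizer.  Shapes stay small (full-graph training on a few thousand
nodes), so everything is dense float64.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a gradient back to the shape of a broadcast operand."""
    grad = np.asarray(grad)
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, value, requires_grad: bool = False, parents=(), backward=None):
        self.value = np.asarray(value, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    # -- graph plumbing ----------------------------------------------------
    @property
    def shape(self):
        return self.value.shape

    def backward(self) -> None:
        """Accumulate gradients of this (scalar) tensor w.r.t. all parents."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if id(node) in seen:
                continue
            if expanded:
                seen.add(id(node))
                topo.append(node)
            else:
                stack.append((node, True))
                for p in node._parents:
                    if id(p) not in seen and p.requires_grad:
                        stack.append((p, False))
        self.grad = np.ones_like(self.value)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.value)
        self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.value + other.value, parents=(self, other))

        def bw(g):
            self._accum(_unbroadcast(g, self.value.shape))
            other._accum(_unbroadcast(g, other.value.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.value, parents=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.value * other.value, parents=(self, other))

        def bw(g):
            self._accum(_unbroadcast(g * other.value, self.value.shape))
            other._accum(_unbroadcast(g * self.value, other.value.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.value / other.value, parents=(self, other))

        def bw(g):
            self._accum(_unbroadcast(g / other.value, self.value.shape))
            other._accum(
                _unbroadcast(-g * self.value / other.value**2, other.value.shape)
            )

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.value @ other.value, parents=(self, other))

        def bw(g):
            self._accum(g @ other.value.T)
            other._accum(self.value.T @ g)

        out._backward = bw
        return out

    @property
    def T(self):
        out = Tensor(self.value.T, parents=(self,))
        out._backward = lambda g: self._accum(g.T)
        return out

    def __getitem__(self, idx):
        out = Tensor(self.value[idx], parents=(self,))

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.value)
                np.add.at(full, idx, g)
                self._accum(full)

        out._backward = bw
        return out

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.value.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.value.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.value.size if axis is None else self.value.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- elementwise nonlinearities --------------------------------------------

def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.value, 0.0), parents=(x,))
    out._backward = lambda g: x._accum(g * (x.value > 0))
    return out


def exp(x: Tensor) -> Tensor:
    out = Tensor(np.exp(x.value), parents=(x,))
    out._backward = lambda g: x._accum(g * out.value)
    return out


def log(x: Tensor) -> Tensor:
    out = Tensor(np.log(x.value), parents=(x,))
    out._backward = lambda g: x._accum(g / x.value)
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.value, -500, 500)))
    out = Tensor(s, parents=(x,))
    out._backward = lambda g: x._accum(g * s * (1.0 - s))
    return out


def softplus(x: Tensor) -> Tensor:
    """log(1 + exp(x)), computed stably."""
    out = Tensor(np.logaddexp(0.0, x.value), parents=(x,))
    out._backward = lambda g: x._accum(g / (1.0 + np.exp(-x.value)))
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Row-stochastic softmax; the detached max shift keeps it stable."""
    shifted = x - x.value.max(axis=axis, keepdims=True)
    e = exp(shifted)
    return e / e.sum(axis=axis, keepdims=True)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    values = [t.value for t in tensors]
    out = Tensor(np.concatenate(values, axis=axis), parents=tuple(tensors))
    sizes = [v.shape[axis] for v in values]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    out._backward = bw
    return out


def binary_cross_entropy_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """mean(softplus(z) - y*z): the numerically stable BCE on raw scores."""
    y = np.asarray(targets, dtype=float)
    return (softplus(logits) - as_tensor(y) * logits).mean()


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
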