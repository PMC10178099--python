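"""Minimal vectorized reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the pyramid-attention forecaster needs:
broadcast-aware arithmetic, batched matrix multiplication, transpose /
reshape / concatenation / fancy gather along an axis, ReLU, tanh, masked
softmax, reductions and a layer-norm building block.  Gradients are checked
against central finite differences in the test suite.

The engine is deliberately small: a :class:`Tensor` wraps an ``ndarray``,
records its parents and a backward closure, and :meth:`Tensor.backward`
runs a topological sweep.  There is no graph reuse, no in-place mutation
and no dtype promotion cleverness — float64 throughout.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np

Array = np.ndarray


def _unbroadcast(grad: Array, shape: tuple[int, ...]) -> Array:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Array | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[Array], Iterable[Array | None]] | None = None

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    # -- graph plumbing ----------------------------------------------------
    @staticmethod
    def _make(data: Array, parents: tuple["Tensor", ...], backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    def backward(self, grad: Array | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(node: Tensor) -> None:
            if id(node) in seen or not node.requires_grad:
                return
            seen.add(id(node))
            for parent in node._parents:
                visit(parent)
            topo.append(node)

        visit(self)
        grads: dict[int, Array] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if pg is None or not parent.requires_grad:
                    continue
                key = id(parent)
                grads[key] = pg if key not in grads else grads[key] + pg

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._wrap(other)
        return Tensor._make(
            self.data + other.data,
            (self, other),
            lambda g: (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape)),
        )

    __radd__ = __add__

    def __sub__(self, other):
        other = self._wrap(other)
        return Tensor._make(
            self.data - other.data,
            (self, other),
            lambda g: (_unbroadcast(g, self.shape), _unbroadcast(-g, other.shape)),
        )

    def __rsub__(self, other):
        return self._wrap(other) - self

    def __mul__(self, other):
        other = self._wrap(other)
        return Tensor._make(
            self.data * other.data,
            (self, other),
            lambda g: (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        return Tensor._make(
            self.data / other.data,
            (self, other),
            lambda g: (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            ),
        )

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __matmul__(self, other):
        other = self._wrap(other)
        out = self.data @ other.data

        def backward(g: Array):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            return _unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape)

        return Tensor._make(out, (self, other), backward)

    def __pow__(self, exponent: float):
        return Tensor._make(
            self.data**exponent,
            (self,),
            lambda g: (g * exponent * self.data ** (exponent - 1),),
        )

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape: int):
        old = self.shape
        return Tensor._make(self.data.reshape(*shape), (self,), lambda g: (g.reshape(old),))

    def transpose(self, *axes: int):
        inverse = tuple(np.argsort(axes))
        return Tensor._make(
            self.data.transpose(*axes), (self,), lambda g: (g.transpose(*inverse),)
        )

    def gather(self, indices, axis: int):
        """Take ``indices`` along ``axis`` (backward scatter-adds)."""
        idx = np.asarray(indices)
        out = np.take(self.data, idx, axis=axis)
        shape = self.shape

        def backward(g: Array):
            full = np.zeros(shape, dtype=np.float64)
            moved = np.moveaxis(full, axis, 0)
            np.add.at(moved, idx, np.moveaxis(g, axis, 0))
            return (full,)

        return Tensor._make(out, (self,), backward)

    @staticmethod
    def concat(tensors: list["Tensor"], axis: int) -> "Tensor":
        sizes = [t.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def backward(g: Array):
            return tuple(np.split(g, splits, axis=axis))

        return Tensor._make(
            np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward
        )

    # -- nonlinearities and reductions --------------------------------------
    def relu(self):
        mask = self.data > 0
        return Tensor._make(self.data * mask, (self,), lambda g: (g * mask,))

    def tanh(self):
        out = np.tanh(self.data)
        return Tensor._make(out, (self,), lambda g: (g * (1 - out**2),))

    def sum(self, axis=None, keepdims: bool = False):
        shape = self.shape

        def backward(g: Array):
            if axis is None:
                return (np.broadcast_to(g, shape).copy(),)
            g_exp = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g_exp, shape).copy(),)

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def masked_softmax(self, mask: Array, axis: int = -1):
        """Softmax along ``axis`` with disallowed positions (mask False) forced
        to exactly zero weight: their scores are replaced by -inf before the
        exponential, so masked values cannot leak into any output."""
        scores = np.where(mask, self.data, -np.inf)
        shifted = scores - scores.max(axis=axis, keepdims=True)
        exp = np.exp(shifted)
        out = exp / exp.sum(axis=axis, keepdims=True)

        def backward(g: Array):
            inner = (g * out).sum(axis=axis, keepdims=True)
            return ((g - inner) * out,)

        return Tensor._make(out, (self,), backward)

    def layer_norm(self, eps: float = 1e-5):
        """Normalize the last axis to zero mean and unit variance."""
        mu = self.data.mean(axis=-1, keepdims=True)
        centered = self.data - mu
        var = (centered**2).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        out = centered * inv
        n = self.data.shape[-1]

        def backward(g: Array):
            g_mean = g.mean(axis=-1, keepdims=True)
            proj = (g * out).mean(axis=-1, keepdims=True)
            return ((g - g_mean - out * proj) * inv,)

        return Tensor._make(out, (self,), backward)


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g**2
            m_hat = self.m[i] / (1 - self.beta1**self.t)
            v_hat = self.v[i] / (1 - self.beta2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


__all__ = ["Adam", "Tensor"]
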