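"""Minimal reverse-mode automatic differentiation on NumPy arrays.

This is the package's compute core: a tape-based :class:`Tensor` supporting
the handful of differentiable operations the repair networks need (broadcasted
arithmetic, batched matmul, reductions, softmax, GELU/ReLU/tanh, reshape and
basic slicing). Gradients flow through ``Tensor.backward()`` on a scalar loss.

The operation set is deliberately small and every gradient is exercised by
finite-difference checks in the test suite; this is not a general deep
learning framework.
"""

from __future__ import annotations

from typing import Callable, Iterable, Optional

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape``, undoing NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # collapse extra leading axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # collapse broadcast (size-1) axes
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")
    __array_priority__ = 100  # keep numpy from hijacking reflected ops

    def __init__(self, data, requires_grad: bool = False,
                 _parents: tuple = (),
                 _backward: Optional[Callable[[np.ndarray], None]] = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._parents = _parents
        self._backward = _backward

    # -- plumbing ------------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accumulate(self, g: np.ndarray) -> None:
        g = _unbroadcast(np.asarray(g, dtype=np.float64), self.data.shape)
        self.grad = g if self.grad is None else self.grad + g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: "Tensor") -> None:
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- arithmetic ----------------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data + other.data,
                     requires_grad=self.requires_grad or other.requires_grad,
                     _parents=(self, other))
        def _bw(g):
            self._accumulate(g)
            other._accumulate(g)
        out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, requires_grad=self.requires_grad,
                     _parents=(self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-self._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return self._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data * other.data,
                     requires_grad=self.requires_grad or other.requires_grad,
                     _parents=(self, other))
        def _bw(g):
            self._accumulate(g * other.data)
            other._accumulate(g * self.data)
        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = self._lift(other)
        return self * other ** -1.0

    def __rtruediv__(self, other) -> "Tensor":
        return self._lift(other) * self ** -1.0

    def __pow__(self, exponent: float) -> "Tensor":
        out = Tensor(self.data ** exponent, requires_grad=self.requires_grad,
                     _parents=(self,))
        out._backward = lambda g: self._accumulate(
            g * exponent * self.data ** (exponent - 1.0)
        )
        return out

    def __matmul__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(np.matmul(self.data, other.data),
                     requires_grad=self.requires_grad or other.requires_grad,
                     _parents=(self, other))
        def _bw(g):
            self._accumulate(np.matmul(g, other.data.swapaxes(-1, -2)))
            other._accumulate(np.matmul(self.data.swapaxes(-1, -2), g))
        out._backward = _bw
        return out

    # -- shape ops -----------------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape),
                     requires_grad=self.requires_grad, _parents=(self,))
        out._backward = lambda g: self._accumulate(g.reshape(self.data.shape))
        return out

    def swapaxes(self, a: int, b: int) -> "Tensor":
        out = Tensor(self.data.swapaxes(a, b),
                     requires_grad=self.requires_grad, _parents=(self,))
        out._backward = lambda g: self._accumulate(g.swapaxes(a, b))
        return out

    def __getitem__(self, key) -> "Tensor":
        out = Tensor(self.data[key], requires_grad=self.requires_grad,
                     _parents=(self,))
        def _bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            self._accumulate(full)
        out._backward = _bw
        return out

    # -- reductions ----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     requires_grad=self.requires_grad, _parents=(self,))
        def _bw(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape))
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.data.shape))
        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities ------------------------------------------------------

    def exp(self) -> "Tensor":
        y = np.exp(self.data)
        out = Tensor(y, requires_grad=self.requires_grad, _parents=(self,))
        out._backward = lambda g: self._accumulate(g * y)
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), requires_grad=self.requires_grad,
                     _parents=(self,))
        out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def tanh(self) -> "Tensor":
        y = np.tanh(self.data)
        out = Tensor(y, requires_grad=self.requires_grad, _parents=(self,))
        out._backward = lambda g: self._accumulate(g * (1.0 - y * y))
        return out

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0),
                     requires_grad=self.requires_grad, _parents=(self,))
        out._backward = lambda g: self._accumulate(g * (self.data > 0))
        return out

    def gelu(self) -> "Tensor":
        """Exact Gaussian-error GELU: x * Phi(x)."""
        from scipy.special import erf
        cdf = 0.5 * (1.0 + erf(self.data / np.sqrt(2.0)))
        pdf = np.exp(-0.5 * self.data ** 2) / np.sqrt(2.0 * np.pi)
        out = Tensor(self.data * cdf, requires_grad=self.requires_grad,
                     _parents=(self,))
        out._backward = lambda g: self._accumulate(
            g * (cdf + self.data * pdf)
        )
        return out

    def softmax(self, axis: int = -1) -> "Tensor":
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(y, requires_grad=self.requires_grad, _parents=(self,))
        out._backward = lambda g: self._accumulate(
            y * (g - (g * y).sum(axis=axis, keepdims=True))
        )
        return out


def parameter(data: np.ndarray) -> Tensor:
    """A learnable tensor (gradient-tracked leaf)."""
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=True)


def zero_grads(params: Iterable[Tensor]) -> None:
    for p in params:
        p.grad = None


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 2e-4,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
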