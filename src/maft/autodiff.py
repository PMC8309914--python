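"""Compact reverse-mode automatic differentiation on NumPy arrays.

The encoder models in this package are small (a few hundred thousand
parameters at most, toy configurations far below that), so a minimal
define-by-run tape over float64 NumPy arrays is sufficient and keeps the
dependency footprint to the scientific-Python base stack.  The engine
supports exactly the operations the transformer, the task heads and the
training losses need: broadcast arithmetic, (batched) matmul, reductions,
relu/exp/log/power, and constant masking for dropout.

Gradients of broadcast operations are un-broadcast by summing over the
expanded axes, so parameters of any shape can enter batched expressions
directly.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array with an attached gradient tape node."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers ------------------------------------------------

    @staticmethod
    def _result(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic ----------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)

        def backward(g, out):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return Tensor._result(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        return Tensor._result(-self.data, (self,), lambda g, out: (-g,))

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)

        def backward(g, out):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return Tensor._result(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        return self * as_tensor(other) ** -1.0

    def __rtruediv__(self, other) -> "Tensor":
        return as_tensor(other) * self ** -1.0

    def __pow__(self, exponent: float) -> "Tensor":
        exponent = float(exponent)
        data = self.data ** exponent

        def backward(g, out):
            return (g * exponent * self.data ** (exponent - 1.0),)

        return Tensor._result(data, (self,), backward)

    def __matmul__(self, other) -> "Tensor":
        other = as_tensor(other)

        def backward(g, out):
            a, b = self.data, other.data
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            return (_unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape))

        return Tensor._result(self.data @ other.data, (self, other), backward)

    # -- shape ops -----------------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        shape = shape[0] if len(shape) == 1 and isinstance(shape[0], tuple) else shape
        orig = self.shape
        return Tensor._result(
            self.data.reshape(shape), (self,), lambda g, out: (g.reshape(orig),)
        )

    def transpose(self, *axes) -> "Tensor":
        axes = axes[0] if len(axes) == 1 and isinstance(axes[0], tuple) else axes
        inv = tuple(np.argsort(axes))
        return Tensor._result(
            self.data.transpose(axes), (self,), lambda g, out: (g.transpose(inv),)
        )

    # -- reductions ----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def backward(g, out):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            return (np.broadcast_to(gg, self.shape).copy(),)

        return Tensor._result(
            self.data.sum(axis=axis, keepdims=keepdims), (self,), backward
        )

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities ------------------------------------------------------

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def backward(g, out):
            return (g * mask,)

        return Tensor._result(np.where(mask, self.data, 0.0), (self,), backward)

    def exp(self) -> "Tensor":
        data = np.exp(self.data)
        return Tensor._result(data, (self,), lambda g, out: (g * out.data,))

    def log(self) -> "Tensor":
        return Tensor._result(
            np.log(self.data), (self,), lambda g, out: (g / self.data,)
        )

    # -- composites ----------------------------------------------------------

    def softmax(self, axis: int = -1) -> "Tensor":
        # max-shift is a constant under differentiation
        shift = Tensor(self.data.max(axis=axis, keepdims=True))
        e = (self - shift).exp()
        return e / e.sum(axis=axis, keepdims=True)

    def logsumexp(self, axis: int = -1) -> "Tensor":
        shift = Tensor(self.data.max(axis=axis, keepdims=True))
        return (self - shift).exp().sum(axis=axis, keepdims=True).log() + shift

    # -- backward pass -------------------------------------------------------

    def backward(self, grad=None) -> None:
        """Accumulate gradients of ``self`` into every reachable leaf."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._backward(g, node)):
                if not parent.requires_grad:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


class Adam:
    """Adam optimizer with the canonical defaults (beta1 0.9, beta2 0.999)."""

    def __init__(self, params: list[Tensor], lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self._m[i] = b1 * self._m[i] + (1 - b1) * p.grad
            self._v[i] = b2 * self._v[i] + (1 - b2) * p.grad ** 2
            m_hat = self._m[i] / (1 - b1 ** self.t)
            v_hat = self._v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
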