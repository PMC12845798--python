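"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small tape-based engine: each operation returns a new
:class:`Tensor` holding references to its parents and a closure that
propagates the upstream gradient.  ``Tensor.backward()`` runs a topological
sweep.  Only the operations needed by the temporal-fusion network are
implemented (broadcast arithmetic, matmul, the usual activations, softmax,
axis reductions, slicing/reshaping/concatenation).

Float64 throughout: the network is small and exact agreement with
brute-force oracles matters more here than raw speed.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = ["Tensor", "concat", "maximum"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    # -- housekeeping ------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _accumulate(self, g: np.ndarray) -> None:
        # copy on first write: g may be a view of (or alias) another grad
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64)
            if self.grad.shape != self.data.shape:
                self.grad = np.broadcast_to(self.grad, self.data.shape).copy()
        else:
            self.grad += g

    def _accumulate_slice(self, idx, g: np.ndarray) -> None:
        """In-place accumulation into a basic slice of the gradient buffer
        (allocates the buffer once; cheap for per-timestep slicing)."""
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad[idx] += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
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
                if isinstance(p, Tensor) and p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = Tensor.as_tensor(other)
        req = self.requires_grad or other.requires_grad
        out = Tensor(self.data + other.data, req, (self, other))

        def _bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))
        out._backward = _bwd
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, self.requires_grad, (self,))

        def _bwd(g):
            if self.requires_grad:
                self._accumulate(-g)
        out._backward = _bwd
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = Tensor.as_tensor(other)
        req = self.requires_grad or other.requires_grad
        out = Tensor(self.data * other.data, req, (self, other))

        def _bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))
        out._backward = _bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        if isinstance(other, Tensor):
            return self * other ** -1.0
        return self * (1.0 / other)

    def __pow__(self, exponent: float) -> "Tensor":
        out = Tensor(self.data ** exponent, self.requires_grad, (self,))

        def _bwd(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1.0))
        out._backward = _bwd
        return out

    def __matmul__(self, other) -> "Tensor":
        other = Tensor.as_tensor(other)
        req = self.requires_grad or other.requires_grad
        out = Tensor(self.data @ other.data, req, (self, other))

        def _bwd(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.shape))
        out._backward = _bwd
        return out

    # -- activations -------------------------------------------------------
    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, self.requires_grad, (self,))

        def _bwd(g):
            if self.requires_grad:
                self._accumulate(g * s * (1.0 - s))
        out._backward = _bwd
        return out

    def tanh(self) -> "Tensor":
        t = np.tanh(self.data)
        out = Tensor(t, self.requires_grad, (self,))

        def _bwd(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - t * t))
        out._backward = _bwd
        return out

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), self.requires_grad, (self,))

        def _bwd(g):
            if self.requires_grad:
                self._accumulate(g * (self.data > 0.0))
        out._backward = _bwd
        return out

    def exp(self) -> "Tensor":
        e = np.exp(self.data)
        out = Tensor(e, self.requires_grad, (self,))

        def _bwd(g):
            if self.requires_grad:
                self._accumulate(g * e)
        out._backward = _bwd
        return out

    def softmax(self, axis: int = -1) -> "Tensor":
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(s, self.requires_grad, (self,))

        def _bwd(g):
            if self.requires_grad:
                # d/dx softmax: s * (g - sum(g*s))
                dot = (g * s).sum(axis=axis, keepdims=True)
                self._accumulate(s * (g - dot))
        out._backward = _bwd
        return out

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))

        def _bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accumulate(np.broadcast_to(gg, self.shape).copy())
        out._backward = _bwd
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False) -> "Tensor":
        m = self.data.max(axis=axis, keepdims=True)
        out_data = m if keepdims else np.squeeze(m, axis=axis)
        out = Tensor(out_data, self.requires_grad, (self,))

        def _bwd(g):
            if not self.requires_grad:
                return
            gg = g if keepdims else np.expand_dims(g, axis)
            mask = self.data == m
            # split gradient across exact ties (measure-zero for float data)
            mask = mask / mask.sum(axis=axis, keepdims=True)
            self._accumulate(mask * gg)
        out._backward = _bwd
        return out

    # -- shape manipulation ------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))

        def _bwd(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.shape))
        out._backward = _bwd
        return out

    def swapaxes(self, a: int, b: int) -> "Tensor":
        out = Tensor(np.swapaxes(self.data, a, b), self.requires_grad, (self,))

        def _bwd(g):
            if self.requires_grad:
                self._accumulate(np.swapaxes(g, a, b))
        out._backward = _bwd
        return out

    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(self.data[idx], self.requires_grad, (self,))

        def _bwd(g):
            if self.requires_grad:
                self._accumulate_slice(idx, g)
        out._backward = _bwd
        return out

    def pad_axis(self, axis: int, left: int, right: int = 0) -> "Tensor":
        """Zero-pad along one axis (used for causal convolution)."""
        pads = [(0, 0)] * self.ndim
        pads[axis] = (left, right)
        out = Tensor(np.pad(self.data, pads), self.requires_grad, (self,))

        def _bwd(g):
            if self.requires_grad:
                sl = [slice(None)] * self.ndim
                sl[axis] = slice(left, left + self.shape[axis])
                self._accumulate(g[tuple(sl)])
        out._backward = _bwd
        return out

    def detach(self) -> "Tensor":
        return Tensor(self.data)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor.as_tensor(t) for t in tensors]
    req = any(t.requires_grad for t in tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 req, tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(int(lo), int(hi))
                t._accumulate(g[tuple(sl)])
    out._backward = _bwd
    return out


def maximum(a: Tensor, b: Tensor) -> Tensor:
    a, b = Tensor.as_tensor(a), Tensor.as_tensor(b)
    req = a.requires_grad or b.requires_grad
    out = Tensor(np.maximum(a.data, b.data), req, (a, b))

    def _bwd(g):
        take_a = a.data >= b.data
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * take_a, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * (~take_a), b.shape))
    out._backward = _bwd
    return out
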