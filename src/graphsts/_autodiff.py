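"""Minimal reverse-mode automatic differentiation on numpy arrays.

The models in this package are deliberately small (hidden sizes of a few
dozen, sequence lengths under a hundred), so a compact tape-based tensor
with the handful of operations they need — matmul, broadcasting add/mul,
relu/tanh, masked softmax, reductions, gather and concatenation — is all
that is required.  Arrays are float64 throughout; gradients are accumulated
by topological traversal of the recorded graph.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers -------------------------------------------

    @staticmethod
    def _wrap(other):
        return other if isinstance(other, Tensor) else Tensor(other)

    @classmethod
    def _from_op(cls, data, parents, backward):
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    # -- arithmetic ------------------------------------------------------

    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.data.shape),
                    _unbroadcast(g, other.data.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward(g):
            return (_unbroadcast(g * other.data, self.data.shape),
                    _unbroadcast(g * self.data, other.data.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, scalar):
        return self * (1.0 / float(scalar))

    def __matmul__(self, other):
        other = self._wrap(other)
        out_data = self.data @ other.data

        def backward(g):
            ga = g @ other.data.swapaxes(-1, -2)
            gb = self.data.swapaxes(-1, -2) @ g
            return (_unbroadcast(ga, self.data.shape),
                    _unbroadcast(gb, other.data.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    def __pow__(self, p: int):
        out_data = self.data ** p

        def backward(g):
            return (g * p * self.data ** (p - 1),)

        return Tensor._from_op(out_data, (self,), backward)

    # -- nonlinearities ---------------------------------------------------

    def relu(self):
        mask = self.data > 0
        out_data = self.data * mask

        def backward(g):
            return (g * mask,)

        return Tensor._from_op(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            return (g * (1.0 - out_data ** 2),)

        return Tensor._from_op(out_data, (self,), backward)

    def softmax_last(self, additive_mask: np.ndarray | None = None):
        """Softmax over the last axis; `additive_mask` (constant) is added
        to the logits first (use large negatives to mask positions)."""
        logits = self.data if additive_mask is None else self.data + additive_mask
        shifted = logits - logits.max(axis=-1, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=-1, keepdims=True)

        def backward(g):
            dot = (g * out_data).sum(axis=-1, keepdims=True)
            return (out_data * (g - dot),)

        return Tensor._from_op(out_data, (self,), backward)

    # -- reductions / shape ------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.data.shape).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.data.shape).copy(),)

        return Tensor._from_op(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    def transpose_last(self):
        out_data = self.data.swapaxes(-1, -2)

        def backward(g):
            return (g.swapaxes(-1, -2),)

        return Tensor._from_op(out_data, (self,), backward)

    def reshape(self, *shape):
        out_data = self.data.reshape(*shape)

        def backward(g):
            return (g.reshape(self.data.shape),)

        return Tensor._from_op(out_data, (self,), backward)

    def take_rows(self, index: np.ndarray):
        """Gather rows (embedding lookup); backward scatter-adds."""
        index = np.asarray(index)
        out_data = self.data[index]

        def backward(g):
            grad = np.zeros_like(self.data)
            np.add.at(grad, index, g)
            return (grad,)

        return Tensor._from_op(out_data, (self,), backward)

    # -- backprop ----------------------------------------------------------

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = np.array(g, dtype=np.float64)
                else:
                    parent.grad += g


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        return tuple(
            np.take(g, range(offsets[i], offsets[i + 1]), axis=axis)
            for i in range(len(tensors))
        )

    return Tensor._from_op(out_data, tuple(tensors), backward)


class Adam:
    """Adam with per-group learning rates (text encoder vs graph side)."""

    def __init__(self, param_groups: list[dict], beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.groups = param_groups
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._state = {}
        for group in self.groups:
            for p in group["params"]:
                self._state[id(p)] = (np.zeros_like(p.data),
                                      np.zeros_like(p.data))

    def zero_grad(self):
        for group in self.groups:
            for p in group["params"]:
                p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for group in self.groups:
            lr = group["lr"]
            for p in group["params"]:
                if p.grad is None:
                    continue
                m, v = self._state[id(p)]
                m *= b1
                m += (1 - b1) * p.grad
                v *= b2
                v += (1 - b2) * p.grad ** 2
                m_hat = m / (1 - b1 ** self.t)
                v_hat = v / (1 - b2 ** self.t)
                p.data -= lr * m_hat / (np.sqrt(v_hat) + self.eps)
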