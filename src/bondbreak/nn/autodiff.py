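"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operations the fragmentation model needs: dense and
constant-matrix products, broadcast add/multiply, row gathering for embedding
lookups, concatenation, mean pooling, ELU, and softmax.  Gradients are
accumulated by a topological backward sweep over the recorded tape.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "parameter", "constant", "matmul", "const_matmul", "add", "sub",
    "mul", "take_rows", "concat", "mean_rows", "elu", "softmax", "mse",
    "scale", "reshape",
]


class Tensor:
    __slots__ = ("data", "grad", "parents", "backward_fn", "requires_grad")

    def __init__(self, data, parents=(), backward_fn=None, requires_grad=False):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.parents = parents
        self.backward_fn = backward_fn
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor):
            stack = [(t, iter(t.parents))]
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen and p.requires_grad:
                        seen.add(id(p))
                        stack.append((p, iter(p.parents)))
                        advanced = True
                        break
                if not advanced:
                    stack.pop()
                    topo.append(node)

        seen.add(id(self))
        visit(self)
        self.grad = np.asarray(grad, dtype=float)
        for node in reversed(topo):
            if node.backward_fn is not None and node.grad is not None:
                node.backward_fn(node.grad)

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=float)
        else:
            self.grad = self.grad + g


def parameter(data) -> Tensor:
    return Tensor(data, requires_grad=True)


def constant(data) -> Tensor:
    return Tensor(data)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def _binary(a: Tensor, b: Tensor, out_data, da, db) -> Tensor:
    out = Tensor(out_data, parents=(a, b))

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(da(g), a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(db(g), b.shape))

    out.backward_fn = backward
    return out


def add(a: Tensor, b: Tensor) -> Tensor:
    return _binary(a, b, a.data + b.data, lambda g: g, lambda g: g)


def sub(a: Tensor, b: Tensor) -> Tensor:
    return _binary(a, b, a.data - b.data, lambda g: g, lambda g: -g)


def mul(a: Tensor, b: Tensor) -> Tensor:
    return _binary(a, b, a.data * b.data, lambda g: g * b.data, lambda g: g * a.data)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    return _binary(
        a, b, a.data @ b.data,
        lambda g: g @ b.data.T,
        lambda g: a.data.T @ g,
    )


def const_matmul(c: np.ndarray, x: Tensor) -> Tensor:
    """Product ``c @ x`` with a constant (non-differentiated) left matrix."""
    out = Tensor(c @ x.data, parents=(x,))

    def backward(g):
        if x.requires_grad:
            x._accumulate(c.T @ g)

    out.backward_fn = backward
    return out


def scale(x: Tensor, s: float) -> Tensor:
    out = Tensor(x.data * s, parents=(x,))

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * s)

    out.backward_fn = backward
    return out


def take_rows(table: Tensor, indices) -> Tensor:
    """Embedding lookup: gather rows of ``table``; gradients scatter-add back."""
    indices = np.asarray(indices, dtype=int)
    out = Tensor(table.data[indices], parents=(table,))

    def backward(g):
        if table.requires_grad:
            acc = np.zeros_like(table.data)
            np.add.at(acc, indices, g)
            table._accumulate(acc)

    out.backward_fn = backward
    return out


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]

    def backward(g):
        offset = 0
        for t, n in zip(tensors, sizes):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(offset, offset + n)
                t._accumulate(g[tuple(sl)])
            offset += n

    out.backward_fn = backward
    return out


def reshape(x: Tensor, shape) -> Tensor:
    out = Tensor(x.data.reshape(shape), parents=(x,))

    def backward(g):
        if x.requires_grad:
            x._accumulate(g.reshape(x.data.shape))

    out.backward_fn = backward
    return out


def mean_rows(x: Tensor) -> Tensor:
    """Mean over axis 0 (global mean pooling of node states)."""
    n = x.data.shape[0]
    out = Tensor(x.data.mean(axis=0), parents=(x,))

    def backward(g):
        if x.requires_grad:
            x._accumulate(np.broadcast_to(g / n, x.data.shape).copy())

    out.backward_fn = backward
    return out


def elu(x: Tensor, alpha: float = 1.0) -> Tensor:
    pos = x.data > 0
    ex = alpha * (np.exp(np.minimum(x.data, 0.0)) - 1.0)
    out_data = np.where(pos, x.data, ex)
    out = Tensor(out_data, parents=(x,))

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * np.where(pos, 1.0, ex + alpha))

    out.backward_fn = backward
    return out


def softmax(x: Tensor) -> Tensor:
    """Softmax over a 1-D logit vector, with the analytic backward pass."""
    z = x.data - x.data.max()
    e = np.exp(z)
    p = e / e.sum()
    out = Tensor(p, parents=(x,))

    def backward(g):
        if x.requires_grad:
            x._accumulate(p * (g - float(g @ p)))

    out.backward_fn = backward
    return out


def mse(pred: Tensor, target: np.ndarray) -> Tensor:
    """Mean squared error against a constant target vector."""
    target = np.asarray(target, dtype=float)
    diff = pred.data - target
    n = diff.size
    out = Tensor(float((diff ** 2).mean()), parents=(pred,))

    def backward(g):
        if pred.requires_grad:
            pred._accumulate((2.0 / n) * diff * g)

    out.backward_fn = backward
    return out
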