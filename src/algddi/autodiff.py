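"""Minimal reverse-mode automatic differentiation on NumPy arrays.

All trainable models in this package (masked-attribute GNN, relational
local encoder, ComplEx factorization, transformer fusion, MLP heads) are
small enough that a float64 NumPy graph with hand-written vector-Jacobian
products is fast, exactly reproducible, and dependency-free.

Conventions:
  * ``Tensor.data`` is always a ``float64`` ndarray.
  * Graphs are built eagerly; ``Tensor.backward()`` runs a topological
    sweep and accumulates into ``Tensor.grad`` for every tensor with
    ``requires_grad=True``.
  * Integer index arrays and sparse matrices enter the graph as constants.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Tensor",
    "tensor",
    "concat",
    "gather_rows",
    "spmm",
    "softmax",
    "log_softmax",
    "Adam",
]


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=np.float64)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # -- graph plumbing ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _make(self, data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): _as_array(grad)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None or t._backward is None:
                if g is not None and t.requires_grad:
                    t.grad = g if t.grad is None else t.grad + g
                continue
            if t.requires_grad and not t._parents:  # leaf (unreachable here)
                t.grad = g if t.grad is None else t.grad + g
            for parent, pg in zip(t._parents, t._backward(g)):
                if pg is None or not parent.requires_grad:
                    continue
                if parent._backward is None:  # leaf
                    parent.grad = pg if parent.grad is None else parent.grad + pg
                else:
                    k = id(parent)
                    grads[k] = pg if k not in grads else grads[k] + pg

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data * other.data

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return Tensor(other) * self ** -1.0

    def __pow__(self, exponent: float):
        out_data = self.data ** exponent

        def backward(g):
            return (g * exponent * self.data ** (exponent - 1.0),)

        return self._make(out_data, (self,), backward)

    def __matmul__(self, other):
        """``A @ B`` with B strictly 2-D; A may carry leading batch dims."""
        other = other if isinstance(other, Tensor) else Tensor(other)
        if other.ndim != 2:
            raise ValueError("use bmm() for batched right operands")
        out_data = self.data @ other.data

        def backward(g):
            ga = g @ other.data.T
            a2 = self.data.reshape(-1, self.shape[-1])
            g2 = g.reshape(-1, g.shape[-1])
            gb = a2.T @ g2
            return (ga, gb)

        return self._make(out_data, (self, other), backward)

    def bmm(self, other: "Tensor") -> "Tensor":
        """Batched matmul: both operands share leading batch dims."""
        out_data = np.matmul(self.data, other.data)

        def backward(g):
            ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
            gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
            return (ga, gb)

        return self._make(out_data, (self, other), backward)

    # -- shape ops --------------------------------------------------------
    def reshape(self, *shape):
        old = self.shape
        return self._make(
            self.data.reshape(*shape), (self,), lambda g: (g.reshape(old),)
        )

    def transpose(self, axes):
        inv = np.argsort(axes)
        return self._make(
            self.data.transpose(axes), (self,), lambda g: (g.transpose(inv),)
        )

    def __getitem__(self, key):
        out_data = self.data[key]
        shape = self.shape

        def backward(g):
            full = np.zeros(shape)
            np.add.at(full, key, g)
            return (full,)

        return self._make(out_data, (self,), backward)

    # -- reductions and nonlinearities -------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.shape

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, shape).copy(),)
            if not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, shape).copy(),)

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def exp(self):
        out_data = np.exp(self.data)
        return self._make(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return self._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def relu(self):
        out_data = np.maximum(self.data, 0.0)
        mask = self.data > 0.0
        return self._make(out_data, (self,), lambda g: (g * mask,))

    def sigmoid(self):
        out_data = np.empty_like(self.data)
        pos = self.data >= 0
        out_data[pos] = 1.0 / (1.0 + np.exp(-self.data[pos]))
        ex = np.exp(self.data[~pos])
        out_data[~pos] = ex / (1.0 + ex)

        def backward(g):
            return (g * out_data * (1.0 - out_data),)

        return self._make(out_data, (self,), backward)

    def softplus(self):
        """log(1 + exp(x)), overflow-safe."""
        out_data = np.logaddexp(0.0, self.data)
        sig = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))
        return self._make(out_data, (self,), lambda g: (g * sig,))


def tensor(data, requires_grad: bool = False) -> Tensor:
    return Tensor(data, requires_grad=requires_grad)


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    out = Tensor(out_data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = backward
    return out


def gather_rows(table: Tensor, idx) -> Tensor:
    """Row lookup ``table[idx]`` (embedding gather); scatter-add backward."""
    idx = np.asarray(idx)
    out_data = table.data[idx]
    shape = table.shape

    def backward(g):
        full = np.zeros(shape)
        np.add.at(full, idx, g)
        return (full,)

    return table._make(out_data, (table,), backward)


def spmm(matrix: sp.spmatrix, x: Tensor) -> Tensor:
    """Constant sparse matrix times dense tensor (2-D)."""
    m = matrix.tocsr()
    out_data = m @ x.data
    mt = m.T.tocsr()
    return x._make(out_data, (x,), lambda g: (mt @ g,))


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor(x.data.max(axis=axis, keepdims=True))  # constant, grad-free
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    z = x - shift
    return z - z.exp().sum(axis=axis, keepdims=True).log()


class Adam:
    """Adam optimizer; deterministic given a fixed call sequence."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
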