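"""Minimal reverse-mode automatic differentiation over NumPy arrays.

A tape-based engine in the style of micrograd, sized for the small gated
graph networks this package trains on CPU.  ``Tensor`` wraps an ndarray,
records its parents and a backward closure, and ``Tensor.backward`` runs the
reverse topological sweep.  The functional helpers (``tanh``, ``sigmoid``,
``concat``, ``logsumexp``, ...) dispatch on type so the same model code runs
taped during training and tape-free (plain ndarrays) at generation time.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad, shape):
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


def _matmul_grads(a, b, g):
    """Gradients of ``a @ b`` w.r.t. both operands, covering the 1-D cases."""
    if a.ndim == 1 and b.ndim == 1:          # dot -> scalar
        return g * b, g * a
    if a.ndim == 1:                          # (n,) @ (n,m) -> (m,)
        return g @ b.T, np.outer(a, g)
    if b.ndim == 1:                          # (n,m) @ (m,) -> (n,)
        return np.outer(g, b), a.T @ g
    return g @ b.swapaxes(-1, -2), a.swapaxes(-1, -2) @ g


class Tensor:
    """An ndarray with a gradient and a place on the tape."""

    __slots__ = ("data", "grad", "_parents", "_backward")

    # make ndarray's binary ops defer to our reflected operators
    __array_ufunc__ = None

    def __init__(self, data, parents=(), backward=None):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accumulate(self, g):
        g = _unbroadcast(np.asarray(g, float), self.data.shape)
        self.grad = g if self.grad is None else self.grad + g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
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

    # -- arithmetic -------------------------------------------------------

    def __add__(self, other):
        if isinstance(other, Tensor):
            out = Tensor(self.data + other.data, (self, other))
            out._backward = lambda g: (self._accumulate(g),
                                       other._accumulate(g))
        else:
            out = Tensor(self.data + other, (self,))
            out._backward = lambda g: self._accumulate(g)
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, (self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-other if isinstance(other, Tensor) else -np.asarray(other))

    def __rsub__(self, other):
        return (-self) + other

    def __mul__(self, other):
        if isinstance(other, Tensor):
            out = Tensor(self.data * other.data, (self, other))
            out._backward = lambda g: (self._accumulate(g * other.data),
                                       other._accumulate(g * self.data))
        else:
            other = np.asarray(other, float)
            out = Tensor(self.data * other, (self,))
            out._backward = lambda g: self._accumulate(g * other)
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return self * other ** -1.0
        return self * (1.0 / np.asarray(other, float))

    def __rtruediv__(self, other):
        return self ** -1.0 * other

    def __pow__(self, k):
        k = float(k)
        out = Tensor(self.data ** k, (self,))
        out._backward = lambda g: self._accumulate(
            g * k * self.data ** (k - 1.0))
        return out

    def __matmul__(self, other):
        odata = other.data if isinstance(other, Tensor) else \
            np.asarray(other, float)
        parents = (self, other) if isinstance(other, Tensor) else (self,)
        out = Tensor(self.data @ odata, parents)

        def bw(g):
            ga, gb = _matmul_grads(self.data, odata, g)
            self._accumulate(ga)
            if isinstance(other, Tensor):
                other._accumulate(gb)
        out._backward = bw
        return out

    def __rmatmul__(self, other):
        other = np.asarray(other, float)
        out = Tensor(other @ self.data, (self,))
        out._backward = lambda g: self._accumulate(
            _matmul_grads(other, self.data, g)[1])
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], (self,))

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)
        out._backward = bw
        return out

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape))
        out._backward = bw
        return out

    def mean(self, axis=None):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), (self,))
        out._backward = lambda g: self._accumulate(
            g.reshape(self.data.shape))
        return out


# -- dual-mode functional helpers -------------------------------------------

def _is_t(*xs):
    return any(isinstance(x, Tensor) for x in xs)


def tanh(x):
    if isinstance(x, Tensor):
        y = np.tanh(x.data)
        out = Tensor(y, (x,))
        out._backward = lambda g: x._accumulate(g * (1.0 - y * y))
        return out
    return np.tanh(x)


def sigmoid(x):
    if isinstance(x, Tensor):
        y = 1.0 / (1.0 + np.exp(-x.data))
        out = Tensor(y, (x,))
        out._backward = lambda g: x._accumulate(g * y * (1.0 - y))
        return out
    return 1.0 / (1.0 + np.exp(-x))


def exp(x):
    if isinstance(x, Tensor):
        y = np.exp(x.data)
        out = Tensor(y, (x,))
        out._backward = lambda g: x._accumulate(g * y)
        return out
    return np.exp(x)


def log(x):
    if isinstance(x, Tensor):
        out = Tensor(np.log(x.data), (x,))
        out._backward = lambda g: x._accumulate(g / x.data)
        return out
    return np.log(x)


def concat(xs, axis=-1):
    if _is_t(*xs):
        ts = [x if isinstance(x, Tensor) else Tensor(x) for x in xs]
        out = Tensor(np.concatenate([t.data for t in ts], axis=axis), tuple(ts))
        sizes = [t.data.shape[axis] for t in ts]
        splits = np.cumsum(sizes)[:-1]

        def bw(g):
            for t, piece in zip(ts, np.split(g, splits, axis=axis)):
                t._accumulate(piece)
        out._backward = bw
        return out
    return np.concatenate(xs, axis=axis)


def logsumexp(x, axis=-1):
    """Numerically stable log-sum-exp; the max shift is treated as constant."""
    if isinstance(x, Tensor):
        c = np.max(x.data, axis=axis, keepdims=True)
        shifted = exp(x - c)
        return log(shifted.sum(axis=axis)) + np.squeeze(c, axis=axis)
    c = np.max(x, axis=axis, keepdims=True)
    return np.log(np.exp(x - c).sum(axis=axis)) + np.squeeze(c, axis=axis)


def softmax(x, axis=-1):
    if isinstance(x, Tensor):
        ls = logsumexp(x, axis=axis)
        if np.ndim(ls.data) < x.ndim:
            ls = ls.reshape(*ls.data.shape, 1)
        return exp(x - ls)
    c = np.max(x, axis=axis, keepdims=True)
    e = np.exp(x - c)
    return e / e.sum(axis=axis, keepdims=True)


def value(x):
    """Underlying ndarray of a Tensor, or the input unchanged."""
    return x.data if isinstance(x, Tensor) else np.asarray(x, float)


class Adam:
    """Adam optimiser over a flat dict of parameter arrays (in place)."""

    def __init__(self, params: dict, lr=1e-2, beta1=0.9, beta2=0.999,
                 eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict):
        self.t += 1
        for k, g in grads.items():
            if g is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
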