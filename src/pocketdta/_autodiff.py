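"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the trainable parts of the package need:
broadcasting arithmetic, matmul, elementwise nonlinearities, reductions,
row gather / segment-sum (for message passing and surface->residue
pooling) and concatenation.  Parameters are ``Tensor`` objects with
``requires_grad=True``; :class:`AdamW` implements decoupled weight decay.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "gather_rows", "segment_sum", "AdamW"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum-reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._backward = _backward

    # -- construction helpers -------------------------------------------
    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- graph plumbing --------------------------------------------------
    def _make(self, data, parents, backward):
        req = any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req)
        if req:
            out._parents = parents
            out._backward = backward
        return out

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad needs a scalar output")
            grad = np.ones_like(self.data)
        # topological order
        topo, visited = [], set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in visited:
                    stack.append((p, False))
        grads = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and node._backward is None:
                # leaf
                node.grad = g if node.grad is None else node.grad + g
                continue
            if node._backward is None:
                continue
            for parent, pg in node._backward(g):
                if not parent.requires_grad:
                    continue
                if parent._backward is None:  # leaf
                    parent.grad = pg if parent.grad is None else parent.grad + pg
                else:
                    key = id(parent)
                    grads[key] = pg if key not in grads else grads[key] + pg

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = Tensor.as_tensor(other)
        def bw(g):
            return ((self, _unbroadcast(g, self.shape)),
                    (other, _unbroadcast(g, other.shape)))
        return self._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __mul__(self, other):
        other = Tensor.as_tensor(other)
        def bw(g):
            return ((self, _unbroadcast(g * other.data, self.shape)),
                    (other, _unbroadcast(g * self.data, other.shape)))
        return self._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __truediv__(self, other):
        return self * Tensor.as_tensor(other) ** -1.0

    def __rtruediv__(self, other):
        return Tensor.as_tensor(other) * self ** -1.0

    def __pow__(self, p: float):
        def bw(g):
            return ((self, g * p * self.data ** (p - 1.0)),)
        return self._make(self.data ** p, (self,), bw)

    def __matmul__(self, other):
        other = Tensor.as_tensor(other)
        a, b = self.data, other.data
        def bw(g):
            if a.ndim == 2 and b.ndim == 2:
                ga, gb = g @ b.T, a.T @ g
            elif a.ndim == 1 and b.ndim == 2:   # (k,)@(k,m)->(m,)
                ga, gb = b @ g, np.outer(a, g)
            elif a.ndim == 2 and b.ndim == 1:   # (n,k)@(k,)->(n,)
                ga, gb = np.outer(g, b), a.T @ g
            else:                               # (k,)@(k,)->()
                ga, gb = g * b, g * a
            return ((self, ga), (other, gb))
        return self._make(a @ b, (self, other), bw)

    # -- elementwise -----------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        def bw(g):
            return ((self, g * out_data),)
        return self._make(out_data, (self,), bw)

    def log(self):
        def bw(g):
            return ((self, g / self.data),)
        return self._make(np.log(self.data), (self,), bw)

    def relu(self):
        mask = self.data > 0
        def bw(g):
            return ((self, g * mask),)
        return self._make(self.data * mask, (self,), bw)

    def sigmoid(self):
        x = self.data
        s = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                     np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
        def bw(g):
            return ((self, g * s * (1.0 - s)),)
        return self._make(s, (self,), bw)

    def tanh(self):
        t = np.tanh(self.data)
        def bw(g):
            return ((self, g * (1.0 - t * t)),)
        return self._make(t, (self,), bw)

    def clip(self, lo: float, hi: float):
        mask = (self.data > lo) & (self.data < hi)
        def bw(g):
            return ((self, g * mask),)
        return self._make(np.clip(self.data, lo, hi), (self,), bw)

    # -- reductions / shaping -------------------------------------------
    def sum(self, axis=None):
        def bw(g):
            if axis is None:
                return ((self, np.broadcast_to(g, self.shape).copy()),)
            ge = np.expand_dims(g, axis)
            return ((self, np.broadcast_to(ge, self.shape).copy()),)
        return self._make(self.data.sum(axis=axis), (self,), bw)

    def mean(self, axis=None):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis) * (1.0 / n)

    def reshape(self, *shape):
        def bw(g):
            return ((self, g.reshape(self.shape)),)
        return self._make(self.data.reshape(*shape), (self,), bw)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def concat(tensors, axis=0) -> Tensor:
    tensors = [Tensor.as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]
    def bw(g):
        parts = np.split(g, splits, axis=axis)
        return tuple(zip(tensors, parts))
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = bw
    return out


def gather_rows(t: Tensor, idx: np.ndarray) -> Tensor:
    """``t[idx]`` along axis 0 with scatter-add backward."""
    idx = np.asarray(idx, dtype=np.intp)
    def bw(g):
        gt = np.zeros_like(t.data)
        np.add.at(gt, idx, g)
        return ((t, gt),)
    return t._make(t.data[idx], (t,), bw)


def segment_sum(t: Tensor, idx: np.ndarray, n: int) -> Tensor:
    """Sum rows of ``t`` into ``n`` buckets given per-row bucket ids."""
    idx = np.asarray(idx, dtype=np.intp)
    out_data = np.zeros((n,) + t.data.shape[1:])
    np.add.at(out_data, idx, t.data)
    def bw(g):
        return ((t, g[idx]),)
    return t._make(out_data, (t,), bw)


class AdamW:
    """Adam with decoupled weight decay on a list of parameter Tensors."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=1e-2):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.wd = lr, betas, eps, weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.betas
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
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.wd * p.data)
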