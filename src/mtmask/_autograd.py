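"""Minimal reverse-mode automatic differentiation over numpy arrays.

A small tape-based engine carrying exactly the operations the spiking
transformer needs: broadcasting arithmetic, (batched) matmul, reductions,
reshapes/permutes, slicing, concatenation, elementwise nonlinearities and
softmax.  Arrays are float32 throughout; gradients accumulate in float32.

Only the public surface used by :mod:`mtmask.model` is exported; this is not a
general-purpose framework.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "AdamW"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """Array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- plumbing ----------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    @staticmethod
    def _node(data, parents, backward, requires_grad):
        out = Tensor(data, requires_grad=requires_grad)
        if requires_grad:
            out._parents = tuple(p for p in parents if isinstance(p, Tensor))
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this node (default seed: ones)."""
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
        self._accumulate(np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._coerce(other)
        rg = self.requires_grad or other.requires_grad

        def bwd(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.shape))

        return self._node(self.data + other.data, (self, other), bwd, rg)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g, a=self):
            a._accumulate(-g)

        return self._node(-self.data, (self,), bwd, self.requires_grad)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        rg = self.requires_grad or other.requires_grad

        def bwd(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.shape))

        return self._node(self.data * other.data, (self, other), bwd, rg)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        return self * other.pow(-1.0)

    def pow(self, p: float):
        def bwd(g, a=self):
            a._accumulate(g * p * a.data ** (p - 1.0))

        return self._node(self.data**p, (self,), bwd, self.requires_grad)

    def matmul(self, other: "Tensor"):
        other = self._coerce(other)
        rg = self.requires_grad or other.requires_grad

        def bwd(g, a=self, b=other):
            if a.requires_grad:
                ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
                a._accumulate(_unbroadcast(ga, a.shape))
            if b.requires_grad:
                gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
                b._accumulate(_unbroadcast(gb, b.shape))

        return self._node(np.matmul(self.data, other.data), (self, other), bwd, rg)

    __matmul__ = matmul

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape):
        old = self.shape

        def bwd(g, a=self):
            a._accumulate(g.reshape(old))

        return self._node(self.data.reshape(*shape), (self,), bwd, self.requires_grad)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def bwd(g, a=self):
            a._accumulate(g.transpose(inv))

        return self._node(self.data.transpose(axes), (self,), bwd, self.requires_grad)

    def slice(self, key):
        """Basic (view-style) indexing with gradient scatter-add."""
        shape = self.shape

        def bwd(g, a=self):
            full = np.zeros(shape, dtype=np.float32)
            full[key] = g
            a._accumulate(full)

        return self._node(self.data[key], (self,), bwd, self.requires_grad)

    def __getitem__(self, key):
        return self.slice(key)

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def bwd(g, a=self):
            if axis is None:
                a._accumulate(np.broadcast_to(g, a.shape).astype(np.float32))
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                a._accumulate(np.broadcast_to(g, a.shape).astype(np.float32))

        return self._node(self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd, self.requires_grad)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod([self.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- nonlinearities ----------------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g, a=self, o=out_data):
            a._accumulate(g * o)

        return self._node(out_data, (self,), bwd, self.requires_grad)

    def log(self):
        def bwd(g, a=self):
            a._accumulate(g / a.data)

        return self._node(np.log(self.data), (self,), bwd, self.requires_grad)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bwd(g, a=self, o=out_data):
            a._accumulate(g * (1.0 - o * o))

        return self._node(out_data, (self,), bwd, self.requires_grad)

    def gelu(self):
        """Gaussian error linear unit (tanh approximation, float32)."""
        x = self.data
        c = np.float32(0.7978845608028654)  # sqrt(2/pi)
        a3 = np.float32(0.044715)
        u = c * (x + a3 * x * x * x)
        t = np.tanh(u)
        half = np.float32(0.5)
        out_data = half * x * (np.float32(1.0) + t)
        du = c * (np.float32(1.0) + np.float32(3.0) * a3 * x * x)
        deriv = half * (np.float32(1.0) + t) + half * x * (np.float32(1.0) - t * t) * du

        def bwd(g, a=self, d=deriv):
            a._accumulate(g * d)

        return self._node(out_data, (self,), bwd, self.requires_grad)

    def softplus(self):
        """Numerically stable log(1 + exp(x)); derivative is the sigmoid."""
        x = self.data
        out_data = np.logaddexp(np.float32(0.0), x)
        from scipy.special import expit

        sig = expit(x)

        def bwd(g, a=self, s=sig):
            a._accumulate(g * s)

        return self._node(out_data, (self,), bwd, self.requires_grad)

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)

        def bwd(g, a=self, s=s):
            dot = (g * s).sum(axis=axis, keepdims=True)
            a._accumulate(s * (g - dot))

        return self._node(s, (self,), bwd, self.requires_grad)

    def layernorm(self, eps: float = 1e-5):
        """Normalize the last axis to zero mean, unit variance (no affine)."""
        mu = self.data.mean(axis=-1, keepdims=True)
        xc = self.data - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        y = xc * inv
        D = self.shape[-1]

        def bwd(g, a=self, y=y, inv=inv):
            gm = g.mean(axis=-1, keepdims=True)
            gy = (g * y).mean(axis=-1, keepdims=True)
            a._accumulate(inv * (g - gm - y * gy))

        return self._node(y.astype(np.float32), (self,), bwd, self.requires_grad)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    """Concatenate along ``axis``, splitting the gradient back."""
    tensors = [Tensor._coerce(t) for t in tensors]
    rg = any(t.requires_grad for t in tensors)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g, ts=tensors):
        for t, piece in zip(ts, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)

    return Tensor._node(np.concatenate([t.data for t in tensors], axis=axis), tensors, bwd, rg)


class AdamW:
    """Decoupled-weight-decay Adam over a flat list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            if self.weight_decay:
                p.data *= 1.0 - self.lr * self.weight_decay
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
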