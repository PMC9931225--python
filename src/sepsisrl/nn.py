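"""Minimal reverse-mode automatic differentiation on numpy arrays.

Provides exactly the pieces the package's models need: a :class:`Tensor`
wrapping an ``ndarray`` with a dynamically built backward graph, dense and
gated-recurrent layers, and an Adam optimizer with decoupled weight decay.
All parameters are float64; the models here are small enough that speed is
not a concern and double precision keeps gradient checks tight.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "stack",
    "Linear",
    "MLP",
    "GRUCell",
    "Adam",
    "Module",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
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
    """An ndarray node in a dynamically recorded computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[], None] | None = None
        self._prev: tuple[Tensor, ...] = ()

    # -- graph plumbing ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += _unbroadcast(g, self.data.shape)

    def backward(self, grad: np.ndarray | None = None) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        # iterative DFS; sequences can be hundreds of steps deep
        path: list[tuple[Tensor, int]] = [(self, 0)]
        while path:
            node, i = path[-1]
            if id(node) in seen:
                path.pop()
                continue
            if i < len(node._prev):
                path[-1] = (node, i + 1)
                child = node._prev[i]
                if id(child) not in seen:
                    path.append((child, 0))
            else:
                seen.add(id(node))
                topo.append(node)
                path.pop()
        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=np.float64).reshape(self.data.shape)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data: np.ndarray, parents: Sequence["Tensor"]) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._prev = tuple(parents)
        return out

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out = self._make(self.data + other.data, (self, other))

        def _bw():
            self._accum(out.grad)
            other._accum(out.grad)

        out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = self._make(-self.data, (self,))
        out._backward = lambda: self._accum(-out.grad)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = self._make(self.data * other.data, (self, other))

        def _bw():
            self._accum(out.grad * other.data)
            other._accum(out.grad * self.data)

        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = self._make(self.data / other.data, (self, other))

        def _bw():
            self._accum(out.grad / other.data)
            other._accum(-out.grad * self.data / other.data**2)

        out._backward = _bw
        return out

    def __rtruediv__(self, other):
        other = self._lift(other)
        out = self._make(other.data / self.data, (self, other))

        def _bw():
            other._accum(out.grad / self.data)
            self._accum(-out.grad * other.data / self.data**2)

        out._backward = _bw
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = self._make(self.data @ other.data, (self, other))

        def _bw():
            self._accum(out.grad @ other.data.T)
            other._accum(self.data.T @ out.grad)

        out._backward = _bw
        return out

    # -- nonlinearities ----------------------------------------------------
    def exp(self):
        e = np.exp(self.data)
        out = self._make(e, (self,))
        out._backward = lambda: self._accum(out.grad * e)
        return out

    def log(self):
        out = self._make(np.log(self.data), (self,))
        out._backward = lambda: self._accum(out.grad / self.data)
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = self._make(t, (self,))
        out._backward = lambda: self._accum(out.grad * (1.0 - t * t))
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = self._make(s, (self,))
        out._backward = lambda: self._accum(out.grad * s * (1.0 - s))
        return out

    def relu(self):
        out = self._make(np.maximum(self.data, 0.0), (self,))
        out._backward = lambda: self._accum(out.grad * (self.data > 0))
        return out

    def softplus(self):
        # numerically stable: log(1+e^x) = max(x,0) + log1p(e^{-|x|})
        sp = np.maximum(self.data, 0.0) + np.log1p(np.exp(-np.abs(self.data)))
        out = self._make(sp, (self,))
        s = 1.0 / (1.0 + np.exp(-self.data))
        out._backward = lambda: self._accum(out.grad * s)
        return out

    def log_softmax(self, axis: int = -1):
        m = self.data.max(axis=axis, keepdims=True)
        z = self.data - m
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        ls = z - lse
        out = self._make(ls, (self,))
        p = np.exp(ls)

        def _bw():
            g = out.grad
            self._accum(g - p * g.sum(axis=axis, keepdims=True))

        out._backward = _bw
        return out

    # -- reductions & reshaping -------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def _bw():
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = self._make(self.data.reshape(*shape), (self,))
        out._backward = lambda: self._accum(out.grad.reshape(self.data.shape))
        return out

    def __getitem__(self, idx):
        out = self._make(self.data[idx], (self,))

        def _bw():
            g = np.zeros_like(self.data)
            np.add.at(g, idx, out.grad)
            self._accum(g)

        out._backward = _bw
        return out

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    out.requires_grad = any(t.requires_grad for t in tensors)
    if out.requires_grad:
        out._prev = tuple(tensors)
        sizes = [t.data.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def _bw():
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                sl = [slice(None)] * out.grad.ndim
                sl[axis] = slice(lo, hi)
                t._accum(out.grad[tuple(sl)])

        out._backward = _bw
    return out


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis))
    out.requires_grad = any(t.requires_grad for t in tensors)
    if out.requires_grad:
        out._prev = tuple(tensors)

        def _bw():
            for i, t in enumerate(tensors):
                t._accum(np.take(out.grad, i, axis=axis))

        out._backward = _bw
    return out


# ---------------------------------------------------------------------------
# Layers


class Module:
    """Base class: parameter collection and train/eval bookkeeping."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError(
                f"state has {len(state)} arrays, model has {len(params)} parameters"
            )
        for i, p in enumerate(params):
            arr = np.asarray(state[f"p{i}"], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for parameter {i}")
            p.data = arr.copy()


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (n_in + n_out))
        self.W = Tensor(rng.normal(0.0, scale, size=(n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class MLP(Module):
    """Feed-forward net with tanh hidden activations and a linear head."""

    def __init__(self, sizes: Sequence[int], rng: np.random.Generator):
        self.layers = [Linear(a, b, rng) for a, b in zip(sizes[:-1], sizes[1:])]

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers[:-1]:
            x = layer(x).tanh()
        return self.layers[-1](x)


class GRUCell(Module):
    """Standard gated recurrent unit (update gate z, reset gate r)."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.n_hidden = n_hidden
        self.lin_z = Linear(n_in + n_hidden, n_hidden, rng)
        self.lin_r = Linear(n_in + n_hidden, n_hidden, rng)
        self.lin_n = Linear(n_in + n_hidden, n_hidden, rng)

    def __call__(self, x: Tensor, h: Tensor) -> Tensor:
        xh = concat([x, h], axis=-1)
        z = self.lin_z(xh).sigmoid()
        r = self.lin_r(xh).sigmoid()
        n = self.lin_n(concat([x, r * h], axis=-1)).tanh()
        return (1.0 - z) * n + z * h

    def init_state(self, batch: int) -> Tensor:
        return Tensor(np.zeros((batch, self.n_hidden)))


class Adam:
    """Adam with decoupled weight decay (AdamW-style)."""

    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
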