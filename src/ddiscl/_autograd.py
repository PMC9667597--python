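"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is the numerical core the drug-pair network is built on: a ``Tensor``
wrapping an ``ndarray`` plus a dynamically recorded tape, a handful of
differentiable primitives (matmul, elementwise arithmetic, exp/log/tanh,
reductions, reshapes, concatenation, fancy row-gather), and the neural
layers composed from them (linear, multi-head self-attention, batch
normalisation, dropout) together with the RAdam optimizer.

All computation is float64 and single-threaded-deterministic: identical
inputs, parameters and RNG state give bitwise-identical outputs.
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concatenate",
    "gelu",
    "log_softmax",
    "softmax",
    "Linear",
    "MultiHeadSelfAttention",
    "BatchNorm1d",
    "Dropout",
    "Module",
    "RAdam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (the inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # collapse leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the autodiff graph holding a float64 array."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    # ------------------------------------------------------------------ meta
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __float__(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -------------------------------------------------------------- backward
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; deep graphs would blow the recursion limit
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
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(grad, self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # ------------------------------------------------------------ arithmetic
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(
            self.data + other.data,
            requires_grad=self.requires_grad or other.requires_grad,
            parents=(self, other),
        )

        def bw(g):
            if self.requires_grad:
                self._accumulate(g)
            if other.requires_grad:
                other._accumulate(g)

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(
            self.data * other.data,
            requires_grad=self.requires_grad or other.requires_grad,
            parents=(self, other),
        )

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * other.data)
            if other.requires_grad:
                other._accumulate(g * self.data)

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return as_tensor(other) * self ** -1.0

    def __pow__(self, exponent: float):
        out = Tensor(
            self.data ** exponent,
            requires_grad=self.requires_grad,
            parents=(self,),
        )

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(
            self.data @ other.data,
            requires_grad=self.requires_grad or other.requires_grad,
            parents=(self, other),
        )

        def bw(g):
            if self.requires_grad:
                self._accumulate(g @ np.swapaxes(other.data, -1, -2))
            if other.requires_grad:
                other._accumulate(np.swapaxes(self.data, -1, -2) @ g)

        out._backward = bw
        return out

    # -------------------------------------------------------------- pointwise
    def exp(self):
        out = Tensor(np.exp(self.data), requires_grad=self.requires_grad, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * out.data)

        out._backward = bw
        return out

    def log(self):
        out = Tensor(np.log(self.data), requires_grad=self.requires_grad, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        out._backward = bw
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), requires_grad=self.requires_grad, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - out.data ** 2))

        out._backward = bw
        return out

    def sqrt(self):
        return self ** 0.5

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(
            self.data.sum(axis=axis, keepdims=keepdims),
            requires_grad=self.requires_grad,
            parents=(self,),
        )

        def bw(g):
            if self.requires_grad:
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.data.shape))

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ---------------------------------------------------------------- shaping
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), requires_grad=self.requires_grad, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.data.shape))

        out._backward = bw
        return out

    def swapaxes(self, a: int, b: int):
        out = Tensor(np.swapaxes(self.data, a, b), requires_grad=self.requires_grad, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(np.swapaxes(g, a, b))

        out._backward = bw
        return out

    @property
    def T(self):
        return self.swapaxes(-1, -2)

    def gather_rows(self, index: np.ndarray):
        """Pick ``self[arange(N), index]`` from a 2-D tensor."""
        index = np.asarray(index, dtype=np.intp)
        rows = np.arange(self.data.shape[0])
        out = Tensor(self.data[rows, index], requires_grad=self.requires_grad, parents=(self,))

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, (rows, index), g)
                self._accumulate(full)

        out._backward = bw
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concatenate(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        requires_grad=any(t.requires_grad for t in tensors),
        parents=tuple(tensors),
    )
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)

    out._backward = bw
    return out


_GELU_C = math.sqrt(2.0 / math.pi)


def gelu(x: Tensor) -> Tensor:
    """Gaussian error linear unit (tanh approximation)."""
    inner = (x + x ** 3.0 * 0.044715) * _GELU_C
    return x * 0.5 * (inner.tanh() + 1.0)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = np.max(x.data, axis=axis, keepdims=True)  # constant shift: no grad
    z = x - Tensor(shift)
    lse = z.exp().sum(axis=axis, keepdims=True).log()
    return z - lse


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    return log_softmax(x, axis=axis).exp()


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------


class Module:
    """Base class: parameter registry plus a shared train/eval switch."""

    def __init__(self):
        self.training = True
        self._params: dict[str, Tensor] = {}
        self._children: dict[str, "Module"] = {}

    def add_param(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(value, requires_grad=True)
        self._params[name] = t
        return t

    def add_module(self, name: str, mod: "Module") -> "Module":
        self._children[name] = mod
        return mod

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for child in self._children.values():
            out.extend(child.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out = {prefix + k: v for k, v in self._params.items()}
        for name, child in self._children.items():
            out.update(child.named_parameters(prefix + name + "."))
        return out

    def state_arrays(self) -> dict[str, np.ndarray]:
        """All learnable parameters and buffers, flat name -> array."""
        out = {k: v.data for k, v in self.named_parameters().items()}
        out.update(self.named_buffers())
        return out

    def named_buffers(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = dict(getattr(self, "_buffers", {}))
        out = {prefix + k: v for k, v in out.items()}
        for name, child in self._children.items():
            out.update(child.named_buffers(prefix + name + "."))
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        buffers = self._all_buffer_holders()
        for key, arr in state.items():
            if key in params:
                params[key].data = np.asarray(arr, dtype=np.float64)
            elif key in buffers:
                holder, name = buffers[key]
                holder._buffers[name] = np.asarray(arr, dtype=np.float64)
            else:
                raise KeyError(f"unknown parameter {key!r} in checkpoint")

    def _all_buffer_holders(self, prefix: str = "") -> dict[str, tuple["Module", str]]:
        out = {prefix + k: (self, k) for k in getattr(self, "_buffers", {})}
        for name, child in self._children.items():
            out.update(child._all_buffer_holders(prefix + name + "."))
        return out

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for child in self._children.values():
            child.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        scale = math.sqrt(2.0 / (n_in + n_out))
        self.W = self.add_param("W", rng.normal(0.0, scale, size=(n_in, n_out)))
        self.b = self.add_param("b", np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class MultiHeadSelfAttention(Module):
    """Scaled dot-product self-attention over a (batch, tokens, dim) tensor."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % n_heads != 0:
            raise ValueError(f"attention dim {dim} not divisible by {n_heads} heads")
        self.dim = dim
        self.n_heads = n_heads
        self.d_head = dim // n_heads
        self.wq = self.add_module("wq", Linear(dim, dim, rng))
        self.wk = self.add_module("wk", Linear(dim, dim, rng))
        self.wv = self.add_module("wv", Linear(dim, dim, rng))
        self.wo = self.add_module("wo", Linear(dim, dim, rng))

    def __call__(self, x: Tensor) -> Tensor:
        b, t, d = x.shape
        h, dh = self.n_heads, self.d_head

        def split_heads(v: Tensor) -> Tensor:
            return v.reshape(b, t, h, dh).swapaxes(1, 2)  # (b, h, t, dh)

        q = split_heads(self.wq(x))
        k = split_heads(self.wk(x))
        v = split_heads(self.wv(x))
        scores = (q @ k.T) * (1.0 / math.sqrt(dh))  # (b, h, t, t)
        attn = softmax(scores, axis=-1)
        ctx = (attn @ v).swapaxes(1, 2).reshape(b, t, d)
        return self.wo(ctx)


class BatchNorm1d(Module):
    """Batch normalisation over the first axis; running stats used in eval."""

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = self.add_param("gamma", np.ones(dim))
        self.beta = self.add_param("beta", np.zeros(dim))
        self._buffers = {
            "running_mean": np.zeros(dim),
            "running_var": np.ones(dim),
        }

    def __call__(self, x: Tensor) -> Tensor:
        if self.training and x.shape[0] > 1:
            mu = x.mean(axis=0, keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=0, keepdims=True)
            m = self.momentum
            self._buffers["running_mean"] = (
                (1 - m) * self._buffers["running_mean"] + m * mu.data.ravel()
            )
            self._buffers["running_var"] = (
                (1 - m) * self._buffers["running_var"] + m * var.data.ravel()
            )
            xhat = (x - mu) * (var + self.eps) ** -0.5
        else:
            mu = Tensor(self._buffers["running_mean"])
            var = Tensor(self._buffers["running_var"])
            xhat = (x - mu) * (var + self.eps) ** -0.5
        return xhat * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout; identity in eval mode. Draws from the rng it is given."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------


class RAdam:
    """Rectified Adam (Liu et al. 2020): Adam with a variance-rectification
    term that turns off the adaptive step while second-moment estimates are
    unreliable, removing the need for warm-up."""

    def __init__(self, params: Sequence[Tensor], lr: float = 2e-5,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.rho_inf = 2.0 / (1.0 - self.b2) - 1.0

    def step(self) -> None:
        self.t += 1
        t = self.t
        b1, b2 = self.b1, self.b2
        b2t = b2 ** t
        rho_t = self.rho_inf - 2.0 * t * b2t / (1.0 - b2t)
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            m_hat = self.m[i] / (1.0 - b1 ** t)
            if rho_t > 4.0:
                v_hat = np.sqrt(self.v[i] / (1.0 - b2t))
                r = math.sqrt(
                    ((rho_t - 4.0) * (rho_t - 2.0) * self.rho_inf)
                    / ((self.rho_inf - 4.0) * (self.rho_inf - 2.0) * rho_t)
                )
                p.data -= self.lr * r * m_hat / (v_hat + self.eps)
            else:
                p.data -= self.lr * m_hat

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
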