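"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the training substrate for the convolutional scoring heads and the
twin transformer encoder.  It is intentionally small: dense float64 tensors,
a topologically-sorted backward pass, and exactly the operations the models
in this package compose.  Custom operations (e.g. the differentiable
Needleman-Wunsch layer) plug in by constructing a :class:`Tensor` with an
explicit backward rule.

All gradients here are checked against central finite differences in the
test suite.
"""

from __future__ import annotations

import copy
import math
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "constant",
    "parameter",
    "matmul",
    "softplus",
    "logsigmoid",
    "relu",
    "softmax",
    "layer_norm",
    "clamp",
    "pad_rows",
    "cosine_similarity",
    "Module",
    "Linear",
    "Conv1d",
    "LayerNorm",
    "MultiHeadSelfAttention",
    "TransformerEncoderLayer",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over extra leading axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus the closure that propagates its gradient."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        parents: Sequence["Tensor"] = (),
        backward: Callable[[np.ndarray], None] | None = None,
        requires_grad: bool | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self._parents = tuple(parents)
        self._backward = backward
        if requires_grad is None:
            requires_grad = any(p.requires_grad for p in self._parents)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None

    # -- graph plumbing ----------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
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
                stack.append((p, False))
        for node in topo:
            node.grad = np.zeros_like(node.data)
        self.grad = np.asarray(grad, dtype=np.float64).reshape(self.data.shape)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    # -- basic properties ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data + other.data, (self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data * other.data, (self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data / other.data, (self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        out._backward = bw
        return out

    def __matmul__(self, other):
        return matmul(self, _as_tensor(other))

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def exp(self):
        out = Tensor(np.exp(self.data), (self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * out.data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), (self,))
        out._backward = lambda g: self.requires_grad and self._accum(g / self.data)
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), (self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            g * (1.0 - out.data**2)
        )
        return out

    def sqrt(self):
        out = Tensor(np.sqrt(self.data), (self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            g * 0.5 / out.data
        )
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), (self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            g.reshape(self.data.shape)
        )
        return out

    def swapaxes(self, a, b):
        out = Tensor(np.swapaxes(self.data, a, b), (self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            np.swapaxes(g, a, b)
        )
        return out

    @property
    def T(self):
        return self.swapaxes(-1, -2)

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], (self,))

        def bw(g):
            if not self.requires_grad:
                return
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        out._backward = bw
        return out


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x, requires_grad=False)


def constant(x) -> Tensor:
    return Tensor(np.asarray(x, dtype=np.float64), requires_grad=False)


def parameter(x) -> Tensor:
    return Tensor(np.asarray(x, dtype=np.float64), requires_grad=True)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    # promote 1-D operands (vector @ matrix etc.) through reshape ops so the
    # batched backward below only ever sees >= 2-D arrays
    if a.data.ndim == 1 and b.data.ndim == 1:
        return (a.reshape(1, -1) @ b.reshape(-1, 1)).reshape(())
    if a.data.ndim == 1:
        return matmul(a.reshape(1, -1), b).reshape(b.data.shape[:-2] + (b.data.shape[-1],))
    if b.data.ndim == 1:
        return matmul(a, b.reshape(-1, 1)).reshape(a.data.shape[:-1])
    out = Tensor(np.matmul(a.data, b.data), (a, b))

    def bw(g):
        if a.requires_grad:
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            a._accum(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            b._accum(_unbroadcast(gb, b.data.shape))

    out._backward = bw
    return out


def softplus(x: Tensor) -> Tensor:
    # numerically stable: log1p(exp(-|x|)) + max(x, 0)
    d = np.log1p(np.exp(-np.abs(x.data))) + np.maximum(x.data, 0.0)
    out = Tensor(d, (x,))
    sig = 1.0 / (1.0 + np.exp(-x.data))
    out._backward = lambda g: x.requires_grad and x._accum(g * sig)
    return out


def logsigmoid(x: Tensor) -> Tensor:
    d = -(np.log1p(np.exp(-np.abs(x.data))) + np.maximum(-x.data, 0.0))
    out = Tensor(d, (x,))
    sig = 1.0 / (1.0 + np.exp(-x.data))
    out._backward = lambda g: x.requires_grad and x._accum(g * (1.0 - sig))
    return out


def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0.0), (x,))
    mask = (x.data > 0).astype(np.float64)
    out._backward = lambda g: x.requires_grad and x._accum(g * mask)
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)
    e = np.exp(x.data - m)
    s = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(s, (x,))

    def bw(g):
        if not x.requires_grad:
            return
        dot = (g * s).sum(axis=axis, keepdims=True)
        x._accum(s * (g - dot))

    out._backward = bw
    return out


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = Tensor(xhat * gain.data + bias.data, (x, gain, bias))
    n = x.data.shape[-1]

    def bw(g):
        if gain.requires_grad:
            gain._accum(_unbroadcast(g * xhat, gain.data.shape))
        if bias.requires_grad:
            bias._accum(_unbroadcast(g, bias.data.shape))
        if x.requires_grad:
            gh = g * gain.data
            x._accum(
                inv
                * (
                    gh
                    - gh.mean(axis=-1, keepdims=True)
                    - xhat * (gh * xhat).mean(axis=-1, keepdims=True)
                )
            )

    out._backward = bw
    return out


def absval(x: Tensor) -> Tensor:
    """|x| with sign(x) backward (subgradient 0 at exactly 0)."""
    out = Tensor(np.abs(x.data), (x,))
    s = np.sign(x.data)
    out._backward = lambda g: x.requires_grad and x._accum(g * s)
    return out


def clamp(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clip values; gradient passes only through unclipped entries."""
    out = Tensor(np.clip(x.data, lo, hi), (x,))
    mask = ((x.data > lo) & (x.data < hi)).astype(np.float64)
    out._backward = lambda g: x.requires_grad and x._accum(g * mask)
    return out


def pad_rows(x: Tensor, before: int, after: int) -> Tensor:
    """Zero-pad a (L, C) tensor along the first axis."""
    out = Tensor(np.pad(x.data, ((before, after), (0, 0))), (x,))
    L = x.data.shape[0]
    out._backward = lambda g: x.requires_grad and x._accum(g[before : before + L])
    return out


def cosine_similarity(a: Tensor, b: Tensor, eps: float = 1e-12) -> Tensor:
    num = (a * b).sum()
    den = ((a * a).sum() + eps).sqrt() * ((b * b).sum() + eps).sqrt()
    return num / den


# ---------------------------------------------------------------------------
# Modules
# ---------------------------------------------------------------------------


class Module:
    """Base class: a named tree of parameter tensors."""

    def parameters(self) -> list[Tensor]:
        return [t for _, t in self.named_parameters()]

    def named_parameters(self) -> list[tuple[str, Tensor]]:
        out: list[tuple[str, Tensor]] = []
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                out.append((name, val))
            elif isinstance(val, Module):
                out.extend((f"{name}.{k}", t) for k, t in val.named_parameters())
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        out.extend(
                            (f"{name}.{i}.{k}", t) for k, t in item.named_parameters()
                        )
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: t.data.copy() for k, t in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) ^ set(state)
        if missing:
            raise KeyError(f"parameter name mismatch: {sorted(missing)}")
        for k, t in own.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != t.data.shape:
                raise ValueError(f"shape mismatch for {k}")
            t.data = arr.copy()


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        scale = math.sqrt(2.0 / (d_in + d_out))
        self.weight = parameter(rng.normal(0.0, scale, size=(d_in, d_out)))
        self.bias = parameter(np.zeros(d_out))

    def __call__(self, x: Tensor) -> Tensor:
        return matmul(x, self.weight) + self.bias


class Conv1d(Module):
    """Same-padded 1-D convolution over a (L, C_in) sequence.

    Implemented as a sum of k shifted matrix products, which keeps the whole
    operation inside the autograd graph without a bespoke backward rule.
    """

    def __init__(self, c_in: int, c_out: int, kernel_size: int, rng: np.random.Generator):
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd for same-padding")
        self.kernel_size = kernel_size
        scale = math.sqrt(2.0 / (c_in * kernel_size + c_out))
        self.weight = parameter(
            rng.normal(0.0, scale, size=(kernel_size, c_in, c_out))
        )
        self.bias = parameter(np.zeros(c_out))

    def __call__(self, x: Tensor) -> Tensor:
        L = x.shape[0]
        half = self.kernel_size // 2
        xp = pad_rows(x, half, half)
        out = None
        for o in range(self.kernel_size):
            term = matmul(xp[o : o + L], self.weight[o])
            out = term if out is None else out + term
        return out + self.bias


class LayerNorm(Module):
    def __init__(self, dim: int):
        self.gain = parameter(np.ones(dim))
        self.bias = parameter(np.zeros(dim))

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gain, self.bias)


class MultiHeadSelfAttention(Module):
    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        if dim % n_heads != 0:
            raise ValueError("dim must be divisible by n_heads")
        self.n_heads = n_heads
        self.dim = dim
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.wo = Linear(dim, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        L, d = x.shape
        h, dh = self.n_heads, self.dim // self.n_heads
        q = self.wq(x).reshape(L, h, dh).swapaxes(0, 1)  # (h, L, dh)
        k = self.wk(x).reshape(L, h, dh).swapaxes(0, 1)
        v = self.wv(x).reshape(L, h, dh).swapaxes(0, 1)
        att = softmax(matmul(q, k.T) * (1.0 / math.sqrt(dh)), axis=-1)
        ctx = matmul(att, v).swapaxes(0, 1).reshape(L, d)
        return self.wo(ctx)


class TransformerEncoderLayer(Module):
    """Post-norm transformer encoder block (attention + feed-forward).

    The output projections of both residual branches start at zero, so each
    block is the identity at initialization and the branches only grow as
    training finds them useful -- a standard stabilization for training
    transformers from scratch on small corpora."""

    def __init__(self, dim: int, n_heads: int, ff_dim: int, rng: np.random.Generator):
        self.attn = MultiHeadSelfAttention(dim, n_heads, rng)
        self.attn.wo.weight.data[:] = 0.0
        self.norm1 = LayerNorm(dim)
        self.ff1 = Linear(dim, ff_dim, rng)
        self.ff2 = Linear(ff_dim, dim, rng)
        self.ff2.weight.data[:] = 0.0
        self.norm2 = LayerNorm(dim)

    def __call__(self, x: Tensor) -> Tensor:
        x = self.norm1(x + self.attn(x))
        x = self.norm2(x + self.ff2(relu(self.ff1(x))))
        return x


def dropout(x: Tensor, rate: float, rng: np.random.Generator | None) -> Tensor:
    """Inverted dropout; identity when rng is None (inference) or rate == 0."""
    if rng is None or rate <= 0.0:
        return x
    keep = (rng.random(x.shape) >= rate).astype(np.float64) / (1.0 - rate)
    return x * constant(keep)


class Adam:
    """Standard Adam optimizer over a list of parameter tensors."""

    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        if self.lr == 0.0:
            return
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1**self.t)
            vh = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mh / (np.sqrt(vh) + self.eps)


def snapshot(module: Module) -> dict[str, np.ndarray]:
    return copy.deepcopy(module.state_dict())
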