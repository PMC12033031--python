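"""Minimal reverse-mode automatic differentiation on numpy arrays, plus the
neural layers used by the sequence propensity models.

The engine is a tape of :class:`Tensor` nodes; calling :meth:`Tensor.backward`
on a scalar loss walks the tape in reverse topological order.  It supports
exactly the operations the package's models need (broadcasted arithmetic,
batched matmul, reshape/transpose/slice/concat, sigmoid/tanh/relu, masked
softmax, layer norm, dropout, binary cross-entropy with logits) and is
gradient-checked against central finite differences in the test suite.

Everything runs in float64 single-threaded numpy, so training is bit-for-bit
reproducible given a seed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Dense",
    "LayerNorm",
    "MultiHeadSelfAttention",
    "TransformerEncoderLayer",
    "LSTMCellBank",
    "Adam",
    "bce_with_logits",
    "dropout",
]


def _reduce_to(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a broadcasted gradient back down to ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    # -- graph mechanics ---------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() only on scalar losses")
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(_reduce_to(g, self.shape))
            if other.requires_grad:
                other._accum(_reduce_to(g, other.shape))

        return self._make(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            if self.requires_grad:
                self._accum(-g)

        return self._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(_reduce_to(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_reduce_to(g * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = self._lift(other)
        # matmul on non-contiguous views (e.g. transposed heads) is much
        # slower than a copy + contiguous multiply
        a = np.ascontiguousarray(self.data)
        b = np.ascontiguousarray(other.data)

        def bwd(g):
            if self.requires_grad:
                ga = np.matmul(g, b.swapaxes(-1, -2))
                self._accum(_reduce_to(ga, self.shape))
            if other.requires_grad:
                gb = np.matmul(a.swapaxes(-1, -2), g)
                other._accum(_reduce_to(gb, other.shape))

        return self._make(np.matmul(a, b), (self, other), bwd)

    def __rmatmul__(self, other):
        return self._lift(other) @ self

    # -- shape -------------------------------------------------------------

    def reshape(self, *shape):
        old = self.shape

        def bwd(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return self._make(self.data.reshape(*shape), (self,), bwd)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def bwd(g):
            if self.requires_grad:
                self._accum(g.transpose(*inv))

        return self._make(self.data.transpose(*axes), (self,), bwd)

    def __getitem__(self, idx):
        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        return self._make(self.data[idx], (self,), bwd)

    @staticmethod
    def concat(tensors: list["Tensor"], axis: int) -> "Tensor":
        tensors = [Tensor._lift(t) for t in tensors]
        sizes = [t.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def bwd(g):
            for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(a, b)
                    t._accum(g[tuple(sl)])

        data = np.concatenate([t.data for t in tensors], axis=axis)
        out = Tensor(data, requires_grad=any(t.requires_grad for t in tensors))
        if out.requires_grad:
            out._parents = tuple(tensors)
            out._backward = bwd
        return out

    # -- reductions & nonlinearities ---------------------------------------

    def sum(self, axis=None, keepdims=False):
        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
            else:
                ge = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(ge, self.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * y * (1.0 - y))

        return self._make(y, (self,), bwd)

    def tanh(self):
        y = np.tanh(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * (1.0 - y * y))

        return self._make(y, (self,), bwd)

    def relu(self):
        mask = self.data > 0

        def bwd(g):
            if self.requires_grad:
                self._accum(g * mask)

        return self._make(self.data * mask, (self,), bwd)

    def softmax(self, bias: np.ndarray | None = None):
        """Softmax over the last axis; ``bias`` is an additive constant
        (e.g. -1e9 at padded key positions) applied before normalization."""
        z = self.data if bias is None else self.data + bias
        z = z - z.max(axis=-1, keepdims=True)
        ez = np.exp(z)
        y = ez / ez.sum(axis=-1, keepdims=True)

        def bwd(g):
            if self.requires_grad:
                dot = (g * y).sum(axis=-1, keepdims=True)
                self._accum((g - dot) * y)

        return self._make(y, (self,), bwd)


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------


def _param(rng: np.random.Generator, shape, scale=None) -> Tensor:
    if scale is None:  # Glorot-uniform
        fan_in, fan_out = shape[0], shape[-1]
        scale = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-scale, scale, size=shape), requires_grad=True)


class Module:
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError("state_dict length mismatch")
        for p, s in zip(params, state):
            p.data = s.copy()


class Dense(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = _param(rng, (d_in, d_out))
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        std = _sqrt(var + self.eps)
        return centered * _reciprocal(std) * self.gamma + self.beta


def _sqrt(x: Tensor) -> Tensor:
    y = np.sqrt(x.data)

    def bwd(g):
        if x.requires_grad:
            x._accum(g * 0.5 / y)

    return x._make(y, (x,), bwd)


def _reciprocal(x: Tensor) -> Tensor:
    y = 1.0 / x.data

    def bwd(g):
        if x.requires_grad:
            x._accum(-g * y * y)

    return x._make(y, (x,), bwd)


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p <= 0.0:
        return x
    mask = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * Tensor(mask)


class MultiHeadSelfAttention(Module):
    """Scaled dot-product self-attention; stores the last attention maps
    (per layer, per head, row-stochastic) for interpretability."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        if dim % n_heads != 0:
            raise ValueError("n_heads must divide embed dim")
        self.dim, self.n_heads, self.d_head = dim, n_heads, dim // n_heads
        self.Wq = Dense(dim, dim, rng)
        self.Wk = Dense(dim, dim, rng)
        self.Wv = Dense(dim, dim, rng)
        self.Wo = Dense(dim, dim, rng)
        self.last_attention: np.ndarray | None = None  # (B, H, L, L)

    def __call__(self, x: Tensor, key_mask: np.ndarray, training: bool = False) -> Tensor:
        B, L, D = x.shape
        H, dh = self.n_heads, self.d_head

        def split(t: Tensor) -> Tensor:  # (B,L,D) -> (B,H,L,dh)
            return t.reshape(B, L, H, dh).transpose(0, 2, 1, 3)

        q, k, v = split(self.Wq(x)), split(self.Wk(x)), split(self.Wv(x))
        scores = q @ k.transpose(0, 1, 3, 2) * (1.0 / np.sqrt(dh))
        bias = np.where(key_mask[:, None, None, :], 0.0, -1e9)
        attn = scores.softmax(bias=bias)
        if not training:  # kept for interpretability; skipped on the training tape
            self.last_attention = attn.data.copy()
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(B, L, D)
        return self.Wo(out)


class TransformerEncoderLayer(Module):
    """Post-layer-norm encoder block: LN(x + Attn(x)), LN(x + FFN(x))."""

    def __init__(self, dim: int, n_heads: int, ff_dim: int, p_drop: float,
                 rng: np.random.Generator):
        self.attn = MultiHeadSelfAttention(dim, n_heads, rng)
        self.ff1 = Dense(dim, ff_dim, rng)
        self.ff2 = Dense(ff_dim, dim, rng)
        self.ln1 = LayerNorm(dim)
        self.ln2 = LayerNorm(dim)
        self.p_drop = p_drop

    def __call__(self, x: Tensor, key_mask: np.ndarray,
                 rng: np.random.Generator, training: bool) -> Tensor:
        a = dropout(self.attn(x, key_mask, training), self.p_drop, rng, training)
        x = self.ln1(x + a)
        f = dropout(self.ff2(self.ff1(x).relu()), self.p_drop, rng, training)
        return self.ln2(x + f)


class LSTMCellBank(Module):
    """Single-layer LSTM unrolled over time with gate weights concatenated
    as [input, forget, cell, output]."""

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator):
        self.d_in, self.d_hidden = d_in, d_hidden
        self.Wx = _param(rng, (d_in, 4 * d_hidden))
        self.Wh = _param(rng, (d_hidden, 4 * d_hidden))
        b = np.zeros(4 * d_hidden)
        b[d_hidden : 2 * d_hidden] = 1.0  # forget-gate bias
        self.b = Tensor(b, requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        """x: (B, T, d_in) -> stacked hidden states (B, T, d_hidden)."""
        B, T, _ = x.shape
        Hd = self.d_hidden
        h = Tensor(np.zeros((B, Hd)))
        c = Tensor(np.zeros((B, Hd)))
        hs: list[Tensor] = []
        for t in range(T):
            xt = x[:, t, :]
            gates = xt @ self.Wx + h @ self.Wh + self.b
            i = gates[:, 0 * Hd : 1 * Hd].sigmoid()
            f = gates[:, 1 * Hd : 2 * Hd].sigmoid()
            g = gates[:, 2 * Hd : 3 * Hd].tanh()
            o = gates[:, 3 * Hd : 4 * Hd].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            hs.append(h.reshape(B, 1, Hd))
        return Tensor.concat(hs, axis=1)


def bce_with_logits(z: Tensor, target: np.ndarray) -> Tensor:
    """Mean binary cross-entropy between sigmoid(z) and binary targets,
    computed stably from logits."""
    t = np.asarray(target, dtype=np.float64)
    zd = z.data
    loss = np.maximum(zd, 0.0) - zd * t + np.log1p(np.exp(-np.abs(zd)))
    n = zd.size

    def bwd(g):
        if z.requires_grad:
            sig = 1.0 / (1.0 + np.exp(-zd))
            z._accum(g * (sig - t) / n)

    return z._make(np.array(loss.mean()), (z,), bwd)


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
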