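"""Minimal reverse-mode autodiff over numpy plus a small transformer encoder.

Float64 throughout; sizes here are desk-scale (a few layers, tens of hidden
units), where numpy matmuls dominate and graph overhead is negligible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

Array = np.ndarray


def _unbroadcast(grad: Array, shape: tuple[int, ...]) -> Array:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data: Array | float,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Optional[Callable[[Array], None]] = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[Array] = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    # -- graph plumbing -----------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def _accum(self, g: Array) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        # iterative DFS post-order (recursion-free topological sort)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- ops ----------------------------------------------------------------

    @staticmethod
    def _lift(x: "Tensor | Array | float") -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g: Array) -> None:
            self._accum(_unbroadcast(g, self.shape))
            other._accum(_unbroadcast(g, other.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g: Array) -> None:
            self._accum(_unbroadcast(g * other.data, self.shape))
            other._accum(_unbroadcast(g * self.data, other.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bw(g: Array) -> None:
            self._accum(_unbroadcast(g / other.data, self.shape))
            other._accum(_unbroadcast(-g * self.data / other.data**2, other.shape))

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bw(g: Array) -> None:
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            self._accum(_unbroadcast(ga, self.shape))
            other._accum(_unbroadcast(gb, other.shape))

        out._backward = bw
        return out

    def exp(self):
        out = Tensor(np.exp(self.data), parents=(self,))
        out._backward = lambda g: self._accum(g * out.data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), parents=(self,))
        out._backward = lambda g: self._accum(g * (1.0 - out.data**2))
        return out

    def pow(self, k: float):
        out = Tensor(self.data**k, parents=(self,))
        out._backward = lambda g: self._accum(g * k * self.data ** (k - 1))
        return out

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bw(g: Array) -> None:
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], tuple):
            shape = shape[0]
        out = Tensor(self.data.reshape(shape), parents=(self,))
        out._backward = lambda g: self._accum(g.reshape(self.shape))
        return out

    def transpose(self, axes: Sequence[int]):
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), parents=(self,))
        out._backward = lambda g: self._accum(g.transpose(inv))
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], parents=(self,))

        def bw(g: Array) -> None:
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            self._accum(full)

        out._backward = bw
        return out

    def broadcast_to(self, shape):
        out = Tensor(np.broadcast_to(self.data, shape).copy(), parents=(self,))
        out._backward = lambda g: self._accum(_unbroadcast(g, self.shape))
        return out


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), parents=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]

    def bw(g: Array) -> None:
        pieces = np.split(g, np.cumsum(sizes)[:-1], axis=axis)
        for t, piece in zip(tensors, pieces):
            t._accum(piece)

    out._backward = bw
    return out


def embedding(weight: Tensor, ids: Array) -> Tensor:
    """Lookup rows of `weight` [V, D] by an integer array `ids` of any shape."""
    ids = np.asarray(ids, dtype=np.int64)
    out = Tensor(weight.data[ids], parents=(weight,))

    def bw(g: Array) -> None:
        full = np.zeros_like(weight.data)
        np.add.at(full, ids.reshape(-1), g.reshape(-1, weight.data.shape[-1]))
        weight._accum(full)

    out._backward = bw
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)  # detached max: gradient still exact
    e = (x - m).exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)
    shifted = x - m
    return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


def logsumexp(x: Tensor, axis: int = -1, keepdims: bool = False) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)
    out = (x - m).exp().sum(axis=axis, keepdims=True).log() + m
    if not keepdims:
        out = out.reshape(tuple(np.squeeze(out.data, axis=axis).shape))
    return out


def gelu(x: Tensor) -> Tensor:
    c = math.sqrt(2.0 / math.pi)
    return x * 0.5 * (1.0 + ((x + x.pow(3.0) * 0.044715) * c).tanh())


def dropout(x: Tensor, p: float, rng: Optional[np.random.Generator], training: bool) -> Tensor:
    if not training or p <= 0.0:
        return x
    if rng is None:
        raise ValueError("dropout in training mode requires an rng")
    keep = (rng.random(x.shape) >= p).astype(np.float64) / (1.0 - p)
    return x * Tensor(keep)


# ---------------------------------------------------------------------------
# Modules
# ---------------------------------------------------------------------------


class Module:
    """Tiny module base: named parameters, state dicts, train/eval flags."""

    def parameters(self) -> dict[str, Tensor]:
        params: dict[str, Tensor] = {}
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                params[name] = val
            elif isinstance(val, Module):
                for sub, p in val.parameters().items():
                    params[f"{name}.{sub}"] = p
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        for sub, p in item.parameters().items():
                            params[f"{name}.{i}.{sub}"] = p
        return params

    def state_dict(self) -> dict[str, Array]:
        return {k: v.data.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: dict[str, Array]) -> None:
        params = self.parameters()
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")
        for k, p in params.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}: {p.data.shape} vs {state[k].shape}")
            p.data = state[k].astype(np.float64).copy()

    def zero_grad(self) -> None:
        for p in self.parameters().values():
            p.zero_grad()


def _param(rng: np.random.Generator, *shape: int, scale: float = 0.02) -> Tensor:
    return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, rng: np.random.Generator, d_in: int, d_out: int):
        self.w = _param(rng, d_in, d_out)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.g = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + self.eps).pow(0.5) * self.g + self.beta


class TransformerLayer(Module):
    def __init__(self, rng: np.random.Generator, dim: int, n_heads: int, p_drop: float):
        if dim % n_heads:
            raise ValueError("hidden_dim must be divisible by n_heads")
        self.n_heads = n_heads
        self.dim = dim
        self.p_drop = p_drop
        self.wq = Linear(rng, dim, dim)
        self.wk = Linear(rng, dim, dim)
        self.wv = Linear(rng, dim, dim)
        self.wo = Linear(rng, dim, dim)
        self.ln1 = LayerNorm(dim)
        self.ff1 = Linear(rng, dim, 4 * dim)
        self.ff2 = Linear(rng, 4 * dim, dim)
        self.ln2 = LayerNorm(dim)

    def __call__(
        self,
        x: Tensor,
        attn_bias: Array,
        training: bool,
        rng: Optional[np.random.Generator],
    ) -> Tensor:
        B, T, D = x.shape
        H, dh = self.n_heads, D // self.n_heads

        def split_heads(t: Tensor) -> Tensor:
            return t.reshape(B, T, H, dh).transpose((0, 2, 1, 3))

        q, k, v = split_heads(self.wq(x)), split_heads(self.wk(x)), split_heads(self.wv(x))
        scores = q @ k.transpose((0, 1, 3, 2)) * (1.0 / math.sqrt(dh))
        scores = scores + Tensor(attn_bias)  # [B,1,1,T] additive pad mask
        attn = softmax(scores, axis=-1)
        attn = dropout(attn, self.p_drop, rng, training)
        ctx = (attn @ v).transpose((0, 2, 1, 3)).reshape(B, T, D)
        x = self.ln1(x + dropout(self.wo(ctx), self.p_drop, rng, training))
        ff = self.ff2(gelu(self.ff1(x)))
        return self.ln2(x + dropout(ff, self.p_drop, rng, training))


@dataclass(frozen=True)
class EncoderConfig:
    """Architecture of the trainable encoder (replaces a large pre-trained LM
    at desk scale; any checkpoint with this interface can be fine-tuned)."""

    vocab_size: int
    hidden_dim: int = 64
    n_layers: int = 2
    n_heads: int = 4
    max_len: int = 64
    dropout_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_dim % self.n_heads:
            raise ValueError("hidden_dim must be divisible by n_heads")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")

    def to_dict(self) -> dict:
        return {
            "vocab_size": self.vocab_size,
            "hidden_dim": self.hidden_dim,
            "n_layers": self.n_layers,
            "n_heads": self.n_heads,
            "max_len": self.max_len,
            "dropout_rate": self.dropout_rate,
            "seed": self.seed,
        }


class TransformerEncoder(Module):
    """Token + position embeddings followed by post-LN transformer layers."""

    def __init__(self, config: EncoderConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.tok_emb = _param(rng, config.vocab_size, config.hidden_dim)
        self.pos_emb = _param(rng, config.max_len, config.hidden_dim)
        self.layers = [
            TransformerLayer(rng, config.hidden_dim, config.n_heads, config.dropout_rate)
            for _ in range(config.n_layers)
        ]
        self.ln = LayerNorm(config.hidden_dim)

    def embed(self, ids: Array) -> Tensor:
        return embedding(self.tok_emb, ids)

    def __call__(
        self,
        ids: Array,
        pad_mask: Array,
        training: bool = False,
        rng: Optional[np.random.Generator] = None,
        token_emb_override: Optional[Tensor] = None,
    ) -> Tensor:
        """Encode ``ids`` [B, T] with boolean ``pad_mask`` [B, T] (True = real
        token). Returns hidden states [B, T, hidden_dim]."""
        B, T = ids.shape
        if T > self.config.max_len:
            raise ValueError(f"sequence length {T} exceeds max_len {self.config.max_len}")
        e = token_emb_override if token_emb_override is not None else self.embed(ids)
        e = e + embedding(self.pos_emb, np.broadcast_to(np.arange(T), (B, T)))
        x = self.ln(dropout(e, self.config.dropout_rate, rng, training))
        attn_bias = np.where(pad_mask, 0.0, -1e9)[:, None, None, :]
        for layer in self.layers:
            x = layer(x, attn_bias, training, rng)
        return x


class Adam:
    """Adam with linear warmup to a constant learning rate."""

    def __init__(
        self,
        params: dict[str, Tensor],
        lr: float = 1e-3,
        warmup_ratio: float = 0.1,
        total_steps: int = 0,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = params
        self.lr = lr
        self.warmup_steps = max(1, int(warmup_ratio * total_steps)) if total_steps else 0
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def current_lr(self) -> float:
        if self.warmup_steps and self.t < self.warmup_steps:
            return self.lr * (self.t + 1) / self.warmup_steps
        return self.lr

    def step(self) -> None:
        lr = self.current_lr()
        self.t += 1
        b1, b2 = self.betas
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()
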