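"""Neural building blocks: linear/conv layers, multi-head self-attention,
transformer encoder blocks and the Adam optimizer.

Parameters are plain `Tensor`s with `requires_grad=True`; modules expose
`parameters()` for the optimizer and `state_dict()`/`load_state_dict()` for
single-file `.npz` checkpoints. Initialisation is always drawn from an
explicit `numpy.random.Generator`, so identical seeds give identical models.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from ._autodiff import Tensor, concat, im2col

__all__ = [
    "Module",
    "Linear",
    "Conv2d",
    "MultiHeadSelfAttention",
    "TransformerBlock",
    "Adam",
    "cross_entropy",
]


class Module:
    """Base class with recursive parameter discovery and checkpointing."""

    def parameters(self) -> Iterator[Tensor]:
        for _, p in self.named_parameters():
            yield p

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad \
                    and value._backward is None:  # leaf tensors only
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix=full + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{full}.{i}.")

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise KeyError(f"checkpoint/model parameter mismatch: {sorted(missing)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, bias: bool = True):
        self.weight = Tensor(_glorot(rng, in_dim, out_dim, (in_dim, out_dim)), requires_grad=True)
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Conv2d(Module):
    """Stride-able 2D convolution over NCHW tensors via im2col."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int,
                 rng: np.random.Generator):
        fan_in = in_ch * kernel * kernel
        self.weight = Tensor(
            _glorot(rng, fan_in, out_ch, (fan_in, out_ch)), requires_grad=True
        )
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True)
        self.kernel = kernel
        self.stride = stride
        self.out_ch = out_ch

    def __call__(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        k, s = self.kernel, self.stride
        ho = (H - k) // s + 1
        wo = (W - k) // s + 1
        cols = im2col(x, k, k, s)                     # (B, ho*wo, C*k*k)
        out = cols @ self.weight + self.bias          # (B, ho*wo, out_ch)
        return out.reshape(B, ho, wo, self.out_ch).transpose(0, 3, 1, 2)


class MultiHeadSelfAttention(Module):
    """Self-attention over an unbatched (T, d) token sequence.

    The post-softmax attention tensor of the most recent forward pass is kept
    on `last_attention` (with `retain_grad()`), so that gradient-weighted
    attention relevance can be read off after a backward pass.
    """

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        if dim % n_heads:
            raise ValueError(f"embed dim {dim} not divisible by {n_heads} heads")
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)
        self.last_attention: Tensor | None = None

    def __call__(self, x: Tensor) -> Tensor:
        T, d = x.shape
        h, hd = self.n_heads, self.head_dim
        qkv = self.qkv(x).reshape(T, 3, h, hd).transpose(1, 2, 0, 3)  # (3, h, T, hd)
        q, k, v = qkv[0], qkv[1], qkv[2]
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / math.sqrt(hd))     # (h, T, T)
        attn = scores.softmax(axis=-1)
        attn.retain_grad()
        self.last_attention = attn
        out = (attn @ v).transpose(1, 0, 2).reshape(T, d)
        return self.proj(out)


class _Mlp(Module):
    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())


class TransformerBlock(Module):
    """Pre-LayerNorm encoder block: x + MHSA(LN(x)), then x + MLP(LN(x))."""

    def __init__(self, dim: int, n_heads: int, mlp_dim: int, rng: np.random.Generator):
        self.attn = MultiHeadSelfAttention(dim, n_heads, rng)
        self.mlp = _Mlp(dim, mlp_dim, rng)
        self.ln1_g = Tensor(np.ones(dim), requires_grad=True)
        self.ln1_b = Tensor(np.zeros(dim), requires_grad=True)
        self.ln2_g = Tensor(np.ones(dim), requires_grad=True)
        self.ln2_b = Tensor(np.zeros(dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        x = x + self.attn(x.layer_norm() * self.ln1_g + self.ln1_b)
        x = x + self.mlp(x.layer_norm() * self.ln2_g + self.ln2_b)
        return x


def cross_entropy(logits: Tensor, target: int) -> Tensor:
    """Negative log-likelihood of `target` under softmax(logits) (1D logits)."""
    logp = logits - (logits.exp().sum()).log()
    return -logp[target]


class Adam:
    """Adam with decoupled-style L2 weight decay added to the gradient."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
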