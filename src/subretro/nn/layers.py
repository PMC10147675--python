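"""Neural layers: linear/embedding/layer-norm, multi-head attention and
pre-norm Transformer encoder/decoder stacks, built on the autograd core.

The architecture follows the standard Transformer: each encoder block is a
self-attention module plus a position-wise feed-forward network with residual
connections; decoder blocks add causal self-attention and cross-attention
over the encoder memory.  Pre-layer-norm placement is used for stable
training at small scale.
"""

from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor, log_softmax, softmax

NEG_INF = -1e9


class Module:
    """Base class with recursive parameter collection."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            params.extend(_collect(value))
        return params


def _collect(value) -> list[Tensor]:
    if isinstance(value, Tensor) and value.requires_grad:
        return [value]
    if isinstance(value, Module):
        return value.parameters()
    if isinstance(value, (list, tuple)):
        out: list[Tensor] = []
        for item in value:
            out.extend(_collect(item))
        return out
    return []


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        scale = math.sqrt(1.0 / d_in)
        self.weight = Tensor(
            rng.uniform(-scale, scale, size=(d_in, d_out)), requires_grad=True
        )
        self.bias = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Embedding(Module):
    def __init__(self, vocab_size: int, d: int, rng: np.random.Generator):
        self.weight = Tensor(
            rng.normal(0.0, 1.0 / math.sqrt(d), size=(vocab_size, d)),
            requires_grad=True,
        )

    def __call__(self, ids: np.ndarray) -> Tensor:
        return self.weight[ids]


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        self.gain = Tensor(np.ones(d), requires_grad=True)
        self.offset = Tensor(np.zeros(d), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered * (var + self.eps).pow(-0.5) * self.gain + self.offset


class MultiHeadAttention(Module):
    def __init__(self, d: int, num_heads: int, rng: np.random.Generator):
        if d % num_heads:
            raise ValueError(f"hidden size {d} not divisible by {num_heads} heads")
        self.num_heads = num_heads
        self.d_head = d // num_heads
        self.q = Linear(d, d, rng)
        self.k = Linear(d, d, rng)
        self.v = Linear(d, d, rng)
        self.out = Linear(d, d, rng)

    def _split(self, x: Tensor, batch: int, length: int) -> Tensor:
        return x.reshape(batch, length, self.num_heads, self.d_head).transpose(
            0, 2, 1, 3
        )

    def __call__(self, query: Tensor, memory: Tensor, mask: np.ndarray | None) -> Tensor:
        """``mask`` is an additive bias broadcastable to (B, 1, Tq, Tk)."""
        batch, t_q = query.shape[0], query.shape[1]
        t_k = memory.shape[1]
        q = self._split(self.q(query), batch, t_q)
        k = self._split(self.k(memory), batch, t_k)
        v = self._split(self.v(memory), batch, t_k)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(self.d_head))
        if mask is not None:
            scores = scores + Tensor(mask)
        attn = softmax(scores, axis=-1)
        context = (attn @ v).transpose(0, 2, 1, 3).reshape(batch, t_q, -1)
        return self.out(context)


class FeedForward(Module):
    def __init__(self, d: int, d_ff: int, rng: np.random.Generator):
        self.inner = Linear(d, d_ff, rng)
        self.outer = Linear(d_ff, d, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.outer(self.inner(x).relu())


class EncoderBlock(Module):
    def __init__(self, d: int, d_ff: int, num_heads: int, rng: np.random.Generator):
        self.norm1 = LayerNorm(d)
        self.attn = MultiHeadAttention(d, num_heads, rng)
        self.norm2 = LayerNorm(d)
        self.ffn = FeedForward(d, d_ff, rng)

    def __call__(self, x: Tensor, mask: np.ndarray | None) -> Tensor:
        h = self.norm1(x)
        x = x + self.attn(h, h, mask)
        return x + self.ffn(self.norm2(x))


class DecoderBlock(Module):
    def __init__(self, d: int, d_ff: int, num_heads: int, rng: np.random.Generator):
        self.norm1 = LayerNorm(d)
        self.self_attn = MultiHeadAttention(d, num_heads, rng)
        self.norm2 = LayerNorm(d)
        self.cross_attn = MultiHeadAttention(d, num_heads, rng)
        self.norm3 = LayerNorm(d)
        self.ffn = FeedForward(d, d_ff, rng)

    def __call__(
        self,
        x: Tensor,
        memory: Tensor,
        self_mask: np.ndarray | None,
        cross_mask: np.ndarray | None,
    ) -> Tensor:
        h = self.norm1(x)
        x = x + self.self_attn(h, h, self_mask)
        x = x + self.cross_attn(self.norm2(x), memory, cross_mask)
        return x + self.ffn(self.norm3(x))


def padding_mask(lengths: np.ndarray, max_len: int) -> np.ndarray:
    """Additive key mask (B, 1, 1, T): 0 on real tokens, NEG_INF on padding."""
    positions = np.arange(max_len)[None, :]
    mask = np.where(positions < lengths[:, None], 0.0, NEG_INF)
    return mask[:, None, None, :]


def causal_mask(length: int) -> np.ndarray:
    mask = np.triu(np.full((length, length), NEG_INF), k=1)
    return mask[None, None, :, :]


class TransformerEncoder(Module):
    """Token + learned positional embeddings followed by ``L`` encoder blocks.

    If ``embedding_size`` differs from ``hidden_size`` a linear projection
    bridges the two (the embedding and hidden widths are configured
    independently).
    """

    def __init__(
        self,
        vocab_size: int,
        embedding_size: int,
        hidden_size: int,
        feedforward_size: int,
        num_blocks: int,
        num_heads: int,
        max_len: int,
        rng: np.random.Generator,
    ):
        self.embed = Embedding(vocab_size, embedding_size, rng)
        self.pos = Embedding(max_len, embedding_size, rng)
        self.project = (
            Linear(embedding_size, hidden_size, rng)
            if embedding_size != hidden_size
            else None
        )
        self.blocks = [
            EncoderBlock(hidden_size, feedforward_size, num_heads, rng)
            for _ in range(num_blocks)
        ]
        self.final_norm = LayerNorm(hidden_size)
        self.scale = math.sqrt(embedding_size)
        self.max_len = max_len

    def __call__(self, ids: np.ndarray, lengths: np.ndarray) -> Tensor:
        if ids.shape[1] > self.max_len:
            raise ValueError(f"sequence length {ids.shape[1]} exceeds {self.max_len}")
        x = self.embed(ids) * self.scale + self.pos(np.arange(ids.shape[1]))
        if self.project is not None:
            x = self.project(x)
        mask = padding_mask(lengths, ids.shape[1])
        for block in self.blocks:
            x = block(x, mask)
        return self.final_norm(x)


class TransformerDecoder(Module):
    def __init__(
        self,
        vocab_size: int,
        embedding_size: int,
        hidden_size: int,
        feedforward_size: int,
        num_blocks: int,
        num_heads: int,
        max_len: int,
        rng: np.random.Generator,
    ):
        self.embed = Embedding(vocab_size, embedding_size, rng)
        self.pos = Embedding(max_len, embedding_size, rng)
        self.project = (
            Linear(embedding_size, hidden_size, rng)
            if embedding_size != hidden_size
            else None
        )
        self.blocks = [
            DecoderBlock(hidden_size, feedforward_size, num_heads, rng)
            for _ in range(num_blocks)
        ]
        self.final_norm = LayerNorm(hidden_size)
        self.out = Linear(hidden_size, vocab_size, rng)
        self.scale = math.sqrt(embedding_size)
        self.max_len = max_len

    def __call__(
        self,
        ids: np.ndarray,
        memory: Tensor,
        memory_lengths: np.ndarray,
    ) -> Tensor:
        """Return logits (B, T, V) for next-token prediction at each position."""
        t = ids.shape[1]
        if t > self.max_len:
            raise ValueError(f"sequence length {t} exceeds {self.max_len}")
        x = self.embed(ids) * self.scale + self.pos(np.arange(t))
        if self.project is not None:
            x = self.project(x)
        self_mask = causal_mask(t)
        cross_mask = padding_mask(memory_lengths, memory.shape[1])
        for block in self.blocks:
            x = block(x, memory, self_mask, cross_mask)
        return self.out(self.final_norm(x))


def label_smoothed_nll(
    logits: Tensor,
    targets: np.ndarray,
    token_mask: np.ndarray,
    smoothing: float,
) -> Tensor:
    """Label-smoothed cross-entropy averaged over unmasked positions.

    ``logits`` (N, V), ``targets`` (N,), ``token_mask`` (N,) with 1 on real
    tokens.  Smoothed target distribution: ``1 - eps`` on the gold token and
    ``eps / V`` spread uniformly.
    """
    logp = log_softmax(logits, axis=-1)
    n, vocab = logits.shape
    gold = logp[np.arange(n), targets]
    uniform = logp.mean(axis=-1)
    per_token = -(1.0 - smoothing) * gold - smoothing * uniform
    mask = Tensor(token_mask.astype(np.float64))
    return (per_token * mask).sum() * (1.0 / max(token_mask.sum(), 1))
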