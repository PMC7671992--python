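"""Transformer encoder-decoder with exportable attention weights.

Attention is the scaled dot product Attn(Q, K, V) = softmax(Q K^T / sqrt(d_K)) V
applied in parallel over heads; sinusoidal positional encodings are added to
the scaled word embeddings before the encoder and decoder stacks.  The
``paper`` preset mirrors the standard base configuration (d_model 512,
8 heads, 6 layers, feed-forward 2048); the ``desk`` preset (64/4/2/256) is
small enough to train on one CPU in seconds and is used throughout the
tests and examples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .layers import Dropout, Embedding, LayerNorm, Linear, Module

__all__ = [
    "TransformerConfig",
    "scaled_dot_product_attention",
    "sinusoidal_encoding",
    "Transformer",
]


@dataclass
class TransformerConfig:
    vocab_size: int
    d_model: int = 512
    n_heads: int = 8
    n_layers: int = 6
    d_ff: int = 2048
    dropout: float = 0.1
    max_len: int = 12

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")

    @property
    def d_k(self) -> int:
        return self.d_model // self.n_heads

    @classmethod
    def paper(cls, vocab_size: int) -> "TransformerConfig":
        return cls(vocab_size=vocab_size)

    @classmethod
    def desk(cls, vocab_size: int) -> "TransformerConfig":
        return cls(vocab_size=vocab_size, d_model=64, n_heads=4, n_layers=2, d_ff=256)


def scaled_dot_product_attention(
    Q: Tensor | np.ndarray,
    K: Tensor | np.ndarray,
    V: Tensor | np.ndarray,
    d_k: int | None = None,
    mask: np.ndarray | None = None,
) -> tuple[Tensor, np.ndarray]:
    """softmax(Q K^T / sqrt(d_k)) V.

    Returns the weighted values and the attention-weight matrix (as a plain
    array, detached) whose rows are probability vectors.  An optional
    additive boolean mask marks forbidden key positions.
    """
    Q = Q if isinstance(Q, Tensor) else Tensor(Q)
    K = K if isinstance(K, Tensor) else Tensor(K)
    V = V if isinstance(V, Tensor) else Tensor(V)
    if d_k is None:
        d_k = Q.shape[-1]
    if d_k <= 0:
        raise ValueError(f"d_k must be positive, got {d_k}")
    scores = Q @ K.transpose(*range(K.ndim - 2), K.ndim - 1, K.ndim - 2)
    scores = scores * (1.0 / np.sqrt(d_k))
    if mask is not None:
        scores = scores + Tensor(np.where(mask, -1e9, 0.0))
    weights = scores.softmax(axis=-1)
    return weights @ V, weights.data.copy()


def sinusoidal_encoding(max_len: int, d_model: int) -> np.ndarray:
    pos = np.arange(max_len)[:, None]
    i = np.arange(d_model // 2)[None, :]
    angle = pos / np.power(10000.0, 2 * i / d_model)
    enc = np.zeros((max_len, d_model))
    enc[:, 0::2] = np.sin(angle)
    enc[:, 1::2] = np.cos(angle)
    return enc


class MultiHeadAttention(Module):
    def __init__(self, config: TransformerConfig, rng: np.random.Generator):
        d = config.d_model
        self.wq = Linear(d, d, rng)
        self.wk = Linear(d, d, rng)
        self.wv = Linear(d, d, rng)
        self.wo = Linear(d, d, rng)
        self.n_heads = config.n_heads
        self.d_k = config.d_k
        self.last_weights: np.ndarray | None = None

    def _split(self, x: Tensor) -> Tensor:
        B, T, _ = x.shape
        return x.reshape(B, T, self.n_heads, self.d_k).transpose(0, 2, 1, 3)

    def __call__(
        self, q: Tensor, kv: Tensor, mask: np.ndarray | None = None
    ) -> Tensor:
        B, Tq, d = q.shape
        heads_q = self._split(self.wq(q))
        heads_k = self._split(self.wk(kv))
        heads_v = self._split(self.wv(kv))
        out, weights = scaled_dot_product_attention(
            heads_q, heads_k, heads_v, self.d_k, mask=mask
        )
        self.last_weights = weights  # (B, heads, Tq, Tk) for inspection
        merged = out.transpose(0, 2, 1, 3).reshape(B, Tq, d)
        return self.wo(merged)


class FeedForward(Module):
    def __init__(self, config: TransformerConfig, rng: np.random.Generator):
        self.lin1 = Linear(config.d_model, config.d_ff, rng)
        self.lin2 = Linear(config.d_ff, config.d_model, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.lin2(self.lin1(x).relu())


class EncoderLayer(Module):
    def __init__(self, config: TransformerConfig, rng: np.random.Generator):
        self.attn = MultiHeadAttention(config, rng)
        self.ff = FeedForward(config, rng)
        self.norm1 = LayerNorm(config.d_model)
        self.norm2 = LayerNorm(config.d_model)
        self.drop = Dropout(config.dropout)

    def __call__(self, x: Tensor, mask: np.ndarray | None) -> Tensor:
        x = self.norm1(x + self.drop(self.attn(x, x, mask)))
        return self.norm2(x + self.drop(self.ff(x)))


class DecoderLayer(Module):
    def __init__(self, config: TransformerConfig, rng: np.random.Generator):
        self.self_attn = MultiHeadAttention(config, rng)
        self.cross_attn = MultiHeadAttention(config, rng)
        self.ff = FeedForward(config, rng)
        self.norm1 = LayerNorm(config.d_model)
        self.norm2 = LayerNorm(config.d_model)
        self.norm3 = LayerNorm(config.d_model)
        self.drop = Dropout(config.dropout)

    def __call__(
        self,
        x: Tensor,
        memory: Tensor,
        self_mask: np.ndarray | None,
        cross_mask: np.ndarray | None,
    ) -> Tensor:
        x = self.norm1(x + self.drop(self.self_attn(x, x, self_mask)))
        x = self.norm2(x + self.drop(self.cross_attn(x, memory, cross_mask)))
        return self.norm3(x + self.drop(self.ff(x)))


class Transformer(Module):
    """Encoder-decoder transformer over navigation-sentence tokens."""

    def __init__(self, config: TransformerConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.embedding = Embedding(config.vocab_size, config.d_model, rng)
        self.pos = sinusoidal_encoding(config.max_len + 2, config.d_model)
        self.enc_layers = [EncoderLayer(config, rng) for _ in range(config.n_layers)]
        self.dec_layers = [DecoderLayer(config, rng) for _ in range(config.n_layers)]
        self.out_proj = Linear(config.d_model, config.vocab_size, rng)
        self._scale = np.sqrt(config.d_model)

    @property
    def d_model(self) -> int:
        return self.config.d_model

    def set_dropout_rng(self, rng: np.random.Generator | None) -> None:
        """Arm (training) or disarm (inference) dropout."""
        for layer in self.enc_layers + self.dec_layers:
            for attr in vars(layer).values():
                if isinstance(attr, Dropout):
                    attr.rng = rng

    def _embed(self, ids: np.ndarray) -> Tensor:
        T = ids.shape[1]
        return self.embedding(ids) * self._scale + Tensor(self.pos[:T])

    def forward_log_probs(
        self,
        src: np.ndarray,
        src_mask: np.ndarray,
        tgt_in: np.ndarray,
    ) -> Tensor:
        """Teacher-forced log-probabilities, shape (B, T_tgt, V).

        ``src_mask`` is (B, T_src) with True at real tokens; the decoder
        self-attention is causal.
        """
        B, Ts = src.shape
        Tt = tgt_in.shape[1]
        pad_mask = ~src_mask[:, None, None, :]  # (B, 1, 1, Ts)
        causal = np.triu(np.ones((Tt, Tt), dtype=bool), k=1)[None, None]
        memory = self._embed(src)
        for layer in self.enc_layers:
            memory = layer(memory, pad_mask)
        x = self._embed(tgt_in)
        for layer in self.dec_layers:
            x = layer(x, memory, causal, pad_mask)
        return self.out_proj(x).log_softmax(axis=-1)

    def next_word_distribution(
        self, src_ids: list[int], prefix_ids: list[int]
    ) -> np.ndarray:
        """p(next token | source, generated prefix), dropout disarmed."""
        if len(prefix_ids) > self.config.max_len + 1:
            raise ValueError("prefix longer than maximum decoding length")
        self.set_dropout_rng(None)
        src = np.asarray([src_ids])
        mask = np.ones_like(src, dtype=bool)
        log_probs = self.forward_log_probs(src, mask, np.asarray([prefix_ids]))
        return np.exp(log_probs.data[0, -1])

    def attention_maps(self) -> dict[str, np.ndarray]:
        """Attention weights of the last forward pass, per layer and kind."""
        maps: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.enc_layers):
            if layer.attn.last_weights is not None:
                maps[f"encoder{i}.self"] = layer.attn.last_weights
        for i, layer in enumerate(self.dec_layers):
            if layer.self_attn.last_weights is not None:
                maps[f"decoder{i}.self"] = layer.self_attn.last_weights
            if layer.cross_attn.last_weights is not None:
                maps[f"decoder{i}.cross"] = layer.cross_attn.last_weights
        return maps
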