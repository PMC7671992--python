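"""GRU encoder-decoder for next-sentence translation.

The standard sequence-to-sequence baseline: a stacked GRU encoder maps the
source sentence x = (x_0..x_n) to hidden states whose final values
initialize a stacked GRU decoder, which emits the target sentence one word
at a time (autoregressive factorization p(y|x) = prod_i p(y_i | y_<i, x)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, stack
from .layers import Embedding, Linear, Module

__all__ = ["EncoderDecoderConfig", "GRUCell", "GRUStack", "Seq2SeqGRU"]


@dataclass
class EncoderDecoderConfig:
    """Architecture of the GRU encoder-decoder.

    Defaults follow the full-scale setup (two layers of 512 units in both
    encoder and decoder); ``desk()`` gives a CPU-friendly preset used for
    testing and examples.
    """

    vocab_size: int
    layers: int = 2
    hidden_units: int = 512
    embedding_dim: int = 256
    max_len: int = 12

    def __post_init__(self) -> None:
        if min(self.vocab_size, self.layers, self.hidden_units, self.embedding_dim) < 1:
            raise ValueError("config dimensions must be positive integers")

    @classmethod
    def desk(cls, vocab_size: int) -> "EncoderDecoderConfig":
        return cls(vocab_size=vocab_size, hidden_units=64, embedding_dim=32)


class GRUCell(Module):
    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator):
        self.x2gates = Linear(d_in, 2 * d_hidden, rng)
        self.h2gates = Linear(d_hidden, 2 * d_hidden, rng)
        self.x2cand = Linear(d_in, d_hidden, rng)
        self.h2cand = Linear(d_hidden, d_hidden, rng)
        self.d_hidden = d_hidden

    def __call__(self, x: Tensor, h: Tensor) -> Tensor:
        gates = (self.x2gates(x) + self.h2gates(h)).sigmoid()
        z = gates[..., : self.d_hidden]
        r = gates[..., self.d_hidden :]
        n = (self.x2cand(x) + self.h2cand(r * h)).tanh()
        return (1.0 - z) * n + z * h


class GRUStack(Module):
    def __init__(self, d_in: int, d_hidden: int, layers: int, rng: np.random.Generator):
        self.cells = [
            GRUCell(d_in if i == 0 else d_hidden, d_hidden, rng) for i in range(layers)
        ]
        self.d_hidden = d_hidden

    def __call__(
        self,
        x_seq: Tensor,
        mask: np.ndarray | None = None,
        h0: list[Tensor] | None = None,
    ) -> tuple[Tensor, list[Tensor]]:
        """Run over a (B, T, d) input; returns (B, T, H) outputs and finals.

        With a (B, T) mask, hidden states freeze once a sequence is padded,
        so the final hidden state is the one at each sequence's true length.
        """
        B, T, _ = x_seq.shape
        hs = h0 if h0 is not None else [
            Tensor(np.zeros((B, cell.d_hidden))) for cell in self.cells
        ]
        hs = list(hs)
        outputs: list[Tensor] = []
        for t in range(T):
            inp = x_seq[:, t, :]
            m = None if mask is None else Tensor(mask[:, t : t + 1].astype(float))
            for i, cell in enumerate(self.cells):
                new_h = cell(inp, hs[i])
                if m is not None:
                    new_h = m * new_h + (1.0 - m) * hs[i]
                hs[i] = new_h
                inp = new_h
            outputs.append(hs[-1])
        return stack(outputs, axis=1), hs


class Seq2SeqGRU(Module):
    """Two-stack GRU encoder-decoder over navigation-sentence tokens."""

    def __init__(self, config: EncoderDecoderConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        V, E, H = config.vocab_size, config.embedding_dim, config.hidden_units
        self.embedding = Embedding(V, E, rng)
        self.encoder = GRUStack(E, H, config.layers, rng)
        self.decoder = GRUStack(E, H, config.layers, rng)
        self.out_proj = Linear(H, V, rng)

    @property
    def d_model(self) -> int:
        return self.config.embedding_dim

    def encode(self, src: np.ndarray, src_mask: np.ndarray) -> list[Tensor]:
        emb = self.embedding(src)
        _, finals = self.encoder(emb, mask=src_mask)
        return finals

    def forward_log_probs(
        self,
        src: np.ndarray,
        src_mask: np.ndarray,
        tgt_in: np.ndarray,
    ) -> Tensor:
        """Teacher-forced log-probabilities, shape (B, T_tgt, V)."""
        finals = self.encode(src, src_mask)
        dec_out, _ = self.decoder(self.embedding(tgt_in), h0=finals)
        return self.out_proj(dec_out).log_softmax(axis=-1)

    def next_word_distribution(
        self, src_ids: list[int], prefix_ids: list[int]
    ) -> np.ndarray:
        """p(next token | source, generated prefix) as a probability vector.

        ``src_ids`` and ``prefix_ids`` are special-token-framed index
        sequences; the prefix starts with SOS.
        """
        if len(prefix_ids) > self.config.max_len + 1:
            raise ValueError("prefix longer than maximum decoding length")
        src = np.asarray([src_ids])
        mask = np.ones_like(src, dtype=bool)
        tgt_in = np.asarray([prefix_ids])
        log_probs = self.forward_log_probs(src, mask, tgt_in)
        return np.exp(log_probs.data[0, -1])
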