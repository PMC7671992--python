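"""LSTM baseline: next landmark-combination class from a 6-step window."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, stack
from .layers import Embedding, Linear, Module

__all__ = ["LSTMConfig", "LSTMClassifier"]


@dataclass
class LSTMConfig:
    """Two-layer LSTM over class-id windows of fixed length 6."""

    n_classes: int
    layers: int = 2
    hidden_units: int = 200
    window_length: int = 6
    embedding_dim: int = 32

    def __post_init__(self) -> None:
        if self.window_length < 1:
            raise ValueError("window_length must be >= 1")

    @classmethod
    def desk(cls, n_classes: int) -> "LSTMConfig":
        return cls(n_classes=n_classes, hidden_units=64)


class LSTMCell(Module):
    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator):
        self.x2g = Linear(d_in, 4 * d_hidden, rng)
        self.h2g = Linear(d_hidden, 4 * d_hidden, rng)
        self.d_hidden = d_hidden

    def __call__(self, x, h, c):
        H = self.d_hidden
        g = self.x2g(x) + self.h2g(h)
        i = g[..., :H].sigmoid()
        f = g[..., H : 2 * H].sigmoid()
        o = g[..., 2 * H : 3 * H].sigmoid()
        cand = g[..., 3 * H :].tanh()
        c_new = f * c + i * cand
        return o * c_new.tanh(), c_new


class LSTMClassifier(Module):
    """Stacked LSTM mapping a window of class ids to a class distribution.

    Windows shorter than the configured length are left-padded with a
    dedicated PAD class (index ``n_classes`` in the input embedding); the
    output layer only ranges over the real classes, so PAD is never
    predicted.
    """

    def __init__(self, config: LSTMConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.pad_class = config.n_classes
        self.embedding = Embedding(config.n_classes + 1, config.embedding_dim, rng)
        self.cells = [
            LSTMCell(
                config.embedding_dim if i == 0 else config.hidden_units,
                config.hidden_units,
                rng,
            )
            for i in range(config.layers)
        ]
        self.out_proj = Linear(config.hidden_units, config.n_classes, rng)

    @property
    def d_model(self) -> int:
        return self.config.hidden_units

    def pad_window(self, window: list[int]) -> list[int]:
        n = self.config.window_length
        w = list(window)[-n:]
        return [self.pad_class] * (n - len(w)) + w

    def forward_log_probs(self, windows: np.ndarray) -> Tensor:
        """Log-probabilities over classes for a (B, window_length) batch."""
        B, T = windows.shape
        if T != self.config.window_length:
            raise ValueError(
                f"window length {T} != configured {self.config.window_length}"
            )
        emb = self.embedding(windows)
        hs = [Tensor(np.zeros((B, c.d_hidden))) for c in self.cells]
        cs = [Tensor(np.zeros((B, c.d_hidden))) for c in self.cells]
        for t in range(T):
            inp = emb[:, t, :]
            for i, cell in enumerate(self.cells):
                hs[i], cs[i] = cell(inp, hs[i], cs[i])
                inp = hs[i]
        return self.out_proj(hs[-1]).log_softmax(axis=-1)

    def predict_next_distribution(self, window: list[int]) -> np.ndarray:
        """Probability vector over classes given the (padded) window."""
        w = np.asarray([self.pad_window(window)])
        return np.exp(self.forward_log_probs(w).data[0])
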