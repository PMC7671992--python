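"""Parameterized building blocks shared by the neural predictors."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["Module", "Linear", "Embedding", "LayerNorm", "Dropout"]


class Module:
    """Bare-bones parameter container."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        scale = np.sqrt(1.0 / d_in)
        self.W = Tensor(rng.uniform(-scale, scale, size=(d_in, d_out)), True)
        self.b = Tensor(np.zeros(d_out), True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class Embedding(Module):
    def __init__(self, n_tokens: int, dim: int, rng: np.random.Generator):
        self.W = Tensor(rng.normal(0.0, 0.02, size=(n_tokens, dim)), True)

    def __call__(self, indices: np.ndarray) -> Tensor:
        return self.W.take_rows(np.asarray(indices))


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.g = Tensor(np.ones(dim), True)
        self.b = Tensor(np.zeros(dim), True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + self.eps) ** 0.5 * self.g + self.b


class Dropout:
    """Inverted dropout; active only when an rng is armed (training)."""

    def __init__(self, p: float):
        self.p = p
        self.rng: np.random.Generator | None = None

    def __call__(self, x: Tensor) -> Tensor:
        if self.rng is None or self.p <= 0.0:
            return x
        keep = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(keep)
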