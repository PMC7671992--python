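"""Sentence generation: beam search with recurrence-decay rescoring.

FESS navigation revisits the same landmarks many times, so a translator
that simply maximizes likelihood tends to repeat the over-represented
tokens indefinitely.  Decoding therefore rescores each word candidate y by
an exponential decay in its *recurrence count*: with r_y the current number
of consecutive preceding sentences containing y and r_mean(y) the mean run
length of y in the training corpus,

    d(y) = 1 - exp(-r_y / r_mean(y))

and the candidate's log-likelihood is degraded by the decay.  The default
score is log p(y|x) + log(1 - d(y)), i.e. the probability is multiplied by
the survival factor (1 - d); the literal product form
s = log p(y|x) * (1 - d(y)) is available as ``paper_literal`` (for negative
log-likelihoods that form *rewards* recurring tokens, which contradicts the
penalization intent, so it is not the default).

Beam search keeps ``beam_size`` hypotheses (default 4 — the vocabulary is
small), terminates hypotheses on EOS or at the maximum sentence length, and
breaks score ties by shorter hypothesis first, then lexicographic token
order.  Multi-step rollout feeds each generated sentence back as the next
source while maintaining the recurrence counts across the series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .sentences import MAX_TOKENS, Sentence, Vocabulary

__all__ = [
    "RecurrenceStats",
    "DecayBeamConfig",
    "decay_penalty",
    "rescore",
    "BeamHypothesis",
    "beam_search",
    "greedy_decode",
    "rollout",
]


class RecurrenceStats:
    """Mean training run length per token.

    A *run* of token y is a maximal streak of consecutive sentences of one
    workflow that all contain y (tokens live in fixed template slots, so
    containment and slot-persistence coincide).  ``r_mean`` is the mean run
    length, floored at 1 so the decay ratio is always defined.
    """

    def __init__(self, mean_runs: dict[str, float] | None = None):
        self._mean = {k: max(1.0, v) for k, v in (mean_runs or {}).items()}

    @classmethod
    def from_sentence_series(
        cls, series: Iterable[Sequence[Sentence]]
    ) -> "RecurrenceStats":
        runs: dict[str, list[int]] = {}
        for sentences in series:
            active: dict[str, int] = {}
            for sent in sentences:
                present = set(sent)
                for tok in list(active):
                    if tok not in present:
                        runs.setdefault(tok, []).append(active.pop(tok))
                for tok in present:
                    active[tok] = active.get(tok, 0) + 1
            for tok, n in active.items():
                runs.setdefault(tok, []).append(n)
        return cls({t: sum(v) / len(v) for t, v in runs.items()})

    def r_mean(self, token: str) -> float:
        return self._mean.get(token, 1.0)

    def to_dict(self) -> dict[str, float]:
        return dict(self._mean)


@dataclass
class DecayBeamConfig:
    beam_size: int = 4
    decay_enabled: bool = True
    score_mode: str = "log_additive"  # or "paper_literal"
    max_len: int = MAX_TOKENS

    def __post_init__(self) -> None:
        if self.beam_size < 1:
            raise ValueError("beam_size must be >= 1")
        if self.score_mode not in ("log_additive", "paper_literal"):
            raise ValueError(f"unknown score mode {self.score_mode!r}")


def decay_penalty(r_y: float, r_mean: float) -> float:
    """d = 1 - exp(-r_y / r_mean); monotone increasing in r_y, in [0, 1)."""
    if r_y < 0:
        raise ValueError("recurrence count must be non-negative")
    if r_mean < 1:
        raise ValueError("r_mean must be >= 1")
    return 1.0 - math.exp(-r_y / r_mean)


def rescore(log_prob: float, d: float, mode: str = "log_additive") -> float:
    """Degrade a candidate's log-likelihood by the decay factor."""
    if log_prob > 0:
        raise ValueError("log_prob must be <= 0")
    if mode == "paper_literal":
        return log_prob * (1.0 - d)
    if d >= 1.0:
        return -math.inf
    return log_prob + math.log(1.0 - d)


@dataclass
class BeamHypothesis:
    tokens: tuple[str, ...]
    score: float
    complete: bool = False

    def sort_key(self):
        # higher score first; ties: shorter, then lexicographic tokens
        return (-self.score, len(self.tokens), self.tokens)


def _candidate_score(
    token: str,
    log_prob: float,
    config: DecayBeamConfig,
    stats: RecurrenceStats | None,
    counts: dict[str, int] | None,
) -> float:
    if not config.decay_enabled or stats is None:
        return log_prob
    r_y = 0 if counts is None else counts.get(token, 0)
    d = decay_penalty(r_y, stats.r_mean(token))
    return rescore(log_prob, d, config.score_mode)


def beam_search(
    model,
    source: Sentence,
    vocab: Vocabulary,
    config: DecayBeamConfig | None = None,
    stats: RecurrenceStats | None = None,
    counts: dict[str, int] | None = None,
) -> tuple[Sentence, list[BeamHypothesis], bool]:
    """Decode the most likely next sentence for one source sentence.

    Returns (best sentence, final beam, completed flag); ``completed`` is
    False when no hypothesis emitted EOS within the maximum length and the
    best partial hypothesis is returned instead.  ``counts`` are the running
    recurrence counts of the sentence series the source belongs to.
    """
    config = config or DecayBeamConfig()
    src_ids = vocab.encode(source)
    beam = [BeamHypothesis(tokens=(), score=0.0)]
    for _ in range(config.max_len + 1):
        candidates: list[BeamHypothesis] = []
        for hyp in beam:
            if hyp.complete:
                candidates.append(hyp)
                continue
            prefix = [vocab.SOS] + [vocab.index(t) for t in hyp.tokens]
            probs = model.next_word_distribution(src_ids, prefix)
            log_probs = np.log(np.maximum(probs, 1e-300))
            for idx in range(len(vocab)):
                if idx in (vocab.PAD, vocab.SOS, vocab.UNK):
                    continue  # specials are never emitted as words
                if probs[idx] <= 0.0:
                    continue  # impossible candidates cannot complete a path
                if idx == vocab.EOS:
                    candidates.append(
                        BeamHypothesis(hyp.tokens, hyp.score + log_probs[idx], True)
                    )
                    continue
                tok = vocab.token(idx)
                s = _candidate_score(
                    tok, float(log_probs[idx]), config, stats, counts
                )
                if len(hyp.tokens) + 1 > config.max_len:
                    continue
                candidates.append(
                    BeamHypothesis(hyp.tokens + (tok,), hyp.score + s)
                )
        if not candidates:  # nothing can extend or terminate: keep partials
            break
        candidates.sort(key=BeamHypothesis.sort_key)
        beam = candidates[: config.beam_size]
        if all(h.complete for h in beam):
            break
    complete = [h for h in beam if h.complete]
    if complete:
        best = min(complete, key=BeamHypothesis.sort_key)
        return best.tokens, beam, True
    best = min(beam, key=BeamHypothesis.sort_key)
    return best.tokens, beam, False


def greedy_decode(
    model, source: Sentence, vocab: Vocabulary, max_len: int = MAX_TOKENS
) -> Sentence:
    """Plain argmax decoding (beam of 1, decay off)."""
    sent, _, _ = beam_search(
        model,
        source,
        vocab,
        DecayBeamConfig(beam_size=1, decay_enabled=False, max_len=max_len),
    )
    return sent


def update_recurrence_counts(
    counts: dict[str, int], sentence: Sentence
) -> dict[str, int]:
    """Advance running streak counts by one sentence of the series."""
    present = set(sentence)
    new_counts = {t: c + 1 for t, c in counts.items() if t in present}
    for t in present:
        new_counts.setdefault(t, 1)
    return new_counts


def rollout(
    model,
    seed_sentence: Sentence,
    horizon: int,
    vocab: Vocabulary,
    config: DecayBeamConfig | None = None,
    stats: RecurrenceStats | None = None,
    initial_counts: dict[str, int] | None = None,
) -> list[Sentence]:
    """Autoregressive multi-step prediction across sentences.

    Each generated sentence becomes the source of the next step; recurrence
    counts are incremented while a token persists and reset when it drops
    out of the series.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    counts = (
        dict(initial_counts)
        if initial_counts is not None
        else update_recurrence_counts({}, seed_sentence)
    )
    source = tuple(seed_sentence)
    out: list[Sentence] = []
    for _ in range(horizon):
        predicted, _, _ = beam_search(model, source, vocab, config, stats, counts)
        out.append(predicted)
        counts = update_recurrence_counts(counts, predicted)
        source = predicted
    return out
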