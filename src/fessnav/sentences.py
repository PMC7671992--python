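"""Navigation sentences: verbalization, tokenization and class sequences.

A navigation state is verbalized with a fixed-slot template::

    step <count> <cavity> <group> <landmark_1> ... <landmark_k> <direction>

with ``k`` between 1 and 3, giving 6-8 tokens per sentence.  Landmark tokens
are emitted in depth-rank order (alphabetical tie-break) so that the surface
form is canonical and exact-match metrics are well defined; any order is
accepted on decode.  Consecutive sentences of the same workflow are paired
into (source, target) training examples for sequence-to-sequence models, and
each state's landmark combination is mapped to a stable integer class id for
the class-level baselines.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .ontology import Direction, NavigationState, SpatialOntology

__all__ = [
    "Sentence",
    "SentencePair",
    "Vocabulary",
    "state_to_sentence",
    "sentence_to_state",
    "make_pairs",
    "ClassCodec",
    "SLOTS",
]

Sentence = tuple[str, ...]

#: Slot names of the fixed template, used for position-specific scoring.
SLOTS = ("step_count", "sinus", "landmark_group", "landmark_combination", "direction")

_DIRECTIONS = {d.value for d in Direction}

MIN_TOKENS = 6
MAX_TOKENS = 10  # template yields 6-8; 10 is the hard band of the annotation


@dataclass(frozen=True)
class SentencePair:
    """Consecutive-sentence training pair from one workflow."""

    source: Sentence
    target: Sentence
    workflow_id: str = ""


def state_to_sentence(state: NavigationState, ontology: SpatialOntology) -> Sentence:
    """Verbalize a navigation state with the fixed-slot template."""
    combo = state.landmark_combination
    if not combo:
        raise ValueError("landmark combination is empty")
    lms = ontology.sort_combination(combo)
    return (
        "step",
        str(state.step_count),
        state.cavity,
        state.landmark_group,
        *lms,
        state.direction.value,
    )


def sentence_to_state(sentence: Sequence[str], ontology: SpatialOntology) -> NavigationState:
    """Parse a template sentence back into a navigation state.

    Landmark tokens are accepted in any order.  Raises ``ValueError`` naming
    the offending slot on malformed input.
    """
    toks = tuple(sentence)
    if len(toks) < MIN_TOKENS:
        raise ValueError(f"too short: {len(toks)} tokens, expected >= {MIN_TOKENS}")
    if len(toks) > MAX_TOKENS:
        raise ValueError(f"too long: {len(toks)} tokens, expected <= {MAX_TOKENS}")
    if toks[0] != "step":
        raise ValueError(f"slot step_count: expected leading 'step', got {toks[0]!r}")
    if not toks[1].isdigit() or int(toks[1]) < 1:
        raise ValueError(f"slot step_count: not a positive integer: {toks[1]!r}")
    if toks[-1] not in _DIRECTIONS:
        raise ValueError(f"slot direction: unknown direction {toks[-1]!r}")
    lms = toks[4:-1]
    if not 1 <= len(lms) <= 3:
        raise ValueError(f"slot landmark_combination: size {len(lms)} not in 1..3")
    for n in lms:
        if n not in ontology:
            raise ValueError(f"slot landmark_combination: unknown landmark {n!r}")
    rep = ontology.representative(lms)
    if toks[2] != rep.cavity:
        raise ValueError(f"slot sinus: {toks[2]!r} inconsistent with {rep.cavity!r}")
    if toks[3] != rep.group:
        raise ValueError(
            f"slot landmark_group: {toks[3]!r} inconsistent with {rep.group!r}"
        )
    return NavigationState(
        step_count=int(toks[1]),
        cavity=toks[2],
        landmark_group=toks[3],
        landmark_combination=frozenset(lms),
        direction=Direction(toks[-1]),
    )


def sentence_slots(sentence: Sequence[str]) -> dict[str, object]:
    """Split a template sentence into its five evaluation slots."""
    toks = tuple(sentence)
    if len(toks) < MIN_TOKENS or toks[0] != "step":
        raise ValueError("not a template sentence")
    return {
        "step_count": toks[1],
        "sinus": toks[2],
        "landmark_group": toks[3],
        "landmark_combination": frozenset(toks[4:-1]),
        "direction": toks[-1],
    }


def make_pairs(
    sentences_per_workflow: dict[str, Sequence[Sentence]],
) -> list[SentencePair]:
    """Pair every two consecutive sentences, never across workflow bounds."""
    pairs: list[SentencePair] = []
    for wf_id, sents in sentences_per_workflow.items():
        for a, b in zip(sents, sents[1:]):
            pairs.append(SentencePair(tuple(a), tuple(b), wf_id))
    return pairs


class Vocabulary:
    """Token <-> index bijection with reserved special indices.

    PAD=0, SOS=1, EOS=2, UNK=3.  Numeral step-count tokens are covered up to
    ``max_step_token`` (default 999); larger step numbers map to UNK so the
    vocabulary stays bounded.
    """

    PAD, SOS, EOS, UNK = 0, 1, 2, 3
    SPECIALS = ("<pad>", "<sos>", "<eos>", "<unk>")

    def __init__(self, tokens: Iterable[str], max_step_token: int = 999):
        self.max_step_token = max_step_token
        seen: dict[str, None] = {}
        for t in tokens:
            if t in self.SPECIALS:
                continue
            if t.isdigit() and int(t) > max_step_token:
                continue
            seen.setdefault(t)
        self._itos = list(self.SPECIALS) + sorted(seen)
        self._stoi = {t: i for i, t in enumerate(self._itos)}

    @classmethod
    def from_sentences(
        cls, sentences: Iterable[Sequence[str]], max_step_token: int = 999
    ) -> "Vocabulary":
        return cls((t for s in sentences for t in s), max_step_token)

    def __len__(self) -> int:
        return len(self._itos)

    def __contains__(self, token: str) -> bool:
        return token in self._stoi

    def index(self, token: str) -> int:
        if token.isdigit() and int(token) > self.max_step_token:
            return self.UNK
        return self._stoi.get(token, self.UNK)

    def token(self, index: int) -> str:
        return self._itos[index]

    def encode(self, sentence: Sequence[str]) -> list[int]:
        """SOS + token indices + EOS; out-of-vocabulary tokens become UNK."""
        return [self.SOS] + [self.index(t) for t in sentence] + [self.EOS]

    def decode(self, indices: Sequence[int]) -> Sentence:
        """Strip specials and map indices back to tokens."""
        out = []
        for i in indices:
            if i == self.EOS:
                break
            if i in (self.PAD, self.SOS):
                continue
            out.append(self._itos[i])
        return tuple(out)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self._stoi, indent=0))

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        stoi = json.loads(Path(path).read_text())
        vocab = cls.__new__(cls)
        vocab.max_step_token = 999
        vocab._itos = [t for t, _ in sorted(stoi.items(), key=lambda kv: kv[1])]
        vocab._stoi = dict(stoi)
        return vocab


class ClassCodec:
    """Stable mapping between landmark combinations and integer class ids.

    Ids are assigned in first-seen order over the corpus, so the same
    combination receives the same id in every workflow.
    """

    def __init__(self) -> None:
        self._ids: dict[tuple[str, ...], int] = {}

    @staticmethod
    def key(combination: Iterable[str]) -> tuple[str, ...]:
        return tuple(sorted(combination))

    @property
    def n_classes(self) -> int:
        return len(self._ids)

    def class_id(self, combination: Iterable[str]) -> int:
        k = self.key(combination)
        if k not in self._ids:
            self._ids[k] = len(self._ids)
        return self._ids[k]

    def combination(self, class_id: int) -> frozenset[str]:
        for k, v in self._ids.items():
            if v == class_id:
                return frozenset(k)
        raise KeyError(class_id)

    def to_class_sequence(self, states: Sequence[NavigationState]) -> list[int]:
        return [self.class_id(st.landmark_combination) for st in states]
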