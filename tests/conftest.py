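"""Shared fixtures: ontology, toy corpora, and a table-driven toy model."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from fessnav.ontology import (
    NavigationState,
    default_ontology,
    infer_direction,
)
from fessnav.sentences import SentencePair, Vocabulary, make_pairs, state_to_sentence


@pytest.fixture(scope="session")
def ontology():
    return default_ontology()


def build_cyclic_sentences(ontology, combos, n_steps):
    """Deterministic cyclic workflow sentences over the given combinations."""
    sents = []
    prev = None
    for i, combo in enumerate(
        itertools.islice(itertools.cycle(combos), n_steps), start=1
    ):
        rep = ontology.representative(combo)
        state = NavigationState(
            step_count=i,
            cavity=rep.cavity,
            landmark_group=rep.group,
            landmark_combination=frozenset(combo),
            direction=infer_direction(prev, combo, ontology),
        )
        sents.append(state_to_sentence(state, ontology))
        prev = combo
    return sents


@pytest.fixture(scope="session")
def cyclic_corpus(ontology):
    """Eight sentences cycling through four combinations, with vocab/pairs."""
    combos = [
        ("middle_nasal_concha",),
        ("middle_nasal_meatus",),
        ("ethmoidal_bulla", "middle_nasal_concha"),
        ("maxillary_sinus_orifice",),
    ]
    sents = build_cyclic_sentences(ontology, combos, 8)
    pairs = make_pairs({"cyc": sents})
    vocab = Vocabulary.from_sentences(sents)
    return sents, pairs, vocab


class TableModel:
    """Toy translator with externally specified next-word distributions.

    ``table`` maps a generated-prefix tuple (token indices, without SOS) to
    a probability vector over the vocabulary; missing prefixes fall back to
    the uniform distribution.  Used as a ground-truth oracle for decoding
    tests.
    """

    def __init__(self, vocab_size: int, table: dict[tuple[int, ...], np.ndarray]):
        self.vocab_size = vocab_size
        self.table = {k: np.asarray(v, dtype=float) for k, v in table.items()}

    def next_word_distribution(self, src_ids, prefix_ids):
        key = tuple(prefix_ids[1:])  # strip SOS
        probs = self.table.get(key)
        if probs is None:
            probs = np.full(self.vocab_size, 1.0 / self.vocab_size)
        return probs / probs.sum()


@pytest.fixture
def table_model_factory():
    return TableModel
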