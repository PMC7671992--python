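"""Metric arithmetic against independent oracles and hand computations."""

from functools import lru_cache

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fessnav.evaluation import (
    bleu1,
    corpus_statistics,
    f1_br,
    jaccard_distance,
    landmark_precision_recall,
    rougeL_recall,
    round_half_up,
    score_pairs,
    slot_precision_recall,
)
from fessnav.ontology import Direction, NavigationState, default_ontology
from fessnav.workflow_io import NavigationWorkflow

ONT = default_ontology()


# --- independent oracles (intentionally different algorithms) -------------

def oracle_bleu1(pred, ref):
    """Clipped unigram precision x brevity penalty via sorted multisets."""
    if not pred:
        return 0.0
    matches = 0
    ref_pool = list(ref)
    for tok in pred:
        if tok in ref_pool:
            ref_pool.remove(tok)
            matches += 1
    precision = matches / len(pred)
    bp = 1.0 if len(pred) >= len(ref) else np.exp(1 - len(ref) / len(pred))
    return bp * precision


def oracle_lcs(a, b):
    """Recursive memoized LCS, independent of the DP-table implementation."""

    @lru_cache(maxsize=None)
    def rec(i, j):
        if i == 0 or j == 0:
            return 0
        if a[i - 1] == b[j - 1]:
            return rec(i - 1, j - 1) + 1
        return max(rec(i - 1, j), rec(i, j - 1))

    return rec(len(a), len(b))


def random_template_sentences(rng, n):
    cavities = ["nasal_cavity", "ethmoidal_sinus", "maxillary_sinus"]
    groups = ["concha_group", "meatus_group", "ethmoid_group"]
    landmarks = ONT.names
    directions = ["inwards", "outwards", "dwell"]
    out = []
    for _ in range(n):
        k = int(rng.integers(1, 4))
        lms = list(rng.choice(landmarks, size=k, replace=False))
        out.append(
            (
                "step",
                str(int(rng.integers(1, 900))),
                str(rng.choice(cavities)),
                str(rng.choice(groups)),
                *lms,
                str(rng.choice(directions)),
            )
        )
    return out


class TestBleu1:
    def test_identical_sentences(self):
        s = ("a", "b", "c")
        assert bleu1(s, s) == 1.0

    def test_disjoint_token_sets(self):
        assert bleu1(("a", "b"), ("c", "d")) == 0.0

    def test_clipping_hand_count(self):
        # pred "a a b" vs ref "a b c": clipped matches 2 of 3, BP = 1
        assert np.isclose(bleu1(("a", "a", "b"), ("a", "b", "c")), 2 / 3)

    def test_brevity_penalty_applies(self):
        val = bleu1(("a",), ("a", "b", "c"))
        assert np.isclose(val, np.exp(1 - 3) * 1.0)

    def test_empty_prediction_scores_zero(self):
        assert bleu1((), ("a",)) == 0.0

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            bleu1(("a",), ())


class TestRougeL:
    def test_identical(self):
        assert rougeL_recall(("a", "b"), ("a", "b")) == 1.0

    def test_subsequence_hand_count(self):
        assert rougeL_recall(("a", "b", "d"), ("a", "b", "c", "d")) == 0.75

    def test_empty_prediction(self):
        assert rougeL_recall((), ("a",)) == 0.0

    def test_order_matters(self):
        assert rougeL_recall(("b", "a"), ("a", "b")) == 0.5


class TestAgainstIndependentOracles:
    def test_bleu_and_rouge_agree_on_random_sentences(self):
        rng = np.random.default_rng(2024)
        sents = random_template_sentences(rng, 200)
        for pred, ref in zip(sents[:100], sents[100:]):
            assert abs(bleu1(pred, ref) - oracle_bleu1(pred, ref)) < 1e-6
            expected_rouge = oracle_lcs(pred, ref) / len(ref)
            assert abs(rougeL_recall(pred, ref) - expected_rouge) < 1e-6


class TestF1BR:
    def test_published_s2s_arithmetic(self):
        # harmonic mean of BLEU-1 0.73 and ROUGE-L 0.77 rounds to 0.75
        value = f1_br(0.73, 0.77)
        assert np.isclose(value, 2 * 0.73 * 0.77 / 1.50)
        assert round_half_up(value) == 0.75

    def test_equal_inputs_fixed_point(self):
        assert f1_br(0.6, 0.6) == pytest.approx(0.6)

    def test_zero_side_forces_zero(self):
        assert f1_br(0.0, 0.9) == 0.0
        assert f1_br(0.0, 0.0) == 0.0

    @given(
        b=st.floats(min_value=0.01, max_value=1.0),
        r=st.floats(min_value=0.01, max_value=1.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_bounded_by_inputs(self, b, r):
        f = f1_br(b, r)
        assert min(b, r) - 1e-12 <= f <= max(b, r) + 1e-12


class TestJaccard:
    def test_identical_zero_distance(self):
        assert jaccard_distance(("a", "b"), ("b", "a")) == 0.0

    def test_disjoint_full_distance(self):
        assert jaccard_distance(("a",), ("b",)) == 1.0

    def test_half_overlap(self):
        assert jaccard_distance(("a", "b", "c"), ("b", "c", "d")) == 0.5

    def test_two_empty_sentences(self):
        assert jaccard_distance((), ()) == 0.0


class TestSlotPrecisionRecall:
    def _sent(self, step, lms, direction):
        rep = ONT.representative(lms)
        return ("step", str(step), rep.cavity, rep.group, *sorted(lms), direction)

    def test_perfect_predictions(self):
        pairs = [
            (self._sent(1, {"middle_nasal_concha"}, "dwell"),) * 2,
            (self._sent(2, {"middle_nasal_meatus"}, "inwards"),) * 2,
        ]
        df = slot_precision_recall(pairs)
        for slot in ("step_count", "sinus", "landmark_group", "direction"):
            assert df.loc[slot, "precision"] == 1.0
            assert df.loc[slot, "recall"] == 1.0
        assert df.loc["overall", "precision"] == 1.0

    def test_direction_confusion_hand_computed(self):
        # four pairs; one "inwards" predicted as "dwell"
        t = [
            self._sent(1, {"middle_nasal_concha"}, "inwards"),
            self._sent(2, {"middle_nasal_concha"}, "inwards"),
            self._sent(3, {"middle_nasal_concha"}, "dwell"),
            self._sent(4, {"middle_nasal_concha"}, "dwell"),
        ]
        p = [t[0], self._sent(2, {"middle_nasal_concha"}, "dwell"), t[2], t[3]]
        df = slot_precision_recall(list(zip(p, t)))
        # inwards: tp=1, predicted 1, true 2 -> P=1, R=0.5
        # dwell:   tp=2, predicted 3, true 2 -> P=2/3, R=1
        assert np.isclose(df.loc["direction", "precision"], (1 + 2 / 3) / 2)
        assert np.isclose(df.loc["direction", "recall"], (0.5 + 1) / 2)

    def test_f1_is_harmonic_mean_of_overall(self):
        t = [self._sent(i, {"middle_nasal_concha"}, "dwell") for i in range(1, 4)]
        p = [t[0], t[1], self._sent(9, {"out_of_patient"}, "inwards")]
        df = slot_precision_recall(list(zip(p, t)))
        op, orr = df.loc["overall", "precision"], df.loc["overall", "recall"]
        assert np.isclose(df.loc["f1", "precision"], f1_br(op, orr))

    def test_malformed_predictions_skipped_and_counted(self):
        t = [self._sent(1, {"middle_nasal_concha"}, "dwell")] * 2
        p = [t[0], ("not", "a", "sentence")]
        df = slot_precision_recall(list(zip(p, t)))
        assert df.attrs["n_skipped"] == 1


class TestLandmarkPrecisionRecall:
    def test_perfect_predictions(self):
        seqs = [frozenset({"middle_nasal_concha"}), frozenset({"middle_nasal_meatus"})]
        df = landmark_precision_recall(seqs, seqs)
        assert df.loc["overall", "precision"] == 1.0
        assert df.loc["overall", "recall"] == 1.0

    def test_in_combination_occurrences_count(self):
        pred = [frozenset({"middle_nasal_concha", "ethmoidal_bulla"})]
        target = [frozenset({"middle_nasal_concha"})]
        df = landmark_precision_recall(pred, target)
        assert df.loc["middle_nasal_concha", "precision"] == 1.0
        assert df.loc["ethmoidal_bulla", "precision"] == 0.0

    def test_macro_mean_matches_hand_computation(self):
        # three landmarks: P = 1, 0.5, 0 -> overall 0.5
        pred = [
            frozenset({"a"}),
            frozenset({"b"}),
            frozenset({"b"}),
            frozenset({"c"}),
        ]
        target = [
            frozenset({"a"}),
            frozenset({"b"}),
            frozenset({"c"}),
            frozenset({"b"}),
        ]
        df = landmark_precision_recall(pred, target)
        assert np.isclose(df.loc["overall", "precision"], (1 + 0.5 + 0) / 3)

    def test_absent_landmark_excluded_from_macro(self):
        pred = [frozenset({"a"})]
        target = [frozenset({"a"})]
        df = landmark_precision_recall(pred, target, landmarks=["a", "ghost"])
        assert np.isnan(df.loc["ghost", "precision"])
        assert df.loc["overall", "precision"] == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            landmark_precision_recall([frozenset({"a"})], [])


def _wf(wf_id, combos, dwell=2.0):
    states = []
    prev = None
    for i, c in enumerate(combos, 1):
        rep = ONT.representative(c)
        states.append(
            NavigationState(
                step_count=i,
                cavity=rep.cavity,
                landmark_group=rep.group,
                landmark_combination=frozenset(c),
                direction=Direction.DWELL,
                start_s=(i - 1) * dwell,
                end_s=i * dwell,
            )
        )
    return NavigationWorkflow(wf_id, states)


class TestCorpusStatistics:
    def test_single_workflow_unique_combinations(self):
        wf = _wf("w", [{"middle_nasal_concha"}, {"middle_nasal_meatus"}, {"out_of_patient"}])
        stats = corpus_statistics([wf])
        assert stats.per_workflow.loc["w", "unique_combinations"] == 3
        assert stats.per_workflow.loc["w", "steps"] == 3

    def test_two_workflow_fractions_hand_computed(self):
        w1 = _wf("w1", [
            {"middle_nasal_concha"},
            {"middle_nasal_concha", "middle_nasal_meatus"},
            {"out_of_patient"},
        ])
        w2 = _wf("w2", [{"middle_nasal_concha"}, {"middle_nasal_meatus"}])
        stats = corpus_statistics([w1, w2])
        assert stats.total_states == 5
        lm = stats.per_landmark
        assert lm.loc["middle_nasal_concha", "individual"] == 2
        assert lm.loc["middle_nasal_concha", "in_combination"] == 1
        assert lm.loc["middle_nasal_concha", "accumulated"] == 3
        assert np.isclose(lm.loc["middle_nasal_concha", "accumulated_fraction"], 3 / 5)
        assert np.isclose(lm.loc["out_of_patient", "accumulated_fraction"], 1 / 5)

    def test_accumulated_identity_holds_exactly(self):
        rng = np.random.default_rng(0)
        names = ONT.names
        wfs = []
        for w in range(3):
            combos = [
                set(rng.choice(names, size=rng.integers(1, 4), replace=False))
                for _ in range(30)
            ]
            wfs.append(_wf(f"w{w}", combos))
        stats = corpus_statistics(wfs)
        lm = stats.per_landmark
        assert (lm["individual"] + lm["in_combination"] == lm["accumulated"]).all()
        # all fractions share the total-state denominator
        assert np.allclose(
            lm["accumulated_fraction"], lm["accumulated"] / stats.total_states
        )

    def test_mean_visibility_duration(self):
        wf = _wf("w", [{"middle_nasal_concha"}] * 4, dwell=3.0)
        stats = corpus_statistics([wf])
        assert stats.per_workflow.loc["w", "mean_visibility_s"] == 3.0


class TestScorePairs:
    def test_report_fields_populated(self):
        s1 = ("step", "1", "nasal_cavity", "concha_group", "middle_nasal_concha", "dwell")
        s2 = ("step", "2", "nasal_cavity", "meatus_group", "middle_nasal_meatus", "inwards")
        report = score_pairs([(s1, s1), (s2, s1)])
        assert report.n_pairs == 2
        assert 0 < report.bleu1 <= 1
        assert 0 < report.rougeL_recall <= 1
        assert report.f1_br == f1_br(report.bleu1, report.rougeL_recall)
        assert isinstance(report.slot_scores, pd.DataFrame)
        rounded = report.rounded()
        assert set(rounded) == {"bleu1", "rougeL_recall", "f1_br", "jaccard_distance"}


def test_round_half_up_ties_away_from_zero():
    # exactly representable ties round away from zero, not to even
    assert round_half_up(0.125, 2) == 0.13
    assert round_half_up(0.375, 2) == 0.38
    assert round_half_up(-0.125, 2) == -0.13
    assert round_half_up(0.744999) == 0.74
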