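"""Translation and prediction metrics plus corpus summary statistics.

Sentence-level generation quality is scored with unigram BLEU (clipped
unigram precision times brevity penalty), ROUGE-L recall (longest common
subsequence length over reference length) and their harmonic mean F1_BR,
which serves as an approximated translation accuracy; word-level Jaccard
distance measures dissimilarity of the token sets.  Position-specific
quality is scored per template slot (step count, sinus, landmark group,
landmark combination, direction) with macro-averaged multi-class precision
and recall, and landmark-level quality accumulates individual and
in-combination occurrences per landmark.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .ontology import NavigationState
from .sentences import SLOTS, Sentence, sentence_slots
from .workflow_io import NavigationWorkflow

__all__ = [
    "bleu1",
    "rougeL_recall",
    "f1_br",
    "jaccard_distance",
    "MetricReport",
    "score_pairs",
    "slot_precision_recall",
    "landmark_precision_recall",
    "corpus_statistics",
    "CorpusStatistics",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, as in the reported tables."""
    factor = 10.0**ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def bleu1(predicted: Sequence[str], reference: Sequence[str]) -> float:
    """Unigram BLEU: clipped unigram precision times brevity penalty."""
    if not reference:
        raise ValueError("empty reference")
    if not predicted:
        return 0.0
    pred_counts = Counter(predicted)
    ref_counts = Counter(reference)
    clipped = sum(min(c, ref_counts[t]) for t, c in pred_counts.items())
    if clipped == 0:
        return 0.0
    precision = clipped / len(predicted)
    bp = 1.0 if len(predicted) >= len(reference) else math.exp(
        1.0 - len(reference) / len(predicted)
    )
    return bp * precision


def _lcs_length(a: Sequence[str], b: Sequence[str]) -> int:
    # standard O(|a||b|) dynamic program; sentences are <= 10 tokens
    m, n = len(a), len(b)
    dp = [[0] * (n + 1) for _ in range(m + 1)]
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            if a[i - 1] == b[j - 1]:
                dp[i][j] = dp[i - 1][j - 1] + 1
            else:
                dp[i][j] = max(dp[i - 1][j], dp[i][j - 1])
    return dp[m][n]


def rougeL_recall(predicted: Sequence[str], reference: Sequence[str]) -> float:
    """ROUGE-L recall: LCS(predicted, reference) / |reference|."""
    if not reference:
        raise ValueError("empty reference")
    if not predicted:
        return 0.0
    return _lcs_length(predicted, reference) / len(reference)


def f1_br(bleu: float, rouge: float) -> float:
    """Harmonic mean of BLEU-1 and ROUGE-L recall (approximated accuracy)."""
    if bleu + rouge == 0:
        return 0.0
    return 2.0 * bleu * rouge / (bleu + rouge)


def jaccard_distance(predicted: Sequence[str], reference: Sequence[str]) -> float:
    """1 - |intersection| / |union| over token sets; 0 for two empty inputs."""
    p, r = set(predicted), set(reference)
    union = p | r
    if not union:
        return 0.0
    return 1.0 - len(p & r) / len(union)


@dataclass
class MetricReport:
    """Aggregated sentence-level scores over a set of prediction pairs."""

    bleu1: float
    rougeL_recall: float
    f1_br: float
    jaccard_distance: float
    n_pairs: int
    slot_scores: pd.DataFrame | None = None
    landmark_scores: pd.DataFrame | None = None

    def rounded(self) -> dict[str, float]:
        return {
            "bleu1": round_half_up(self.bleu1),
            "rougeL_recall": round_half_up(self.rougeL_recall),
            "f1_br": round_half_up(self.f1_br),
            "jaccard_distance": round_half_up(self.jaccard_distance),
        }

    def to_dict(self) -> dict:
        out: dict = {
            "bleu1": self.bleu1,
            "rougeL_recall": self.rougeL_recall,
            "f1_br": self.f1_br,
            "jaccard_distance": self.jaccard_distance,
            "n_pairs": self.n_pairs,
        }
        if self.slot_scores is not None:
            out["slot_scores"] = self.slot_scores.to_dict(orient="index")
        if self.landmark_scores is not None:
            out["landmark_scores"] = self.landmark_scores.to_dict(orient="index")
        return out


def score_pairs(
    pairs: Iterable[tuple[Sentence, Sentence]], with_slots: bool = True
) -> MetricReport:
    """Score (predicted, target) sentence pairs; averages over pairs."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no pairs to score")
    b = sum(bleu1(p, t) for p, t in pairs) / len(pairs)
    r = sum(rougeL_recall(p, t) for p, t in pairs) / len(pairs)
    j = sum(jaccard_distance(p, t) for p, t in pairs) / len(pairs)
    slot_df = slot_precision_recall(pairs) if with_slots else None
    return MetricReport(
        bleu1=b,
        rougeL_recall=r,
        f1_br=f1_br(b, r),
        jaccard_distance=j,
        n_pairs=len(pairs),
        slot_scores=slot_df,
    )


def _macro_pr(
    truths: list, preds: list, exclude_absent: bool = False
) -> tuple[float, float]:
    """Macro-averaged multi-class precision/recall over observed labels.

    A label with no predicted and no true occurrences contributes nothing
    (its precision is undefined); a label that occurs on one side only
    counts as 0 on the undefined side unless ``exclude_absent``.
    """
    labels = sorted(set(truths) | set(preds), key=repr)
    precisions, recalls = [], []
    for lab in labels:
        tp = sum(1 for t, p in zip(truths, preds) if t == lab and p == lab)
        n_pred = sum(1 for p in preds if p == lab)
        n_true = sum(1 for t in truths if t == lab)
        if n_pred == 0 and n_true == 0:
            continue
        precisions.append(tp / n_pred if n_pred else 0.0)
        recalls.append(tp / n_true if n_true else 0.0)
    if not precisions:
        return 0.0, 0.0
    return sum(precisions) / len(precisions), sum(recalls) / len(recalls)


def slot_precision_recall(
    pairs: Iterable[tuple[Sentence, Sentence]]
) -> pd.DataFrame:
    """Position-specific precision/recall per template slot.

    Rows: the five slots, an ``overall`` macro mean across slots, and the
    harmonic-mean ``f1`` of the overall precision and recall.  The landmark
    combination slot is compared as a set.  Malformed predictions are
    skipped and counted in the ``n_skipped`` attribute.
    """
    truth_by_slot: dict[str, list] = {s: [] for s in SLOTS}
    pred_by_slot: dict[str, list] = {s: [] for s in SLOTS}
    n_skipped = 0
    for pred, target in pairs:
        try:
            p_slots = sentence_slots(pred)
            t_slots = sentence_slots(target)
        except ValueError:
            n_skipped += 1
            continue
        for s in SLOTS:
            truth_by_slot[s].append(t_slots[s])
            pred_by_slot[s].append(p_slots[s])
    rows = {}
    for s in SLOTS:
        p, r = _macro_pr(truth_by_slot[s], pred_by_slot[s])
        rows[s] = {"precision": p, "recall": r}
    overall_p = sum(rows[s]["precision"] for s in SLOTS) / len(SLOTS)
    overall_r = sum(rows[s]["recall"] for s in SLOTS) / len(SLOTS)
    rows["overall"] = {"precision": overall_p, "recall": overall_r}
    f1 = f1_br(overall_p, overall_r)
    rows["f1"] = {"precision": f1, "recall": f1}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.attrs["n_skipped"] = n_skipped
    return df


def landmark_precision_recall(
    predicted: Sequence[frozenset[str] | set[str]],
    target: Sequence[frozenset[str] | set[str]],
    landmarks: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-landmark precision/recall over aligned combination sequences.

    A predicted occurrence of a landmark (individually or inside a
    combination) at step t is a true positive iff the landmark occurs in the
    target combination at step t.  The ``overall`` row is the unweighted
    macro mean over landmarks; landmarks never predicted and never present
    are excluded from the macro mean (their precision is undefined).
    """
    if len(predicted) != len(target):
        raise ValueError(
            f"length mismatch: {len(predicted)} predicted vs {len(target)} target"
        )
    if landmarks is None:
        landmarks = sorted({n for c in list(predicted) + list(target) for n in c})
    rows = {}
    precisions, recalls = [], []
    for lm in landmarks:
        tp = sum(1 for p, t in zip(predicted, target) if lm in p and lm in t)
        n_pred = sum(1 for p in predicted if lm in p)
        n_true = sum(1 for t in target if lm in t)
        if n_pred == 0 and n_true == 0:
            rows[lm] = {"precision": float("nan"), "recall": float("nan")}
            continue
        p = tp / n_pred if n_pred else 0.0
        r = tp / n_true if n_true else 0.0
        rows[lm] = {"precision": p, "recall": r}
        precisions.append(p)
        recalls.append(r)
    overall_p = sum(precisions) / len(precisions) if precisions else 0.0
    overall_r = sum(recalls) / len(recalls) if recalls else 0.0
    rows["overall"] = {"precision": overall_p, "recall": overall_r}
    f1 = f1_br(overall_p, overall_r)
    rows["f1"] = {"precision": f1, "recall": f1}
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclass
class CorpusStatistics:
    """Summary of a workflow corpus: per-workflow and per-landmark tables.

    ``per_workflow`` columns: steps, duration_s, unique_combinations,
    mean_visibility_s.  ``per_landmark`` columns: individual, in_combination,
    accumulated counts plus the corresponding fractions of the total state
    count (the shared denominator for all three fraction columns).
    """

    per_workflow: pd.DataFrame
    per_landmark: pd.DataFrame
    total_states: int

    @property
    def mean_steps(self) -> float:
        return float(self.per_workflow["steps"].mean())

    @property
    def mean_unique_combinations(self) -> float:
        return float(self.per_workflow["unique_combinations"].mean())

    def to_dict(self) -> dict:
        return {
            "total_states": self.total_states,
            "mean_steps": self.mean_steps,
            "mean_duration_s": float(self.per_workflow["duration_s"].mean()),
            "mean_unique_combinations": self.mean_unique_combinations,
            "mean_visibility_s": float(
                self.per_workflow["mean_visibility_s"].mean()
            ),
            "per_workflow": self.per_workflow.to_dict(orient="index"),
            "per_landmark": self.per_landmark.to_dict(orient="index"),
        }


def corpus_statistics(workflows: Sequence[NavigationWorkflow]) -> CorpusStatistics:
    """Per-workflow step/duration/combination summaries and landmark counts.

    A state whose combination has size 1 counts as an *individual*
    observation of its landmark; size >= 2 counts each member as an
    *in-combination* observation.  Accumulated = individual + in-combination,
    and every fraction uses the total state count as denominator.
    """
    wf_rows = {}
    individual: Counter = Counter()
    in_combination: Counter = Counter()
    total_states = 0
    for wf in workflows:
        durations = [st.duration_s for st in wf.states]
        combos = {frozenset(st.landmark_combination) for st in wf.states}
        wf_rows[wf.workflow_id] = {
            "steps": len(wf.states),
            "duration_s": wf.duration_s,
            "unique_combinations": len(combos),
            "mean_visibility_s": (
                sum(durations) / len(durations) if durations else 0.0
            ),
        }
        total_states += len(wf.states)
        for st in wf.states:
            combo = st.landmark_combination
            if len(combo) == 1:
                individual[next(iter(combo))] += 1
            else:
                for name in combo:
                    in_combination[name] += 1
    lm_rows = {}
    for lm in sorted(set(individual) | set(in_combination)):
        ind = individual.get(lm, 0)
        comb = in_combination.get(lm, 0)
        acc = ind + comb
        lm_rows[lm] = {
            "individual": ind,
            "in_combination": comb,
            "accumulated": acc,
            "individual_fraction": ind / total_states if total_states else 0.0,
            "in_combination_fraction": comb / total_states if total_states else 0.0,
            "accumulated_fraction": acc / total_states if total_states else 0.0,
        }
    per_lm = pd.DataFrame.from_dict(lm_rows, orient="index").sort_values(
        "accumulated", ascending=False
    )
    return CorpusStatistics(
        per_workflow=pd.DataFrame.from_dict(wf_rows, orient="index"),
        per_landmark=per_lm,
        total_states=total_states,
    )
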