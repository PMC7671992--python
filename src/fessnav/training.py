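"""Losses, learning-rate schedule, augmentation and cross-validation.

All neural predictors are trained with Adam (beta = (0.9, 0.98),
eps = 1e-9) under a warm-up learning-rate schedule: the rate grows linearly
up to ``n_warmup`` steps (default 200) and decays proportionally to
step^(-0.5) afterwards.  The standard schedule scales by d_model^(-0.5); a
``paper_literal`` variant scaling by sqrt(d_model) instead is retained
behind a flag (it produces learning rates above 1 and is not the default).

The sentence translators are trained on consecutive-sentence pairs; the
transformer uses a label-smoothed Kullback-Leibler loss (smoothing 0.1),
the GRU encoder-decoder and the LSTM baseline plain cross-entropy.  Source
sentences can be augmented with random swap and random deletion operations.
Evaluation uses leave-one-out cross-validation over whole workflows, with
the left-in pairs shuffled and split 9:1 into training and validation sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .models.autodiff import Adam, Tensor
from .sentences import Sentence, SentencePair, Vocabulary

__all__ = [
    "OptimizerConfig",
    "LearningRateSchedule",
    "TrainingConfig",
    "lr_at",
    "label_smoothed_kl_loss",
    "cross_entropy_loss",
    "smoothed_target_distribution",
    "augment",
    "Fold",
    "loocv_folds",
    "train",
    "train_classifier",
    "TrainingResults",
]


@dataclass
class OptimizerConfig:
    beta1: float = 0.9
    beta2: float = 0.98
    eps: float = 1e-9

    def __post_init__(self) -> None:
        if not (0 < self.beta1 < 1 and 0 < self.beta2 < 1):
            raise ValueError("betas must lie in (0, 1)")


@dataclass
class LearningRateSchedule:
    d_model: int
    n_warmup: int = 200
    mode: str = "standard"  # or "paper_literal"

    def __post_init__(self) -> None:
        if self.n_warmup < 1:
            raise ValueError("n_warmup must be >= 1")
        if self.mode not in ("standard", "paper_literal"):
            raise ValueError(f"unknown schedule mode {self.mode!r}")

    def __call__(self, step: int) -> float:
        return lr_at(step, self)


def lr_at(step: int, schedule: LearningRateSchedule) -> float:
    """Warm-up learning rate at a 1-based optimizer step."""
    if step < 1:
        raise ValueError("step must be >= 1")
    ramp = min(step**-0.5, step * schedule.n_warmup**-1.5)
    if schedule.mode == "paper_literal":
        return np.sqrt(schedule.d_model) * ramp
    return schedule.d_model**-0.5 * ramp


@dataclass
class TrainingConfig:
    """Batching, loss and augmentation settings for one training run."""

    batch_size: int = 20
    epochs: int = 10
    label_smoothing: float = 0.1
    loss: str = "cross_entropy"  # or "kl_smoothed"
    n_warmup: int = 200
    schedule_mode: str = "standard"
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    augment_sources: bool = False
    p_delete: float = 0.1
    n_swaps: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0 <= self.label_smoothing < 1:
            raise ValueError("label_smoothing must lie in [0, 1)")
        if self.loss not in ("cross_entropy", "kl_smoothed"):
            raise ValueError(f"unknown loss {self.loss!r}")


def smoothed_target_distribution(
    target: int, smoothing: float, vocab_size: int, pad_index: int = Vocabulary.PAD
) -> np.ndarray:
    """Label-smoothed ground-truth distribution.

    Mass 1 - smoothing on the target, smoothing / (V - 2) on every other
    token except PAD (V - 2 = all tokens minus target minus PAD).
    """
    p = np.full(vocab_size, smoothing / (vocab_size - 2))
    p[pad_index] = 0.0
    p[target] = 1.0 - smoothing
    return p


def _check_normalized(log_probs: Tensor) -> None:
    sums = np.exp(log_probs.data).sum(axis=-1)
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise ValueError("predictions are not normalized probability vectors")


def label_smoothed_kl_loss(
    log_probs: Tensor,
    targets: np.ndarray,
    smoothing: float,
    vocab_size: int,
    mask: np.ndarray | None = None,
    pad_index: int = Vocabulary.PAD,
) -> Tensor:
    """D_KL(P_truth || P_pred) against label-smoothed targets, batch mean.

    ``log_probs`` has shape (..., V), ``targets`` the matching index shape.
    Equals cross-entropy against the smoothed distribution minus its
    (constant) entropy, so it is non-negative and zero iff the prediction
    equals the smoothed target exactly.
    """
    if not 0 <= smoothing < 1:
        raise ValueError("smoothing must lie in [0, 1)")
    _check_normalized(log_probs)
    flat_targets = np.asarray(targets).reshape(-1)
    P = np.stack(
        [
            smoothed_target_distribution(t, smoothing, vocab_size, pad_index)
            for t in flat_targets
        ]
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        ent_terms = np.where(P > 0, P * np.log(P), 0.0)
    neg_entropy = ent_terms.sum(axis=-1)  # -H(P_truth), constant in the model
    flat_logq = log_probs.reshape(-1, vocab_size)
    cross = -(Tensor(P) * flat_logq).sum(axis=-1)
    kl = cross + Tensor(neg_entropy)
    if mask is None:
        return kl.mean()
    m = np.asarray(mask, dtype=float).reshape(-1)
    return (kl * Tensor(m)).sum() * (1.0 / max(m.sum(), 1.0))


def cross_entropy_loss(
    log_probs: Tensor, targets: np.ndarray, mask: np.ndarray | None = None
) -> Tensor:
    """Negative log-likelihood of the targets, batch mean over real tokens."""
    flat_targets = np.asarray(targets).reshape(-1)
    V = log_probs.shape[-1]
    flat = log_probs.reshape(-1, V)
    nll = -flat[np.arange(len(flat_targets)), flat_targets]
    if mask is None:
        return nll.mean()
    m = np.asarray(mask, dtype=float).reshape(-1)
    return (nll * Tensor(m)).sum() * (1.0 / max(m.sum(), 1.0))


def augment(
    sentence: Sequence[str],
    rng: np.random.Generator | int,
    p_delete: float = 0.1,
    n_swaps: int = 1,
) -> Sentence:
    """Random-swap then random-deletion augmentation of a source sentence.

    The step-count slot (leading "step <n>") is exempt from deletion so
    source and target remain alignable, and sentences are never shortened
    below 2 tokens.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    toks = list(sentence)
    if len(toks) < 2:
        return tuple(toks)
    for _ in range(n_swaps):
        i, j = rng.integers(0, len(toks), size=2)
        toks[i], toks[j] = toks[j], toks[i]
    protected = {i for i, t in enumerate(toks) if t == "step" or t.isdigit()}
    kept = [
        t
        for i, t in enumerate(toks)
        if i in protected or rng.random() >= p_delete
    ]
    while len(kept) < 2:
        kept = toks[: 2]
    return tuple(kept)


@dataclass
class Fold:
    """One leave-one-out fold: test on one workflow, train on the rest."""

    test_workflow: str
    train_pairs: list[SentencePair]
    val_pairs: list[SentencePair]
    test_pairs: list[SentencePair]


def loocv_folds(pairs: Sequence[SentencePair], seed: int = 0) -> list[Fold]:
    """Leave-one-workflow-out folds with a shuffled 9:1 train/val split."""
    by_wf: dict[str, list[SentencePair]] = {}
    for p in pairs:
        by_wf.setdefault(p.workflow_id, []).append(p)
    if len(by_wf) < 2:
        raise ValueError("leave-one-out needs at least 2 workflows")
    folds = []
    for i, wf_id in enumerate(sorted(by_wf)):
        left_in = [p for w, ps in sorted(by_wf.items()) if w != wf_id for p in ps]
        rng = np.random.default_rng((seed + i) % (2**31 - 1))
        order = rng.permutation(len(left_in))
        shuffled = [left_in[j] for j in order]
        n_val = len(shuffled) // 10
        folds.append(
            Fold(
                test_workflow=wf_id,
                train_pairs=shuffled[n_val:],
                val_pairs=shuffled[:n_val],
                test_pairs=list(by_wf[wf_id]),
            )
        )
    return folds


@dataclass
class TrainingResults:
    """Fit summary: the trained model plus per-epoch loss diagnostics."""

    model: object
    loss_history: list[float]
    config: TrainingConfig
    n_steps: int

    @property
    def final_loss(self) -> float | None:
        return self.loss_history[-1] if self.loss_history else None

    def summary(self) -> str:
        lines = [
            f"{type(self.model).__name__} training summary",
            "-" * 40,
            f"epochs:          {len(self.loss_history)}",
            f"optimizer steps: {self.n_steps}",
            f"batch size:      {self.config.batch_size}",
            f"loss criterion:  {self.config.loss}",
            f"label smoothing: {self.config.label_smoothing}",
        ]
        for e, loss in enumerate(self.loss_history, 1):
            lines.append(f"epoch {e:3d}  mean loss {loss:.4f}")
        return "\n".join(lines)


def _pad_batch(seqs: list[list[int]], pad: int) -> tuple[np.ndarray, np.ndarray]:
    T = max(len(s) for s in seqs)
    arr = np.full((len(seqs), T), pad, dtype=int)
    mask = np.zeros((len(seqs), T), dtype=bool)
    for i, s in enumerate(seqs):
        arr[i, : len(s)] = s
        mask[i, : len(s)] = True
    return arr, mask


def train(
    model,
    pairs: Sequence[SentencePair],
    vocab: Vocabulary,
    config: TrainingConfig,
) -> TrainingResults:
    """Train a sentence translator on consecutive-sentence pairs.

    Batches are reassembled and reshuffled every epoch; runs are
    deterministic under a fixed ``config.seed``.  ``epochs=0`` returns the
    model unchanged with an empty history.
    """
    if not pairs:
        raise ValueError("no training pairs")
    rng = np.random.default_rng(config.seed)
    aug_rng = np.random.default_rng(config.seed + 1)
    drop_rng = np.random.default_rng(config.seed + 2)
    if hasattr(model, "set_dropout_rng"):
        model.set_dropout_rng(drop_rng)
    schedule = LearningRateSchedule(
        model.d_model, n_warmup=config.n_warmup, mode=config.schedule_mode
    )
    opt = Adam(
        model.parameters(),
        beta1=config.optimizer.beta1,
        beta2=config.optimizer.beta2,
        eps=config.optimizer.eps,
    )
    V = len(vocab)
    history: list[float] = []
    step = 0
    for _ in range(config.epochs):
        order = rng.permutation(len(pairs))
        epoch_losses: list[float] = []
        for start in range(0, len(order), config.batch_size):
            batch = [pairs[i] for i in order[start : start + config.batch_size]]
            sources = [
                augment(p.source, aug_rng, config.p_delete, config.n_swaps)
                if config.augment_sources
                else p.source
                for p in batch
            ]
            src, src_mask = _pad_batch(
                [vocab.encode(s) for s in sources], vocab.PAD
            )
            tgt_full = [vocab.encode(p.target) for p in batch]
            tgt_in, _ = _pad_batch([t[:-1] for t in tgt_full], vocab.PAD)
            tgt_out, tgt_mask = _pad_batch([t[1:] for t in tgt_full], vocab.PAD)
            log_probs = model.forward_log_probs(src, src_mask, tgt_in)
            if config.loss == "kl_smoothed":
                loss = label_smoothed_kl_loss(
                    log_probs, tgt_out, config.label_smoothing, V, mask=tgt_mask
                )
            else:
                loss = cross_entropy_loss(log_probs, tgt_out, mask=tgt_mask)
            opt.zero_grad()
            loss.backward()
            step += 1
            opt.lr = schedule(step)
            opt.step()
            epoch_losses.append(loss.item())
        history.append(float(np.mean(epoch_losses)))
    if hasattr(model, "set_dropout_rng"):
        model.set_dropout_rng(None)
    return TrainingResults(model, history, config, step)


def train_classifier(
    model,
    class_sequences: Sequence[Sequence[int]],
    config: TrainingConfig,
) -> TrainingResults:
    """Train the LSTM window classifier on class-id sequences.

    Every position t >= 1 of every sequence yields one example: the window
    of the 6 preceding class ids (left-padded) and the class at t.
    """
    windows: list[list[int]] = []
    targets: list[int] = []
    for seq in class_sequences:
        for t in range(1, len(seq)):
            windows.append(model.pad_window(list(seq[:t])))
            targets.append(seq[t])
    if not windows:
        raise ValueError("no training examples")
    X = np.asarray(windows)
    y = np.asarray(targets)
    rng = np.random.default_rng(config.seed)
    schedule = LearningRateSchedule(model.d_model, n_warmup=config.n_warmup)
    opt = Adam(model.parameters())
    history: list[float] = []
    step = 0
    for _ in range(config.epochs):
        order = rng.permutation(len(X))
        epoch_losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            log_probs = model.forward_log_probs(X[idx])
            loss = cross_entropy_loss(log_probs, y[idx])
            opt.zero_grad()
            loss.backward()
            step += 1
            opt.lr = schedule(step)
            opt.step()
            epoch_losses.append(loss.item())
        history.append(float(np.mean(epoch_losses)))
    return TrainingResults(model, history, config, step)
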