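"""Learning-rate schedule, losses, augmentation and cross-validation."""

import numpy as np
import pytest

from fessnav.models import Seq2SeqGRU, EncoderDecoderConfig, Tensor
from fessnav.sentences import SentencePair, Vocabulary
from fessnav.training import (
    LearningRateSchedule,
    OptimizerConfig,
    TrainingConfig,
    augment,
    cross_entropy_loss,
    label_smoothed_kl_loss,
    loocv_folds,
    lr_at,
    smoothed_target_distribution,
    train,
)


class TestLearningRateSchedule:
    def test_branches_equal_at_warmup(self):
        sched = LearningRateSchedule(d_model=64, n_warmup=200)
        n = sched.n_warmup
        assert np.isclose(n**-0.5, n * n**-1.5)
        assert np.isclose(lr_at(n, sched), 64**-0.5 * n**-0.5)

    def test_linear_ramp_before_warmup(self):
        sched = LearningRateSchedule(d_model=64, n_warmup=50)
        rates = [lr_at(s, sched) for s in range(1, 51)]
        assert all(a < b for a, b in zip(rates, rates[1:]))

    def test_standard_mode_numeric_value(self):
        sched = LearningRateSchedule(d_model=64, n_warmup=200)
        expected = 64**-0.5 * 100 * 200**-1.5
        assert np.isclose(lr_at(100, sched), expected)
        assert 100 * 200**-1.5 < 100**-0.5  # ramp branch is the minimum here

    def test_paper_literal_mode_scales_by_sqrt_d(self):
        lit = LearningRateSchedule(d_model=64, n_warmup=200, mode="paper_literal")
        std = LearningRateSchedule(d_model=64, n_warmup=200)
        assert np.isclose(lr_at(100, lit), 64 * lr_at(100, std))

    @pytest.mark.parametrize("mode", ["standard", "paper_literal"])
    def test_continuous_at_warmup(self, mode):
        sched = LearningRateSchedule(d_model=32, n_warmup=100, mode=mode)
        n = sched.n_warmup
        gap_before = lr_at(n, sched) - lr_at(n - 1, sched)
        gap_after = lr_at(n, sched) - lr_at(n + 1, sched)
        assert abs(gap_before) < lr_at(n, sched) * 0.02
        assert abs(gap_after) < lr_at(n, sched) * 0.02

    def test_step_zero_rejected(self):
        with pytest.raises(ValueError):
            lr_at(0, LearningRateSchedule(d_model=64))

    def test_decay_after_warmup(self):
        sched = LearningRateSchedule(d_model=64, n_warmup=10)
        assert lr_at(40, sched) < lr_at(10, sched)
        assert np.isclose(lr_at(40, sched), 64**-0.5 * 40**-0.5)


class TestLosses:
    def test_kl_zero_when_prediction_equals_smoothed_target(self):
        V, target, s = 6, 4, 0.1
        P = smoothed_target_distribution(target, s, V)
        log_q = Tensor(np.log(np.maximum(P, 1e-300))[None, :])
        # PAD has zero truth mass, so its prediction value is irrelevant;
        # renormalize to a proper distribution placing epsilon on PAD
        q = np.maximum(P, 1e-12)
        q /= q.sum()
        loss = label_smoothed_kl_loss(Tensor(np.log(q)[None, :]), np.array([target]), s, V)
        assert loss.item() < 1e-6

    def test_zero_smoothing_equals_nll(self):
        rng = np.random.default_rng(0)
        logits = rng.normal(size=(5, 7))
        log_q = Tensor(logits).log_softmax(-1)
        targets = rng.integers(1, 7, size=5)
        kl = label_smoothed_kl_loss(log_q, targets, 0.0, 7)
        ce = cross_entropy_loss(Tensor(log_q.data), targets)
        assert np.isclose(kl.item(), ce.item(), atol=1e-12)

    def test_three_class_hand_computation(self):
        # vocabulary {PAD, a, b}: target a, smoothing 0.3
        q = np.array([0.2, 0.5, 0.3])
        P = np.array([0.0, 0.7, 0.3])  # 1-s on target, s/(V-2) on b, 0 on PAD
        expected = sum(p * np.log(p / qq) for p, qq in zip(P, q) if p > 0)
        loss = label_smoothed_kl_loss(
            Tensor(np.log(q)[None, :]), np.array([1]), 0.3, 3
        )
        assert np.isclose(loss.item(), expected, atol=1e-12)

    def test_loss_identity_kl_equals_ce_minus_entropy(self):
        """KL(P||Q) == H(P, Q) - H(P) for the smoothed target, to 1e-6."""
        rng = np.random.default_rng(1)
        V, B, s = 11, 8, 0.1
        log_q = Tensor(rng.normal(size=(B, V))).log_softmax(-1)
        targets = rng.integers(1, V, size=B)
        kl = label_smoothed_kl_loss(Tensor(log_q.data), targets, s, V).item()
        ce_minus_h = 0.0
        for i, t in enumerate(targets):
            P = smoothed_target_distribution(t, s, V)
            cross_entropy = -(P * log_q.data[i]).sum()
            entropy = -(P[P > 0] * np.log(P[P > 0])).sum()
            ce_minus_h += cross_entropy - entropy
        assert abs(kl - ce_minus_h / B) < 1e-6

    def test_unnormalized_predictions_rejected(self):
        bad = Tensor(np.log(np.array([[0.5, 0.2, 0.2]])))
        with pytest.raises(ValueError, match="normalized"):
            label_smoothed_kl_loss(bad, np.array([1]), 0.1, 3)


class TestAugment:
    SENT = ("step", "7", "nasal_cavity", "concha_group", "middle_nasal_concha", "dwell")

    def test_identity_when_disabled(self):
        assert augment(self.SENT, 0, p_delete=0.0, n_swaps=0) == self.SENT

    def test_single_token_unchanged(self):
        assert augment(("only",), 0, p_delete=0.9, n_swaps=3) == ("only",)

    def test_reproducible_under_fixed_seed(self):
        a = augment(self.SENT, 123, p_delete=0.3, n_swaps=2)
        b = augment(self.SENT, 123, p_delete=0.3, n_swaps=2)
        assert a == b

    def test_never_below_two_tokens(self):
        for seed in range(20):
            out = augment(("a", "b", "c"), seed, p_delete=0.99, n_swaps=0)
            assert len(out) >= 2

    def test_step_slot_survives_deletion(self):
        # deletion never removes "step" or the numeral token
        for seed in range(20):
            out = augment(self.SENT, seed, p_delete=0.95, n_swaps=0)
            assert "step" in out and "7" in out


def _pairs_for(workflows: dict[str, int]) -> list[SentencePair]:
    out = []
    for wf, n in workflows.items():
        for i in range(n):
            out.append(SentencePair((f"{wf}", f"{i}"), (f"{wf}", f"{i + 1}"), wf))
    return out


class TestLOOCV:
    def test_fold_count_matches_workflows(self):
        pairs = _pairs_for({f"w{i}": 10 for i in range(22)})
        assert len(loocv_folds(pairs)) == 22

    def test_test_pairs_never_in_training(self):
        pairs = _pairs_for({"a": 8, "b": 9, "c": 7})
        for fold in loocv_folds(pairs, seed=1):
            train_ids = {id(p) for p in fold.train_pairs + fold.val_pairs}
            assert all(id(p) not in train_ids for p in fold.test_pairs)
            assert all(p.workflow_id != fold.test_workflow for p in fold.train_pairs)

    def test_nine_to_one_split_sizes(self):
        # 3650 left-in pairs split into 3285 train and 365 validation
        pairs = _pairs_for({"keep": 3650, "out": 5})
        fold = [f for f in loocv_folds(pairs) if f.test_workflow == "out"][0]
        assert len(fold.val_pairs) == 365
        assert len(fold.train_pairs) == 3285

    def test_partition_is_disjoint_and_exhaustive(self):
        pairs = _pairs_for({"a": 6, "b": 5, "c": 4, "d": 7})
        folds = loocv_folds(pairs, seed=3)
        test_sets = [frozenset(id(p) for p in f.test_pairs) for f in folds]
        union = set().union(*test_sets)
        assert len(union) == len(pairs)  # exhaustive
        for i, a in enumerate(test_sets):
            for b in test_sets[i + 1 :]:
                assert not (a & b)  # pairwise disjoint
        for fold in folds:
            in_fold = fold.train_pairs + fold.val_pairs
            assert len(in_fold) == len(pairs) - len(fold.test_pairs)

    def test_single_workflow_rejected(self):
        with pytest.raises(ValueError):
            loocv_folds(_pairs_for({"only": 5}))


@pytest.fixture(scope="module")
def tiny_setup():
    sents = [
        ("step", str(i), "nasal_cavity", "concha_group", "middle_nasal_concha", "dwell")
        for i in range(1, 12)
    ]
    pairs = [SentencePair(a, b, "w") for a, b in zip(sents, sents[1:])]
    vocab = Vocabulary.from_sentences(sents)
    return pairs, vocab


class TestTrainLoop:

    def test_loss_decreases_on_small_corpus(self, tiny_setup):
        pairs, vocab = tiny_setup
        model = Seq2SeqGRU(EncoderDecoderConfig.desk(len(vocab)), seed=0)
        res = train(model, pairs, vocab, TrainingConfig(epochs=15, n_warmup=20, seed=0))
        assert res.loss_history[-1] < res.loss_history[0]
        assert len(res.loss_history) == 15

    def test_same_seed_gives_identical_history(self, tiny_setup):
        pairs, vocab = tiny_setup
        histories = []
        for _ in range(2):
            model = Seq2SeqGRU(EncoderDecoderConfig.desk(len(vocab)), seed=5)
            res = train(model, pairs, vocab, TrainingConfig(epochs=3, seed=5))
            histories.append(res.loss_history)
        assert histories[0] == histories[1]

    def test_zero_epochs_returns_model_unchanged(self, tiny_setup):
        pairs, vocab = tiny_setup
        model = Seq2SeqGRU(EncoderDecoderConfig.desk(len(vocab)), seed=0)
        before = [p.data.copy() for p in model.parameters()]
        res = train(model, pairs, vocab, TrainingConfig(epochs=0, seed=0))
        assert res.loss_history == []
        for p, b in zip(model.parameters(), before):
            assert np.array_equal(p.data, b)

    def test_empty_pairs_rejected(self, tiny_setup):
        _, vocab = tiny_setup
        model = Seq2SeqGRU(EncoderDecoderConfig.desk(len(vocab)), seed=0)
        with pytest.raises(ValueError):
            train(model, [], vocab, TrainingConfig())

    def test_summary_mentions_loss_criterion(self, tiny_setup):
        pairs, vocab = tiny_setup
        model = Seq2SeqGRU(EncoderDecoderConfig.desk(len(vocab)), seed=0)
        res = train(model, pairs, vocab, TrainingConfig(epochs=1, seed=0))
        text = res.summary()
        assert "cross_entropy" in text and "epoch   1" in text


def test_optimizer_config_validates_betas():
    with pytest.raises(ValueError):
        OptimizerConfig(beta1=1.2)
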