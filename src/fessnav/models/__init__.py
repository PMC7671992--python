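"""Next-step predictors behind a common contract.

Two sentence-level translators (GRU encoder-decoder and transformer) expose
``forward_log_probs`` for teacher-forced training and
``next_word_distribution`` for autoregressive decoding; two class-level
baselines (LSTM window classifier and Gaussian-emission HMM) expose
``predict_next_distribution`` over landmark-combination class ids.
"""

from .autodiff import Adam, Tensor
from .hmm import GaussianHMM, HMMConfig
from .lstm import LSTMClassifier, LSTMConfig
from .seq2seq import EncoderDecoderConfig, Seq2SeqGRU
from .transformer import (
    Transformer,
    TransformerConfig,
    scaled_dot_product_attention,
    sinusoidal_encoding,
)

__all__ = [
    "Adam",
    "Tensor",
    "GaussianHMM",
    "HMMConfig",
    "LSTMClassifier",
    "LSTMConfig",
    "EncoderDecoderConfig",
    "Seq2SeqGRU",
    "Transformer",
    "TransformerConfig",
    "scaled_dot_product_attention",
    "sinusoidal_encoding",
    "next_word_distribution",
]


def next_word_distribution(model, src_ids, prefix_ids):
    """Probability vector over the vocabulary for the next target word."""
    return model.next_word_distribution(list(src_ids), list(prefix_ids))


def save_checkpoint(model, path) -> None:
    """Single-file checkpoint: config JSON header plus parameter arrays."""
    import json
    from dataclasses import asdict

    import numpy as np

    if isinstance(model, GaussianHMM):
        np.savez(
            path,
            __header__=json.dumps({"kind": "hmm", "config": asdict(model.config)}),
            startprob=model.startprob,
            transmat=model.transmat,
            means=model.means,
            variances=model.variances,
            n_classes=np.array(model.n_classes),
        )
        return
    kind = {Seq2SeqGRU: "s2s", Transformer: "transformer", LSTMClassifier: "lstm"}[
        type(model)
    ]
    header = json.dumps({"kind": kind, "config": asdict(model.config)})
    arrays = {f"param_{i}": p.data for i, p in enumerate(model.parameters())}
    np.savez(path, __header__=header, **arrays)


def load_checkpoint(path):
    """Rebuild a model saved by :func:`save_checkpoint`."""
    import json

    import numpy as np

    with np.load(path, allow_pickle=False) as data:
        header = json.loads(str(data["__header__"]))
        kind, cfg = header["kind"], header["config"]
        if kind == "hmm":
            model = GaussianHMM(HMMConfig(**cfg))
            model.startprob = data["startprob"]
            model.transmat = data["transmat"]
            model.means = data["means"]
            model.variances = data["variances"]
            model.n_classes = int(data["n_classes"])
            return model
        cls, cfg_cls = {
            "s2s": (Seq2SeqGRU, EncoderDecoderConfig),
            "transformer": (Transformer, TransformerConfig),
            "lstm": (LSTMClassifier, LSTMConfig),
        }[kind]
        model = cls(cfg_cls(**cfg))
        for i, p in enumerate(model.parameters()):
            p.data[...] = data[f"param_{i}"]
    return model
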