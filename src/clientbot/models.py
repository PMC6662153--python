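"""The two recurrent conversational models.

* A tagged language model: one LSTM layer trained on a flat token stream in
  which ``<p>``/``<t>`` tags mark speaker changes, by truncated
  backpropagation over fixed-length windows.
* An encoder–decoder (seq2seq): an LSTM encoder reads the therapist
  statement; a separate LSTM decoder, initialized from the encoder's final
  state, is trained to emit the client statement followed by ``<eos>``.

Both are optimized with Adagrad under global-norm gradient clipping.  The
hyperparameters the original system used at scale (1024 and 3000 hidden
units, vocabulary of 15 000, 50-token windows, learning rates .05 and .01,
clip 5) are the stated defaults of the two configs; the package's tests run
much smaller instances of the same architecture.

Perplexity — exp of the mean negative log-probability per predicted token —
is the model-selection metric.  Padding positions are excluded; speaker-tag
positions count as predicted positions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from ._nn import Adagrad, LSTMLayer, SoftmaxOutput, clip_gradients, softmax
from .corpus import EOS, Seq2SeqPair, Vocabulary

__all__ = [
    "LMConfig",
    "Seq2SeqConfig",
    "TrainingReport",
    "TrainedLM",
    "TrainedSeq2Seq",
    "train_lm",
    "train_seq2seq",
    "next_token_distribution",
    "perplexity",
    "save_model",
    "load_model",
]


@dataclass
class LMConfig:
    hidden_units: int = 1024
    embed_dim: int = 64
    layers: int = 1
    learning_rate: float = 0.05
    sequence_length: int = 50
    clip_norm: float = 5.0
    epochs: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.hidden_units, self.layers, self.sequence_length, self.epochs) < 1:
            raise ValueError("counts must be >= 1")
        if self.learning_rate <= 0 or self.clip_norm <= 0:
            raise ValueError("learning_rate and clip_norm must be positive")
        if self.layers != 1:
            raise NotImplementedError("only single-layer models are supported")


@dataclass
class Seq2SeqConfig:
    hidden_units: int = 3000
    embed_dim: int = 64
    layers: int = 1
    learning_rate: float = 0.01
    clip_norm: float = 5.0
    vocab_size: int = 15000
    epochs: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.hidden_units, self.layers, self.epochs) < 1:
            raise ValueError("counts must be >= 1")
        if self.learning_rate <= 0 or self.clip_norm <= 0:
            raise ValueError("learning_rate and clip_norm must be positive")
        if self.layers != 1:
            raise NotImplementedError("only single-layer models are supported")


@dataclass
class TrainingReport:
    """Per-epoch mean training loss (nats/token), the largest post-clip
    gradient norm observed, and held-out perplexity when eval data was given."""

    epoch_losses: list[float] = field(default_factory=list)
    max_post_clip_grad_norm: float = 0.0
    heldout_perplexity: float | None = None


class TrainedLM:
    """Tagged language model: p(next token | all previous stream tokens)."""

    kind = "lm"

    def __init__(self, layer: LSTMLayer, out: SoftmaxOutput, vocab: Vocabulary,
                 config: LMConfig, report: TrainingReport):
        self.layer = layer
        self.out = out
        self.vocab = vocab
        self.config = config
        self.report = report

    # -- incremental decoding protocol -------------------------------------
    def start(self, context: Sequence[str] = ()) -> tuple:
        """State after consuming ``context``; pair with :meth:`distribution`."""
        state = self.layer.zero_state()
        for idx in self.vocab.encode(context):
            state, _ = self.layer.step(idx, state)
        return state

    def step(self, state, token_index: int):
        new_state, _ = self.layer.step(token_index, state)
        return new_state

    def distribution(self, state) -> np.ndarray:
        return self.out.probs(state[0])

    def next_token_distribution(self, context: Sequence[str]) -> np.ndarray:
        return self.distribution(self.start(context))

    def token_log_probs(self, stream: Sequence[str]) -> list[float]:
        """Log-probability of each stream token given its prefix (pads skipped)."""
        idxs = self.vocab.encode(stream)
        pad = self.vocab.pad_index
        state = self.layer.zero_state()
        lps: list[float] = []
        for idx in idxs:
            if idx != pad:
                p = self.out.probs(state[0])[idx]
                lps.append(float(np.log(max(p, 1e-300))))
            state, _ = self.layer.step(idx, state)
        return lps


class TrainedSeq2Seq:
    """Encoder–decoder model mapping a therapist statement to a client reply."""

    kind = "seq2seq"

    def __init__(self, encoder: LSTMLayer, decoder: LSTMLayer, out: SoftmaxOutput,
                 vocab: Vocabulary, config: Seq2SeqConfig, report: TrainingReport):
        self.encoder = encoder
        self.decoder = decoder
        self.out = out
        self.vocab = vocab
        self.config = config
        self.report = report

    def encode(self, source: Sequence[str]):
        state = self.encoder.zero_state()
        for idx in self.vocab.encode(source):
            state, _ = self.encoder.step(idx, state)
        return state

    @property
    def eos_index(self) -> int:
        return self.vocab.eos_index

    # -- incremental decoding protocol (shared with the beam searcher) -----
    def decoder_start(self, source: Sequence[str]):
        """Returns (state, log-prob vector for the first output token)."""
        state = self.encode(source)
        state, _ = self.decoder.step(self.vocab.eos_index, state)
        return state, _log(self.out.probs(state[0]))

    def decoder_step(self, state, token_index: int):
        state, _ = self.decoder.step(token_index, state)
        return state, _log(self.out.probs(state[0]))

    def next_token_distribution(self, source: Sequence[str],
                                partial_target: Sequence[str] = ()) -> np.ndarray:
        state, logp = self.decoder_start(source)
        for idx in self.vocab.encode(partial_target):
            state, logp = self.decoder_step(state, idx)
        return np.exp(logp)

    def token_log_probs(self, pairs: Sequence[Seq2SeqPair]) -> list[float]:
        """Teacher-forced log-probabilities of target tokens + eos, per pair."""
        pad = self.vocab.pad_index
        lps: list[float] = []
        for pair in pairs:
            state, logp = self.decoder_start(pair.source)
            targets = self.vocab.encode(pair.target) + [self.vocab.eos_index]
            for idx in targets:
                if idx != pad:
                    lps.append(float(logp[idx]))
                state, logp = self.decoder_step(state, idx)
        return lps

    def greedy_decode(self, source: Sequence[str], max_len: int = 30) -> list[str]:
        state, logp = self.decoder_start(source)
        out: list[int] = []
        for _ in range(max_len):
            nxt = int(np.argmax(logp))
            if nxt == self.vocab.eos_index:
                break
            out.append(nxt)
            state, logp = self.decoder_step(state, nxt)
        return self.vocab.decode(out)


def _log(p: np.ndarray) -> np.ndarray:
    return np.log(np.maximum(p, 1e-300))


def train_lm(stream: Sequence[str], vocab: Vocabulary, config: LMConfig,
             eval_stream: Sequence[str] | None = None) -> TrainedLM:
    """Truncated backpropagation through time over fixed-length windows."""
    if len(stream) < config.sequence_length + 1:
        raise ValueError("token stream is shorter than one training window")
    rng = np.random.default_rng(config.seed)
    layer = LSTMLayer(len(vocab), config.embed_dim, config.hidden_units, rng)
    out = SoftmaxOutput(config.hidden_units, len(vocab))
    opt = Adagrad([layer.params, out.params], config.learning_rate)
    idxs = vocab.encode(stream)
    L = config.sequence_length
    windows = [idxs[s : s + L + 1] for s in range(0, len(idxs) - 1, L)]
    windows = [w for w in windows if len(w) >= 2]
    report = TrainingReport()
    for _ in range(config.epochs):
        total, count = 0.0, 0
        for w in windows:
            loss, n = _lm_window_update(layer, out, opt, w, config.clip_norm, report)
            total += loss
            count += n
        report.epoch_losses.append(total / count)
    model = TrainedLM(layer, out, vocab, config, report)
    if eval_stream is not None:
        report.heldout_perplexity = perplexity(model, eval_stream)
    return model


def _lm_window_update(layer, out, opt, window, clip_norm, report):
    inputs, targets = window[:-1], window[1:]
    state = layer.zero_state()
    caches, hs = [], []
    for idx in inputs:
        state, cache = layer.step(idx, state)
        caches.append(cache)
        hs.append(state[0])
    lg, og = layer.zero_grads(), out.zero_grads()
    n = len(targets)
    dhs = []
    total = 0.0
    for h, tgt in zip(hs, targets):
        loss, dh = out.loss_and_grad(h, tgt, og)
        total += loss
        dhs.append(dh / n)
    for k in og:
        og[k] /= n
    dh_next = np.zeros(layer.hidden)
    dc_next = np.zeros(layer.hidden)
    for t in range(len(inputs) - 1, -1, -1):
        dh_next, dc_next = layer.backward_step(dhs[t] + dh_next, dc_next, caches[t], lg)
    norm = clip_gradients([lg, og], clip_norm)
    report.max_post_clip_grad_norm = max(report.max_post_clip_grad_norm, norm)
    opt.update([lg, og])
    return total, n


def train_seq2seq(pairs: Sequence[Seq2SeqPair], vocab: Vocabulary, config: Seq2SeqConfig,
                  eval_pairs: Sequence[Seq2SeqPair] | None = None) -> TrainedSeq2Seq:
    """Teacher-forced training of the encoder–decoder on statement pairs."""
    if not pairs:
        raise ValueError("no training pairs")
    rng = np.random.default_rng(config.seed)
    encoder = LSTMLayer(len(vocab), config.embed_dim, config.hidden_units, rng)
    decoder = LSTMLayer(len(vocab), config.embed_dim, config.hidden_units, rng)
    out = SoftmaxOutput(config.hidden_units, len(vocab))
    opt = Adagrad([encoder.params, decoder.params, out.params], config.learning_rate)
    eos = vocab.eos_index
    encoded = [(vocab.encode(p.source), vocab.encode(p.target) + [eos]) for p in pairs]
    report = TrainingReport()
    for _ in range(config.epochs):
        total, count = 0.0, 0
        for src, tgt in encoded:
            loss, n = _s2s_pair_update(encoder, decoder, out, opt, src, tgt, eos,
                                       config.clip_norm, report)
            total += loss
            count += n
        report.epoch_losses.append(total / count)
    model = TrainedSeq2Seq(encoder, decoder, out, vocab, config, report)
    if eval_pairs is not None:
        report.heldout_perplexity = perplexity(model, eval_pairs)
    return model


def _s2s_pair_update(encoder, decoder, out, opt, src, tgt, eos, clip_norm, report):
    # encoder forward
    state = encoder.zero_state()
    enc_caches = []
    for idx in src:
        state, cache = encoder.step(idx, state)
        enc_caches.append(cache)
    # decoder forward, teacher forced: inputs = [eos] + tgt[:-1], outputs = tgt
    dec_inputs = [eos] + tgt[:-1]
    dec_caches, hs = [], []
    for idx in dec_inputs:
        state, cache = decoder.step(idx, state)
        dec_caches.append(cache)
        hs.append(state[0])
    eg, dg, og = encoder.zero_grads(), decoder.zero_grads(), out.zero_grads()
    n = len(tgt)
    total = 0.0
    dhs = []
    for h, t in zip(hs, tgt):
        loss, dh = out.loss_and_grad(h, t, og)
        total += loss
        dhs.append(dh / n)
    for k in og:
        og[k] /= n
    dh_next = np.zeros(decoder.hidden)
    dc_next = np.zeros(decoder.hidden)
    for t in range(len(dec_inputs) - 1, -1, -1):
        dh_next, dc_next = decoder.backward_step(dhs[t] + dh_next, dc_next, dec_caches[t], dg)
    # gradient flows from decoder start state into the encoder's final state
    for t in range(len(src) - 1, -1, -1):
        dh_next, dc_next = encoder.backward_step(dh_next, dc_next, enc_caches[t], eg)
    norm = clip_gradients([eg, dg, og], clip_norm)
    report.max_post_clip_grad_norm = max(report.max_post_clip_grad_norm, norm)
    opt.update([eg, dg, og])
    return total, n


def next_token_distribution(model, context: Sequence[str]) -> np.ndarray:
    """Probability vector over the vocabulary for the next token.

    For the tagged LM ``context`` is the stream prefix; for the seq2seq model
    it is the source statement (first decoder position).
    """
    return model.next_token_distribution(context)


def perplexity(model, eval_data) -> float:
    """exp(mean negative log-probability per predicted token).

    ``model`` needs a ``token_log_probs(eval_data)`` method; both trained
    model classes provide one (a token stream for the LM, statement pairs for
    the seq2seq model).
    """
    lps = model.token_log_probs(eval_data)
    if not lps:
        raise ValueError("no predicted positions in eval data")
    return float(np.exp(-np.mean(lps)))


# -- checkpoints -----------------------------------------------------------

_FORMAT = "clientbot-ckpt-1"


def save_model(model: TrainedLM | TrainedSeq2Seq, path: str | Path) -> None:
    """Single-file npz archive: versioned header, config, vocabulary, weights."""
    header = {
        "format": _FORMAT,
        "kind": model.kind,
        "config": asdict(model.config),
        "vocab": model.vocab.to_dict(),
        "report": asdict(model.report),
    }
    arrays = {}
    if model.kind == "lm":
        groups = {"layer": model.layer.params, "out": model.out.params}
    else:
        groups = {"encoder": model.encoder.params, "decoder": model.decoder.params,
                  "out": model.out.params}
    for gname, params in groups.items():
        for k, v in params.items():
            arrays[f"{gname}.{k}"] = v
    np.savez_compressed(path, header=json.dumps(header), **arrays)


def load_model(path: str | Path) -> TrainedLM | TrainedSeq2Seq:
    with np.load(path, allow_pickle=False) as data:
        header = json.loads(str(data["header"]))
        if header["format"] != _FORMAT:
            raise ValueError(f"unsupported checkpoint format: {header['format']}")
        vocab = Vocabulary.from_dict(header["vocab"])
        report = TrainingReport(**header["report"])
        arrays = {k: data[k] for k in data.files if k != "header"}
    rng = np.random.default_rng(0)
    if header["kind"] == "lm":
        config = LMConfig(**header["config"])
        layer = LSTMLayer(len(vocab), config.embed_dim, config.hidden_units, rng)
        out = SoftmaxOutput(config.hidden_units, len(vocab))
        _load_group(arrays, "layer", layer.params)
        _load_group(arrays, "out", out.params)
        return TrainedLM(layer, out, vocab, config, report)
    config = Seq2SeqConfig(**header["config"])
    encoder = LSTMLayer(len(vocab), config.embed_dim, config.hidden_units, rng)
    decoder = LSTMLayer(len(vocab), config.embed_dim, config.hidden_units, rng)
    out = SoftmaxOutput(config.hidden_units, len(vocab))
    _load_group(arrays, "encoder", encoder.params)
    _load_group(arrays, "decoder", decoder.params)
    _load_group(arrays, "out", out.params)
    return TrainedSeq2Seq(encoder, decoder, out, vocab, config, report)


def _load_group(arrays: dict, gname: str, params: dict) -> None:
    for k in params:
        params[k] = arrays[f"{gname}.{k}"]
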