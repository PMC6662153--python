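"""Response generation for the simulated client.

The bot's first few replies come from the seq2seq model via beam search
(beam size 10 by default); after ``switch_after`` client responses it
switches to the tagged language model, decoded by per-step sampling, which
yields longer, more symptom-laden turns.  Candidates containing a banned
phrase ("i love you") are removed outright; candidates containing an
undersampled phrase ("i don't know") are removed with a configured
probability.

The beam searcher uses a nested selection rule: the active set kept at
width B+1 always contains the set kept at width B.  This keeps decoding
deterministic and guarantees that widening the beam never lowers the best
returned score; at B = 1 it reduces exactly to greedy decoding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .corpus import (
    EOS,
    PATIENT_TAG,
    THERAPIST_TAG,
    Speaker,
    Transcript,
    Utterance,
    detokenize,
    make_lm_stream,
    tokenize,
)

__all__ = [
    "Candidate",
    "PolicyConfig",
    "DialogueState",
    "beam_decode",
    "sample_decode",
    "filter_candidates",
    "respond",
]


@dataclass
class Candidate:
    """One decoded response: tokens, total log-probability, and which model
    produced it."""

    tokens: list[str]
    score: float
    source: str  # "seq2seq" | "lm"

    @property
    def text(self) -> str:
        return detokenize(self.tokens)


@dataclass
class PolicyConfig:
    beam_size: int = 10
    switch_after: int = 5  # client responses before switching seq2seq -> lm
    banned_phrases: frozenset[str] = frozenset({"i love you"})
    undersampled_phrases: frozenset[str] = frozenset({"i don't know"})
    undersample_prob: float = 0.9
    max_decode_len: int = 30
    temperature: float = 1.0
    fallback_text: str = "mm-hmm"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beam_size < 1 or self.switch_after < 0:
            raise ValueError("beam_size >= 1 and switch_after >= 0 required")
        if not 0.0 <= self.undersample_prob <= 1.0:
            raise ValueError("undersample_prob must be in [0, 1]")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass
class DialogueState:
    """Running conversation state: history plus the bot-response counter that
    drives the model switch."""

    client_response_count: int = 0
    history: list[Utterance] = field(default_factory=list)
    rng: np.random.Generator = field(default_factory=lambda: np.random.default_rng(0))


def beam_decode(model, source: Sequence[str], beam_size: int, max_len: int) -> list[Candidate]:
    """Beam search over the model's incremental decoding protocol.

    ``model`` must provide ``decoder_start(source) -> (state, logp)``,
    ``decoder_step(state, token) -> (state, logp)`` and ``eos_index``.
    Returns up to ``beam_size`` candidates ranked by total log-probability
    (ties broken lexicographically on the token-id sequence).  A candidate
    ends at eos (eos log-probability included in its score) or at
    ``max_len`` tokens.
    """
    if beam_size < 1:
        raise ValueError("beam_size must be >= 1")
    eos = model.eos_index
    state0, logp0 = model.decoder_start(source)
    # each active beam: (score, ids tuple, state, logp vector)
    active: list[tuple[float, tuple[int, ...], object, np.ndarray]] = [
        (0.0, (), state0, logp0)
    ]
    completed: list[tuple[float, tuple[int, ...]]] = []
    for _ in range(max_len):
        # every token, eos included, competes for the beam slots; a beam whose
        # winning extension is eos retires to the completed bank
        per_beam_exts: list[list[tuple[float, tuple[int, ...], int]]] = []
        for b_idx, (score, ids, _state, logp) in enumerate(active):
            exts = [
                (score + float(logp[tok]), ids + (tok,), b_idx)
                for tok in range(len(logp))
            ]
            exts.sort(key=lambda e: (-e[0], e[1]))
            per_beam_exts.append(exts)
        # nested selection: slot b may draw extensions of beams 1..b only
        chosen: list[tuple[float, tuple[int, ...], int]] = []
        chosen_ids: set[tuple[int, ...]] = set()
        pool: list[tuple[float, tuple[int, ...], int]] = []
        next_ext = 0  # how many beams' extension lists have been merged in
        for b in range(beam_size):
            while next_ext <= b and next_ext < len(per_beam_exts):
                pool.extend(per_beam_exts[next_ext])
                pool.sort(key=lambda e: (-e[0], e[1]))
                next_ext += 1
            pick = next((e for e in pool if e[1] not in chosen_ids), None)
            if pick is None:
                break
            chosen.append(pick)
            chosen_ids.add(pick[1])
        new_active = []
        for score, ids, parent in chosen:
            if ids[-1] == eos:
                completed.append((score, ids[:-1]))  # eos prob is in the score
                continue
            parent_state = active[parent][2]
            state, logp = model.decoder_step(parent_state, ids[-1])
            new_active.append((score, ids, state, logp))
        active = new_active
        if not active:
            break
    # length-capped actives count as candidates too
    completed.extend((score, ids) for score, ids, _s, _l in active)
    completed.sort(key=lambda c: (-c[0], c[1]))
    vocab = getattr(model, "vocab", None)
    out = []
    for score, ids in completed[:beam_size]:
        tokens = vocab.decode(ids) if vocab is not None else [str(i) for i in ids]
        out.append(Candidate(tokens=tokens, score=score, source="seq2seq"))
    return out


def sample_decode(model, context: Sequence[str], temperature: float, max_len: int,
                  rng: np.random.Generator | int) -> Candidate:
    """Sample one continuation token-by-token from the tagged LM.

    Temperature rescales the distribution as p^(1/T) (renormalized); the
    T -> 0 limit is greedy decoding.  Generation stops at eos, at a
    speaker-tag emission (the tag is not kept), or at ``max_len``.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    vocab = model.vocab
    stop_ids = {vocab.eos_index, vocab.index(PATIENT_TAG), vocab.index(THERAPIST_TAG)}
    state = model.start(context)
    tokens: list[int] = []
    score = 0.0
    for _ in range(max_len):
        p = model.distribution(state)
        logp = np.log(np.maximum(p, 1e-300))
        scaled = logp / temperature
        scaled -= scaled.max()
        q = np.exp(scaled)
        q /= q.sum()
        tok = int(rng.choice(len(q), p=q))
        score += float(logp[tok])  # score under the unscaled model
        if tok in stop_ids:
            break
        tokens.append(tok)
        state = model.step(state, tok)
    return Candidate(tokens=vocab.decode(tokens), score=min(score, 0.0), source="lm")


def _contains_any(text: str, phrases) -> bool:
    return any(phrase in text for phrase in phrases)


def filter_candidates(candidates: list[Candidate], config: PolicyConfig,
                      rng: np.random.Generator) -> list[Candidate]:
    """Apply the response filters, preserving order.

    Banned phrases remove a candidate unconditionally; undersampled phrases
    remove it independently with probability ``undersample_prob`` (substring
    match on the detokenized lowercase text).  If nothing survives, the
    configured neutral fallback utterance is returned instead.
    """
    kept: list[Candidate] = []
    for cand in candidates:
        text = cand.text.lower()
        if _contains_any(text, config.banned_phrases):
            continue
        if _contains_any(text, config.undersampled_phrases):
            if rng.random() < config.undersample_prob:
                continue
        kept.append(cand)
    if not kept:
        source = candidates[0].source if candidates else "lm"
        kept = [Candidate(tokens=config.fallback_text.split(), score=0.0, source=source)]
    return kept


def respond(state: DialogueState, trainee_utterance: str, models, config: PolicyConfig
            ) -> tuple[Utterance, DialogueState]:
    """Produce the bot's next client turn and update the dialogue state.

    ``models`` is a (seq2seq, lm) pair.  Responses 1..switch_after come from
    beam search on the trainee's last statement; later responses come from
    sampling the tagged LM conditioned on the recent tagged history.
    """
    seq2seq, lm = models
    state.history.append(Utterance(Speaker.THERAPIST, trainee_utterance))
    if state.client_response_count < config.switch_after:
        cands = beam_decode(seq2seq, tokenize(trainee_utterance),
                            config.beam_size, config.max_decode_len)
        survivors = filter_candidates(cands, config, state.rng)
        best = survivors[0]
    else:
        context = _tagged_context(state.history, lm.config.sequence_length)
        cand = sample_decode(lm, context, config.temperature,
                             config.max_decode_len, state.rng)
        best = filter_candidates([cand], config, state.rng)[0]
    text = best.text if best.tokens else config.fallback_text
    response = Utterance(Speaker.CLIENT, text)
    response.tokens = tokenize(text)
    state.history.append(response)
    state.client_response_count += 1
    response.source = best.source  # type: ignore[attr-defined]
    return response, state


def _tagged_context(history: list[Utterance], max_tokens: int) -> list[str]:
    """Tagged token stream of the recent history, ending with ``<p>`` so the
    LM continues in the client role."""
    stream = make_lm_stream([Transcript("ctx", [u for u in history
                                               if u.speaker != Speaker.SYSTEM])])
    stream = stream + [PATIENT_TAG]
    return stream[-max_tokens:]
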