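"""Dialogue data model: utterances, transcripts, tokenization, vocabulary,
and serialization into the two shapes the conversational models consume
(a flat tagged token stream and therapist→client statement pairs).

Transcripts are plain JSONL, one utterance per line:
``{"transcript_id": ..., "speaker": "T"|"C", "text": ...}``.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Speaker",
    "Utterance",
    "Transcript",
    "Vocabulary",
    "Seq2SeqPair",
    "PAD",
    "UNK",
    "NUMBER",
    "EOS",
    "PATIENT_TAG",
    "THERAPIST_TAG",
    "SPECIALS",
    "tokenize",
    "detokenize",
    "build_vocab",
    "make_lm_stream",
    "make_seq2seq_pairs",
    "split_train_test",
    "read_transcripts",
    "write_transcripts",
]

PAD = "<pad>"
UNK = "<unk>"
NUMBER = "<number>"
EOS = "<eos>"
PATIENT_TAG = "<p>"
THERAPIST_TAG = "<t>"

#: Special tokens, in their fixed index order at the bottom of every vocabulary.
SPECIALS = (PAD, UNK, NUMBER, EOS, PATIENT_TAG, THERAPIST_TAG)


class Speaker(str, Enum):
    THERAPIST = "T"
    CLIENT = "C"
    SYSTEM = "S"


@dataclass
class Utterance:
    """One talk turn: who spoke and what they said.

    ``tokens`` is filled by :meth:`tokenize` (lowercased, punctuation split,
    numerals masked with the ``<number>`` placeholder).
    """

    speaker: Speaker
    text: str
    tokens: list[str] | None = None

    def __post_init__(self) -> None:
        self.speaker = Speaker(self.speaker)
        if self.speaker in (Speaker.THERAPIST, Speaker.CLIENT) and not self.text.strip():
            raise ValueError("therapist/client utterance text must be non-empty")

    def tokenize(self) -> list[str]:
        self.tokens = tokenize(self.text)
        return self.tokens


@dataclass
class Transcript:
    """An ordered sequence of utterances from one session.

    Consecutive same-speaker utterances are allowed; transcribed speech
    routinely contains them.
    """

    id: str
    utterances: list[Utterance] = field(default_factory=list)

    def tokenize(self) -> "Transcript":
        for utt in self.utterances:
            if utt.tokens is None:
                utt.tokenize()
        return self

    def __len__(self) -> int:
        return len(self.utterances)


_TOKEN_RE = re.compile(r"[a-z']+|[0-9]+|[^\sa-z0-9']")


def tokenize(text: str) -> list[str]:
    """Lowercase, split punctuation into separate tokens, and replace every
    maximal digit run with the ``<number>`` placeholder.

    Idempotent: tokenizing the space-joined output returns the same sequence.
    Empty or whitespace-only input yields an empty list.
    """
    out: list[str] = []
    for tok in _TOKEN_RE.findall(text.lower()):
        out.append(NUMBER if tok[0].isdigit() else tok)
    # <number> re-tokenizes as "<", "number", ">" — collapse for idempotence
    merged: list[str] = []
    i = 0
    while i < len(out):
        if (out[i] == "<" and i + 2 < len(out) and out[i + 2] == ">"
                and out[i + 1].isalpha()):
            merged.append(f"<{out[i + 1]}>")
            i += 3
        else:
            merged.append(out[i])
            i += 1
    return merged


def detokenize(tokens: Sequence[str]) -> str:
    return " ".join(tokens)


class Vocabulary:
    """Token→index bijection with a frequency-capped content vocabulary.

    The special tokens occupy the lowest indices in fixed order; at most
    ``max_size`` content tokens follow, most frequent first, frequency ties
    broken lexicographically so equal corpora give equal vocabularies.
    """

    def __init__(self, content_tokens: Sequence[str], max_size: int):
        self.max_size = max_size
        self._itos: list[str] = list(SPECIALS) + list(content_tokens)
        self._stoi: dict[str, int] = {t: i for i, t in enumerate(self._itos)}
        if len(self._stoi) != len(self._itos):
            raise ValueError("duplicate tokens in vocabulary")

    def __len__(self) -> int:
        return len(self._itos)

    def __contains__(self, token: str) -> bool:
        return token in self._stoi

    @property
    def unk_index(self) -> int:
        return self._stoi[UNK]

    @property
    def pad_index(self) -> int:
        return self._stoi[PAD]

    @property
    def eos_index(self) -> int:
        return self._stoi[EOS]

    def index(self, token: str) -> int:
        return self._stoi.get(token, self._stoi[UNK])

    def token(self, index: int) -> str:
        return self._itos[index]

    def encode(self, tokens: Iterable[str]) -> list[int]:
        return [self.index(t) for t in tokens]

    def decode(self, indices: Iterable[int]) -> list[str]:
        return [self._itos[i] for i in indices]

    @property
    def tokens(self) -> list[str]:
        return list(self._itos)

    def to_dict(self) -> dict:
        return {"max_size": self.max_size, "content": self._itos[len(SPECIALS):]}

    @classmethod
    def from_dict(cls, d: dict) -> "Vocabulary":
        return cls(d["content"], d["max_size"])


def build_vocab(transcripts: Iterable[Transcript], max_size: int) -> Vocabulary:
    """Keep the ``max_size`` most frequent content tokens across the corpus.

    Everything else encodes to ``<unk>``. Deterministic in corpus content,
    regardless of transcript order.
    """
    if max_size < 1:
        raise ValueError("max_size must be >= 1")
    counts: Counter[str] = Counter()
    for tr in transcripts:
        tr.tokenize()
        for utt in tr.utterances:
            counts.update(t for t in utt.tokens if t not in SPECIALS or t == NUMBER)
    counts.pop(NUMBER, None)  # <number> is always present as a special
    if not counts:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    kept = [tok for tok, _ in ordered[:max_size]]
    return Vocabulary(kept, max_size)


_TAG_FOR = {Speaker.CLIENT: PATIENT_TAG, Speaker.THERAPIST: THERAPIST_TAG}


def make_lm_stream(transcripts: Iterable[Transcript]) -> list[str]:
    """Flatten transcripts into one token stream with speaker-change tags.

    Client runs are prefixed ``<p>``, therapist runs ``<t>``; a tag is
    emitted only at the start of a transcript and at speaker changes, so
    the content token count is preserved exactly.
    """
    stream: list[str] = []
    for tr in transcripts:
        tr.tokenize()
        prev: Speaker | None = None
        for utt in tr.utterances:
            if utt.speaker not in _TAG_FOR:
                raise ValueError(f"unsupported speaker in LM stream: {utt.speaker}")
            if utt.speaker != prev:
                stream.append(_TAG_FOR[utt.speaker])
                prev = utt.speaker
            stream.extend(utt.tokens)
        # a new transcript restarts run tracking
    return stream


@dataclass
class Seq2SeqPair:
    """One training pair: a therapist statement and the client statement that
    immediately follows it. ``target`` carries no eos; the trainer appends it."""

    source: list[str]
    target: list[str]

    def __post_init__(self) -> None:
        if not self.source or not self.target:
            raise ValueError("source and target must be non-empty")


def _merged_statements(tr: Transcript) -> list[tuple[Speaker, list[str]]]:
    """Merge consecutive same-speaker utterances into single statements."""
    tr.tokenize()
    runs: list[tuple[Speaker, list[str]]] = []
    for utt in tr.utterances:
        if runs and runs[-1][0] == utt.speaker:
            runs[-1][1].extend(utt.tokens)
        else:
            runs.append((utt.speaker, list(utt.tokens)))
    return runs


def make_seq2seq_pairs(transcripts: Iterable[Transcript]) -> list[Seq2SeqPair]:
    """One pair per therapist→client statement adjacency, after merging
    consecutive same-speaker utterances into single statements."""
    pairs: list[Seq2SeqPair] = []
    for tr in transcripts:
        runs = _merged_statements(tr)
        for (spk_a, toks_a), (spk_b, toks_b) in zip(runs, runs[1:]):
            if spk_a == Speaker.THERAPIST and spk_b == Speaker.CLIENT:
                if toks_a and toks_b:
                    pairs.append(Seq2SeqPair(list(toks_a), list(toks_b)))
    return pairs


def split_train_test(
    transcripts: Sequence[Transcript], test_frac: float, seed: int
) -> tuple[list[Transcript], list[Transcript]]:
    """Transcript-level random split (no utterance leakage across the split).

    Test size is ``round(n * test_frac)`` but at least 1; reproducible for a
    fixed seed.
    """
    if not 0 < test_frac < 1:
        raise ValueError("test_frac must be in (0, 1)")
    if len(transcripts) < 2:
        raise ValueError("need at least 2 transcripts to split")
    import numpy as np

    rng = np.random.default_rng(seed)
    n = len(transcripts)
    n_test = max(1, round(n * test_frac))
    perm = rng.permutation(n)
    test_idx = set(perm[:n_test].tolist())
    train = [transcripts[i] for i in range(n) if i not in test_idx]
    test = [transcripts[i] for i in range(n) if i in test_idx]
    return train, test


def read_transcripts(path: str | Path) -> list[Transcript]:
    """Read JSONL transcripts; malformed records raise with the line number."""
    by_id: dict[str, Transcript] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as e:
                raise ValueError(f"line {lineno}: invalid JSON ({e})") from None
            for key in ("transcript_id", "speaker", "text"):
                if key not in rec:
                    raise ValueError(f"line {lineno}: missing field '{key}'")
            try:
                speaker = Speaker(rec["speaker"])
            except ValueError:
                raise ValueError(
                    f"line {lineno}: bad speaker value {rec['speaker']!r}"
                ) from None
            tid = str(rec["transcript_id"])
            tr = by_id.setdefault(tid, Transcript(tid))
            tr.utterances.append(Utterance(speaker, rec["text"]))
    return list(by_id.values())


def write_transcripts(transcripts: Iterable[Transcript], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for tr in transcripts:
            for utt in tr.utterances:
                fh.write(
                    json.dumps(
                        {
                            "transcript_id": tr.id,
                            "speaker": utt.speaker.value,
                            "text": utt.text,
                        }
                    )
                    + "\n"
                )
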