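"""Utterance-level counseling-skill coding.

Each trainee statement is assigned one MISC-style code — open question,
closed question, reflection, or other — by an L2-regularized multinomial
logistic regression over discrete sentence features (unigrams, bigrams, a
question-mark indicator, the first token, and a length bucket).  Agreement
between two label sequences is quantified with Cohen's kappa.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.feature_extraction import DictVectorizer
from sklearn.linear_model import LogisticRegression

from .corpus import tokenize

__all__ = [
    "SkillLabel",
    "featurize",
    "SkillClassifier",
    "train_skill_classifier",
    "classify_utterance",
    "AgreementReport",
    "cohen_kappa",
    "read_labeled_tsv",
    "write_labeled_tsv",
]


class SkillLabel(str, Enum):
    OPEN_QUESTION = "open_question"
    CLOSED_QUESTION = "closed_question"
    REFLECTION = "reflection"
    OTHER = "other"


#: Fixed label order used for deterministic tie-breaking.
LABEL_ORDER = (
    SkillLabel.OPEN_QUESTION,
    SkillLabel.CLOSED_QUESTION,
    SkillLabel.REFLECTION,
    SkillLabel.OTHER,
)


def _tokens_of(utterance) -> list[str]:
    if isinstance(utterance, str):
        return tokenize(utterance)
    return list(utterance)


def featurize(utterance) -> dict[str, float]:
    """Discrete sentence features for one utterance (text or token list).

    Unigram and bigram counts, an ends-with-question-mark indicator, the
    identity of the first token, and a coarse token-count bucket.
    """
    tokens = _tokens_of(utterance)
    if not tokens:
        raise ValueError("cannot featurize an empty utterance")
    feats: dict[str, float] = {}
    for tok in tokens:
        feats[f"u={tok}"] = feats.get(f"u={tok}", 0.0) + 1.0
    for a, b in zip(tokens, tokens[1:]):
        key = f"b={a}_{b}"
        feats[key] = feats.get(key, 0.0) + 1.0
    feats["ends_q"] = 1.0 if tokens[-1] == "?" else 0.0
    feats[f"first={tokens[0]}"] = 1.0
    n = len(tokens)
    bucket = "short" if n <= 3 else ("medium" if n <= 9 else "long")
    feats[f"len={bucket}"] = 1.0
    return feats


@dataclass
class SkillClassifier:
    """Multinomial logistic model over discrete sentence features."""

    vectorizer: DictVectorizer
    model: LogisticRegression
    labels: tuple[SkillLabel, ...]
    _cache: dict[str, SkillLabel] = field(default_factory=dict, repr=False)

    def posterior(self, utterance) -> dict[SkillLabel, float]:
        X = self.vectorizer.transform([featurize(utterance)])
        proba = self.model.predict_proba(X)[0]
        by_class = {SkillLabel(c): float(p) for c, p in zip(self.model.classes_, proba)}
        return {lab: by_class.get(lab, 0.0) for lab in LABEL_ORDER}

    def classify(self, utterance) -> SkillLabel:
        post = self.posterior(utterance)
        best = max(post.values())
        for lab in LABEL_ORDER:  # fixed order breaks exact ties
            if post[lab] == best:
                return lab
        raise AssertionError("unreachable")

    def classify_cached(self, text: str) -> SkillLabel:
        """Classify with memoization on the normalized text.

        Intended for simulation loops where utterances come from a finite
        template set; identical inputs always yield identical labels, so
        caching cannot change any output.
        """
        key = " ".join(tokenize(text))
        hit = self._cache.get(key)
        if hit is None:
            hit = self._cache[key] = self.classify(text)
        return hit

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump({"vectorizer": self.vectorizer, "model": self.model,
                         "labels": self.labels}, fh)

    @classmethod
    def load(cls, path: str | Path) -> "SkillClassifier":
        with open(path, "rb") as fh:
            d = pickle.load(fh)
        return cls(d["vectorizer"], d["model"], d["labels"])


def train_skill_classifier(labeled: Sequence[tuple], regularization: float = 1.0,
                           seed: int = 0) -> SkillClassifier:
    """Fit the skill classifier on (utterance, SkillLabel) examples.

    ``regularization`` is the inverse-variance weight of the L2 penalty
    (sklearn's ``C`` is its reciprocal).  The fit is convex, so the same data
    always yields the same decision function.
    """
    if not labeled:
        raise ValueError("no training data")
    texts, labels = zip(*labeled)
    labels = [SkillLabel(l) for l in labels]
    present = set(labels)
    if len(present) < 2:
        raise ValueError("need at least 2 distinct labels to train")
    vectorizer = DictVectorizer()
    X = vectorizer.fit_transform([featurize(t) for t in texts])
    model = LogisticRegression(
        C=1.0 / regularization, max_iter=2000, random_state=seed,
    )
    model.fit(X, [l.value for l in labels])
    return SkillClassifier(vectorizer, model, tuple(sorted(present, key=LABEL_ORDER.index)))


def classify_utterance(model: SkillClassifier, utterance) -> SkillLabel:
    return model.classify(utterance)


@dataclass
class AgreementReport:
    observed_agreement: float
    expected_agreement: float
    kappa: float
    confusion: dict[tuple, int]


def cohen_kappa(labels_a: Sequence, labels_b: Sequence) -> AgreementReport:
    """Chance-corrected agreement: kappa = (p_o - p_e) / (1 - p_e).

    ``p_e`` is the sum of products of the two raters' marginal proportions.
    When ``p_e`` is 1 (both raters constant on the same label) agreement is
    perfect by definition and kappa is 1; a constant disagreement with
    ``p_e`` = 1 is undefined and raises.
    """
    if len(labels_a) != len(labels_b):
        raise ValueError("label sequences must have equal length")
    n = len(labels_a)
    if n == 0:
        raise ValueError("empty label sequences")
    confusion: dict[tuple, int] = {}
    for a, b in zip(labels_a, labels_b):
        confusion[(a, b)] = confusion.get((a, b), 0) + 1
    p_o = sum(c for (a, b), c in confusion.items() if a == b) / n
    cats = sorted({a for a, _ in confusion} | {b for _, b in confusion}, key=str)
    marg_a = {c: sum(v for (a, _), v in confusion.items() if a == c) / n for c in cats}
    marg_b = {c: sum(v for (_, b), v in confusion.items() if b == c) / n for c in cats}
    p_e = sum(marg_a[c] * marg_b[c] for c in cats)
    if p_e >= 1.0 - 1e-12:
        if p_o >= 1.0 - 1e-12:
            kappa = 1.0
        else:
            raise ValueError("kappa undefined: expected agreement is 1 but observed is not")
    else:
        kappa = (p_o - p_e) / (1.0 - p_e)
    return AgreementReport(p_o, p_e, kappa, confusion)


def read_labeled_tsv(path: str | Path) -> list[tuple[str, SkillLabel]]:
    """TSV with columns label, text (no header)."""
    out: list[tuple[str, SkillLabel]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            try:
                label, text = line.split("\t", 1)
                out.append((text, SkillLabel(label)))
            except ValueError:
                raise ValueError(f"line {lineno}: expected 'label<TAB>text'") from None
    return out


def write_labeled_tsv(labeled: Iterable[tuple[str, SkillLabel]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for text, label in labeled:
            fh.write(f"{SkillLabel(label).value}\t{text}\n")
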