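"""Synthetic stand-ins for everything the original proprietary data provided.

Three generators, all template-grammar based and bit-reproducible under a
seed:

* dialogue corpora for training the conversational models — alternating
  therapist/client turns, where client turns mix short small talk with
  longer symptom-laden talk containing numerals and spoken-language
  disfluencies;
* labeled utterances for the skill coder, built so the four skill classes
  are true by construction and separable by the coder's feature set;
* simulated trainees for end-to-end randomized-trial simulation.  A trainee
  samples each utterance's skill from a multinomial; a feedback event adds a
  boost toward the prompted skill, part of which decays turn by turn and
  part of which persists (skill retention after feedback is removed).  The
  effect size is an input of the simulation, never an output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .coder import SkillClassifier, SkillLabel, train_skill_classifier
from .corpus import Speaker, Transcript, Utterance
from .curriculum import (
    Arm,
    CONVERSATIONAL_PHASES,
    CurriculumConfig,
    SessionLog,
    handle_trainee_turn,
    init_session,
    record_satisfaction,
    run_posttest,
    run_quiz,
)

__all__ = [
    "CorpusGenConfig",
    "TraineeAgentConfig",
    "TraineeAgent",
    "generate_corpus",
    "generate_labeled_utterances",
    "default_coder",
    "simulate_trainee_turn",
    "simulate_rct",
]


# -- template grammars -------------------------------------------------------

_TOPICS = ("work", "sleep", "your family", "drinking", "the medication",
           "school", "money", "your health")

_OPEN_STEMS = ("what do you think about", "how do you feel about",
               "why is it hard to talk about", "tell me more about",
               "what has been going on with", "how are things with")

_CLOSED_STEMS = ("do you worry about", "did you talk to anyone about",
                 "are you concerned about", "is it hard to deal with",
                 "have you thought about", "does anyone know about")

_REFLECTION_STEMS = ("it sounds like you are worried about",
                     "you feel overwhelmed by", "so you have been struggling with",
                     "it sounds like you have a lot on your mind about",
                     "you feel unsure about", "so you keep coming back to")

_OTHER_LINES = ("ok .", "i see .", "right .", "mm-hmm .", "that makes sense .",
                "yeah , i understand .", "thanks for sharing that .", "hello .",
                "good morning .", "let us keep going .")

_SMALL_TALK = ("yeah .", "i am fine .", "ok , sure .", "not much , really .",
               "hi , how are you ?", "pretty good today .", "i guess so .")

_SYMPTOM_LINES = (
    "i have not been sleeping much lately , maybe {n} hours a night .",
    "i take {n} pills in the morning and it still does not help .",
    "work has been piling up and i missed {n} days this month .",
    "i have been feeling down for about {n} weeks now .",
    "my doctor changed my prescription {n} times already .",
    "i keep arguing with my family , it happened {n} times this week .",
)

_DISFLUENCIES = ("uh ,", "um ,", "you know ,", "i mean ,")


def _open_question(rng: np.random.Generator) -> str:
    return f"{_choice(rng, _OPEN_STEMS)} {_choice(rng, _TOPICS)} ?"


def _closed_question(rng: np.random.Generator) -> str:
    return f"{_choice(rng, _CLOSED_STEMS)} {_choice(rng, _TOPICS)} ?"


def _reflection(rng: np.random.Generator) -> str:
    return f"{_choice(rng, _REFLECTION_STEMS)} {_choice(rng, _TOPICS)} ."


def _other(rng: np.random.Generator) -> str:
    return _choice(rng, _OTHER_LINES)


_MAKERS = {
    SkillLabel.OPEN_QUESTION: _open_question,
    SkillLabel.CLOSED_QUESTION: _closed_question,
    SkillLabel.REFLECTION: _reflection,
    SkillLabel.OTHER: _other,
}


def _choice(rng: np.random.Generator, seq: Sequence[str]) -> str:
    return seq[int(rng.integers(len(seq)))]


# -- corpus generator --------------------------------------------------------

@dataclass
class CorpusGenConfig:
    n_transcripts: int = 40
    min_turns: int = 6
    max_turns: int = 12
    numeral_rate: float = 0.6  # share of symptom lines carrying a numeral
    disfluency_rate: float = 0.3
    symptom_rate: float = 0.6  # vs short small talk, for client turns
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.numeral_rate, self.disfluency_rate, self.symptom_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if self.min_turns < 2 or self.max_turns < self.min_turns:
            raise ValueError("need max_turns >= min_turns >= 2")


def _client_line(rng: np.random.Generator, cfg: CorpusGenConfig) -> str:
    if rng.random() < cfg.symptom_rate:
        template = _choice(rng, _SYMPTOM_LINES)
        if rng.random() < cfg.numeral_rate:
            line = template.format(n=int(rng.integers(1, 20)))
        else:
            line = template.format(n="a few")
    else:
        line = _choice(rng, _SMALL_TALK)
    if rng.random() < cfg.disfluency_rate:
        words = line.split(" ")
        words.insert(1, _choice(rng, _DISFLUENCIES))
        line = " ".join(words)
    return line


def _therapist_line(rng: np.random.Generator) -> str:
    kind = _choice(rng, ("open", "closed", "reflection", "other"))
    return {"open": _open_question, "closed": _closed_question,
            "reflection": _reflection, "other": _other}[kind](rng)


def generate_corpus(config: CorpusGenConfig) -> list[Transcript]:
    """Alternating therapist/client transcripts from the template grammars."""
    rng = np.random.default_rng(config.seed)
    transcripts = []
    for i in range(config.n_transcripts):
        n_turns = int(rng.integers(config.min_turns, config.max_turns + 1))
        utts = []
        for t in range(n_turns):
            if t % 2 == 0:
                utts.append(Utterance(Speaker.THERAPIST, _therapist_line(rng)))
            else:
                utts.append(Utterance(Speaker.CLIENT, _client_line(rng, config)))
        transcripts.append(Transcript(f"syn-{i:04d}", utts))
    return transcripts


# -- labeled utterances for the coder ---------------------------------------

def generate_labeled_utterances(n_per_label: int, seed: int
                                ) -> list[tuple[str, SkillLabel]]:
    """(utterance, label) pairs, ``n_per_label`` for each of the four codes.

    Labels are true by construction: open questions use open interrogative
    stems and end with "?", closed questions use yes/no auxiliary stems,
    reflections use restating declarative stems, and "other" is backchannel
    or filler talk.
    """
    if n_per_label < 1:
        raise ValueError("n_per_label must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[tuple[str, SkillLabel]] = []
    for label in SkillLabel:
        maker = _MAKERS[label]
        for _ in range(n_per_label):
            out.append((maker(rng), label))
    perm = rng.permutation(len(out))
    return [out[i] for i in perm]


def default_coder(seed: int = 0, n_per_label: int = 100) -> SkillClassifier:
    """Skill classifier trained on the synthetic labeled set."""
    return train_skill_classifier(generate_labeled_utterances(n_per_label, seed),
                                  seed=seed)


# -- simulated trainee -------------------------------------------------------

@dataclass
class TraineeAgentConfig:
    """Behavior model of a simulated trainee.

    ``baseline`` is the skill distribution of an untrained person (defaults
    follow the pre-training rates of the study population this package
    emulates: about a quarter open questions and under a tenth reflections).
    A feedback event adds ``responsiveness`` to a boost toward the prompted
    skill; a ``retention`` share of the boost persists after feedback stops,
    the rest decays by ``decay`` per turn.  ``responsiveness`` = 0 makes
    feedback inert, so both arms behave identically.
    """

    baseline: dict[SkillLabel, float] = field(default_factory=lambda: {
        SkillLabel.OPEN_QUESTION: 0.24,
        SkillLabel.CLOSED_QUESTION: 0.15,
        SkillLabel.REFLECTION: 0.09,
        SkillLabel.OTHER: 0.52,
    })
    responsiveness: float = 1.0
    decay: float = 0.1
    retention: float = 0.6
    max_boost: float = 0.85
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.baseline.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("baseline distribution must sum to 1")
        if self.responsiveness < 0:
            raise ValueError("responsiveness must be >= 0")
        for r in (self.decay, self.retention):
            if not 0.0 <= r <= 1.0:
                raise ValueError("decay and retention must be in [0, 1]")


class TraineeAgent:
    """Multinomial-with-shift trainee: samples a skill, emits a template
    utterance of that class."""

    def __init__(self, config: TraineeAgentConfig, seed: int | None = None):
        self.config = config
        self.rng = np.random.default_rng(config.seed if seed is None else seed)
        self.transient = 0.0
        self.persistent = 0.0
        self.prompted: SkillLabel | None = None
        self.last_label: SkillLabel | None = None

    def observe_feedback(self, skill: SkillLabel) -> None:
        rho = self.config.responsiveness
        self.prompted = skill if rho > 0 else self.prompted
        self.transient += rho * (1.0 - self.config.retention)
        self.persistent += rho * self.config.retention

    def distribution(self) -> dict[SkillLabel, float]:
        base = self.config.baseline
        w = min(self.transient + self.persistent, self.config.max_boost)
        if self.prompted is None or w == 0.0:
            return dict(base)
        return {lab: (1.0 - w) * p + (w if lab is self.prompted else 0.0)
                for lab, p in base.items()}

    def respond(self, last_bot_utterance: str | None = None,
                pending_feedback: SkillLabel | None = None) -> str:
        if pending_feedback is not None:
            self.observe_feedback(pending_feedback)
        dist = self.distribution()
        labels = list(dist)
        probs = np.array([dist[l] for l in labels])
        label = labels[int(self.rng.choice(len(labels), p=probs / probs.sum()))]
        self.last_label = label
        self.transient *= 1.0 - self.config.decay
        return _MAKERS[label](self.rng)


def simulate_trainee_turn(agent: TraineeAgent, last_bot_utterance: str | None,
                          pending_feedback: SkillLabel | None) -> str:
    """One simulated trainee utterance (see :class:`TraineeAgent`)."""
    return agent.respond(last_bot_utterance, pending_feedback)


# -- end-to-end randomized trial --------------------------------------------

def _run_session(arm: Arm, agent: TraineeAgent, config: CurriculumConfig,
                 coder: SkillClassifier, seed: int, models=None) -> SessionLog:
    session = init_session(arm, config, models, coder, seed)
    run_quiz(session, [q["answer"] for q in session.config.quiz_questions])
    last_bot: str | None = None
    pending: SkillLabel | None = None
    while session.phase in CONVERSATIONAL_PHASES:
        text = agent.respond(last_bot, pending)
        pending = None
        event = handle_trainee_turn(session, text)
        if event is None:
            continue
        if "feedback_skill" in event:
            pending = SkillLabel(event["feedback_skill"])
        bot_events = [e for e in session.log.events if e["kind"] == "bot"]
        last_bot = bot_events[-1]["text"] if bot_events else None
    responses = [agent.respond(prompt, None) for prompt in config.posttest_prompts]
    run_posttest(session, responses)
    record_satisfaction(session, {
        "system": int(session.rng.integers(2, 5)),
        "person": int(session.rng.integers(1, 4)),
        "overall": int(session.rng.integers(2, 5)),
    })
    return session.log


def simulate_rct(n_per_arm: int, agent_config: TraineeAgentConfig,
                 curriculum_config: CurriculumConfig, seed: int,
                 coder: SkillClassifier | None = None, models=None
                 ) -> list[SessionLog]:
    """Run a full two-arm simulated trial and return all session logs.

    Treatment and control trainees share one agent configuration; the arm —
    and therefore whether feedback events ever reach the agent — is the only
    difference between groups.
    """
    if n_per_arm < 2:
        raise ValueError("need at least 2 participants per arm")
    if coder is None:
        coder = default_coder(seed=0)
    rng = np.random.default_rng(seed)
    logs: list[SessionLog] = []
    for arm in (Arm.TREATMENT, Arm.CONTROL):
        for _ in range(n_per_arm):
            agent_seed = int(rng.integers(0, 2**31 - 1))
            session_seed = int(rng.integers(0, 2**31 - 1))
            agent = TraineeAgent(agent_config, seed=agent_seed)
            logs.append(_run_session(arm, agent, curriculum_config, coder,
                                     session_seed, models=models))
    return logs
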