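"""The staged training session.

A session walks a fixed curriculum: introduction + 3-question quiz, then six
conversational/assessment phases — before training, open-question training,
reflection training, combined training, a test phase with all feedback and
prompts removed, and a fixed posttest of 5 standardized client statements.
Trainees are randomized to a treatment arm (real-time skill feedback during
the training phases) or a control arm (identical instruction and prompts,
no feedback).  Every event is appended to a session log that round-trips
through JSONL.

Feedback rule: in a feedback-enabled phase of a treatment session, if the
share of the trainee's last ``feedback_window`` utterances that used the
phase's target skill falls below ``feedback_threshold`` percent (and the
cooldown has expired), the system prompts them to practice the skill, with
an example.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np

from .coder import SkillClassifier, SkillLabel
from .corpus import Speaker, Utterance
from .decoding import DialogueState, PolicyConfig, respond

__all__ = [
    "Arm",
    "Phase",
    "PhaseSpec",
    "FeedbackEvent",
    "QuizResult",
    "CurriculumConfig",
    "SessionLog",
    "Session",
    "init_session",
    "run_quiz",
    "handle_trainee_turn",
    "check_feedback",
    "advance_phase",
    "run_posttest",
    "write_session_log",
    "read_session_log",
]


class Arm(str, Enum):
    TREATMENT = "treatment"
    CONTROL = "control"


class Phase(str, Enum):
    INTRO = "intro"  # introduction + quiz, pre-conversational
    BEFORE_TRAINING = "before_training"
    OPEN_QUESTION_TRAINING = "open_question_training"
    REFLECTION_TRAINING = "reflection_training"
    TRAINING_BOTH = "training_both"
    TEST = "test"
    POSTTEST_FIXED = "posttest_fixed"


#: The six assessed phases, in curriculum order.
PHASE_ORDER = (
    Phase.BEFORE_TRAINING,
    Phase.OPEN_QUESTION_TRAINING,
    Phase.REFLECTION_TRAINING,
    Phase.TRAINING_BOTH,
    Phase.TEST,
    Phase.POSTTEST_FIXED,
)

CONVERSATIONAL_PHASES = PHASE_ORDER[:5]


@dataclass
class PhaseSpec:
    name: Phase
    target_skills: frozenset[SkillLabel]
    feedback_enabled: bool
    turns: int


_SKILL_EXAMPLES = {
    SkillLabel.OPEN_QUESTION: "what has that been like for you ?",
    SkillLabel.REFLECTION: "it sounds like this has been weighing on you .",
}

_SKILL_NAMES = {
    SkillLabel.OPEN_QUESTION: "open questions",
    SkillLabel.REFLECTION: "reflections",
}

_DEFAULT_INTRO = (
    "welcome . in this session you will practice two listening skills . "
    "an open question invites the other person to elaborate , for example : "
    "' what brings you here today ? ' . a reflection restates what the other "
    "person has said , for example : ' it sounds like you are worried about "
    "work . ' you will chat with a simulated person and practice these skills ."
)

_DEFAULT_QUIZ = (
    {
        "question": "which of these is an open question ?",
        "options": ["do you smoke ?", "what has your week been like ?", "i see ."],
        "answer": 1,
    },
    {
        "question": "which of these is a reflection ?",
        "options": ["how old are you ?", "it sounds like you feel stuck .", "ok ."],
        "answer": 1,
    },
    {
        "question": "what are you practicing in this session ?",
        "options": ["diagnosis", "listening skills", "typing speed"],
        "answer": 1,
    },
)

_DEFAULT_POSTTEST_PROMPTS = (
    "i got a new prescription but i am not sure it is helping",
    "my family keeps saying that i drink too much",
    "i have been missing work a lot lately , you know , because of the parties",
    "i take 2 pills at night and i still cannot sleep",
    "everything at my job piles up and it never seems to end",
)

_PHASE_PROMPTS = {
    Phase.BEFORE_TRAINING: "to begin , just chat with the simulated person .",
    Phase.OPEN_QUESTION_TRAINING: "now practice open questions .",
    Phase.REFLECTION_TRAINING: "now practice reflections .",
    Phase.TRAINING_BOTH: "now practice both open questions and reflections .",
    Phase.TEST: "for the last 5 minutes , show us your best listening skills .",
    Phase.POSTTEST_FIXED: "please respond to 5 example client statements using the skills you have learned .",
}

#: Canned client lines used when a session runs without neural models
#: (e.g. large simulation studies); drawn uniformly per turn.
_TEMPLATE_CLIENT_LINES = (
    "well , i guess it was just one of those things .",
    "i have not been sleeping much lately .",
    "yeah , maybe .",
    "my job has been really stressful , you know .",
    "i take 2 pills in the morning and then , uh , 1 at night .",
    "i do not really talk about it with anyone .",
    "it has been a hard month .",
    "hm , i had not thought about it that way .",
)


@dataclass
class CurriculumConfig:
    phase_turns: dict[Phase, int] = field(default_factory=lambda: {
        Phase.BEFORE_TRAINING: 10,
        Phase.OPEN_QUESTION_TRAINING: 10,
        Phase.REFLECTION_TRAINING: 10,
        Phase.TRAINING_BOTH: 10,
        Phase.TEST: 10,
    })
    feedback_window: int = 5
    feedback_threshold: float = 20.0  # percent of window using a target skill
    feedback_cooldown: int = 3  # trainee turns between feedback events
    intro_text: str = _DEFAULT_INTRO
    quiz_questions: tuple = _DEFAULT_QUIZ
    posttest_prompts: tuple = _DEFAULT_POSTTEST_PROMPTS
    policy: PolicyConfig = field(default_factory=PolicyConfig)

    def __post_init__(self) -> None:
        if self.feedback_window < 1:
            raise ValueError("feedback_window must be >= 1")
        if not 0 <= self.feedback_threshold <= 100:
            raise ValueError("feedback_threshold must be in [0, 100]")
        if len(self.posttest_prompts) != 5:
            raise ValueError("exactly 5 posttest prompts required")
        if len(self.quiz_questions) != 3:
            raise ValueError("exactly 3 quiz questions required")

    @classmethod
    def reduced(cls, training_turns: int = 4, test_turns: int = 8) -> "CurriculumConfig":
        """Short-session variant used for large simulation studies."""
        return cls(phase_turns={
            Phase.BEFORE_TRAINING: training_turns,
            Phase.OPEN_QUESTION_TRAINING: training_turns,
            Phase.REFLECTION_TRAINING: training_turns,
            Phase.TRAINING_BOTH: training_turns,
            Phase.TEST: test_turns,
        })

    def phase_specs(self) -> dict[Phase, PhaseSpec]:
        targets = {
            Phase.BEFORE_TRAINING: frozenset(),
            Phase.OPEN_QUESTION_TRAINING: frozenset({SkillLabel.OPEN_QUESTION}),
            Phase.REFLECTION_TRAINING: frozenset({SkillLabel.REFLECTION}),
            Phase.TRAINING_BOTH: frozenset({SkillLabel.OPEN_QUESTION, SkillLabel.REFLECTION}),
            Phase.TEST: frozenset({SkillLabel.OPEN_QUESTION, SkillLabel.REFLECTION}),
            Phase.POSTTEST_FIXED: frozenset(),
        }
        feedback_on = {Phase.OPEN_QUESTION_TRAINING, Phase.REFLECTION_TRAINING,
                       Phase.TRAINING_BOTH}
        return {
            p: PhaseSpec(p, targets[p], p in feedback_on,
                         self.phase_turns.get(p, 0) if p is not Phase.POSTTEST_FIXED else 5)
            for p in PHASE_ORDER
        }


@dataclass
class FeedbackEvent:
    phase: Phase
    turn: int
    window_rate: float  # percent of recent turns using the target skill
    skill: SkillLabel  # the skill the prompt asks for
    prompt: str


@dataclass
class QuizResult:
    correct: list[bool]
    attempts: int = 1


@dataclass
class SessionLog:
    """Flat, JSON-serializable record of one full session."""

    session_id: str
    arm: Arm
    seed: int
    events: list[dict] = field(default_factory=list)
    satisfaction: dict | None = None


class Session:
    """Mutable state of one trainee's pass through the curriculum."""

    def __init__(self, session_id: str, arm: Arm, config: CurriculumConfig,
                 models, coder: SkillClassifier, seed: int):
        self.arm = Arm(arm)
        self.config = config
        self.models = models  # (seq2seq, lm) or None for the template responder
        self.coder = coder
        self.seed = seed
        self.rng = np.random.default_rng(seed)
        self.specs = config.phase_specs()
        self.phase: Phase = Phase.INTRO
        self.phase_turns = 0  # trainee turns taken in the current phase
        self.turns_since_feedback: int | None = None  # None = no feedback yet this phase
        self.window: list[SkillLabel] = []  # recent labels in the current phase
        self.quiz: QuizResult | None = None
        self.completed = False
        self.log = SessionLog(session_id, self.arm, seed)
        self.dialogue = DialogueState(rng=np.random.default_rng(seed + 1))
        self._t = 0
        self._emit("system", text=config.intro_text)

    # -- logging -----------------------------------------------------------
    def _emit(self, kind: str, **fields) -> dict:
        event = {"t": self._t, "kind": kind, **fields}
        self._t += 1
        self.log.events.append(event)
        return event

    # -- bot side ----------------------------------------------------------
    def _bot_reply(self, trainee_text: str) -> tuple[str, str]:
        if self.models is not None:
            utt, _ = respond(self.dialogue, trainee_text, self.models, self.config.policy)
            return utt.text, utt.source
        line = _TEMPLATE_CLIENT_LINES[int(self.rng.integers(len(_TEMPLATE_CLIENT_LINES)))]
        return line, "template"


def init_session(arm: Arm, config: CurriculumConfig, models, coder: SkillClassifier,
                 seed: int, session_id: str | None = None) -> Session:
    """Start a session: both arms get byte-identical introduction content."""
    sid = session_id or f"session-{Arm(arm).value}-{seed}"
    return Session(sid, arm, config, models, coder, seed)


def run_quiz(session: Session, answers: Sequence[int]) -> QuizResult:
    """Score the 3-question comprehension quiz.

    The quiz is a minimal engagement check: progression is never gated on
    the score.  Completing it moves the session into the first
    conversational phase.
    """
    if len(answers) != len(session.config.quiz_questions):
        raise ValueError(f"expected {len(session.config.quiz_questions)} answers")
    correct = [int(a) == q["answer"] for a, q in zip(answers, session.config.quiz_questions)]
    session.quiz = QuizResult(correct=correct)
    session._emit("quiz", correct=correct)
    if session.phase is Phase.INTRO:
        advance_phase(session)
    return session.quiz


def check_feedback(window: Sequence[SkillLabel], phase: PhaseSpec, arm: Arm,
                   config: CurriculumConfig, turns_since_feedback: int | None,
                   turn: int) -> FeedbackEvent | None:
    """Decide whether to prompt the trainee to use the target skill more.

    Fires only for the treatment arm, in feedback-enabled phases, once the
    window is full, when the target-skill rate is below the threshold, and
    when the cooldown since the previous feedback has expired.
    """
    if arm is not Arm.TREATMENT or not phase.feedback_enabled:
        return None
    if len(window) < config.feedback_window:
        return None
    if turns_since_feedback is not None and turns_since_feedback < config.feedback_cooldown:
        return None
    recent = list(window)[-config.feedback_window:]
    rate = 100.0 * sum(1 for l in recent if l in phase.target_skills) / len(recent)
    if rate >= config.feedback_threshold:
        return None
    # name the target skill the trainee is using least
    skills = sorted(phase.target_skills,
                    key=lambda s: (sum(1 for l in recent if l is s), s.value))
    skill = skills[0] if skills else SkillLabel.REFLECTION
    prompt = (f"try to use more {_SKILL_NAMES[skill]} , for example : "
              f"' {_SKILL_EXAMPLES[skill]} '")
    return FeedbackEvent(phase=phase.name, turn=turn, window_rate=rate, skill=skill,
                         prompt=prompt)


def handle_trainee_turn(session: Session, text: str) -> dict | None:
    """Process one trainee utterance: label it, reply, maybe give feedback.

    Returns the trainee event dict, or None for empty input (the trainee is
    re-prompted; nothing is logged).  Automatically advances the phase when
    its turn budget is spent.
    """
    if session.phase not in CONVERSATIONAL_PHASES:
        raise ValueError(f"session is not in a conversational phase (in {session.phase.value})")
    if not text.strip():
        return None
    label = session.coder.classify_cached(text)
    spec = session.specs[session.phase]
    event = session._emit("trainee", phase=session.phase.value, text=text, label=label.value)
    bot_text, bot_source = session._bot_reply(text)
    session._emit("bot", phase=session.phase.value, text=bot_text, source=bot_source)
    session.window.append(label)
    session.phase_turns += 1
    if session.turns_since_feedback is not None:
        session.turns_since_feedback += 1
    fb = check_feedback(session.window, spec, session.arm, session.config,
                        session.turns_since_feedback, session.phase_turns)
    if fb is not None:
        session._emit("feedback", phase=fb.phase.value, turn=fb.turn,
                      window_rate=fb.window_rate, skill=fb.skill.value, prompt=fb.prompt)
        session.turns_since_feedback = 0
        event["feedback"] = fb.prompt
        event["feedback_skill"] = fb.skill.value
    if session.phase_turns >= session.specs[session.phase].turns:
        advance_phase(session)
    return event


def advance_phase(session: Session, clock=None) -> Session:
    """Move to the next phase in the fixed order, emitting its prompt."""
    if session.completed:
        raise ValueError("session already completed")
    order = (Phase.INTRO,) + PHASE_ORDER
    nxt = order[order.index(session.phase) + 1]
    session.phase = nxt
    session.phase_turns = 0
    session.turns_since_feedback = None
    session.window = []
    session._emit("phase", phase=nxt.value)
    session._emit("system", text=_PHASE_PROMPTS[nxt])
    return session


def run_posttest(session: Session, responses: Sequence[str]) -> list[dict]:
    """Score the 5 fixed-prompt responses and complete the session.

    The prompts are identical for every session and both arms.
    """
    if session.phase is not Phase.POSTTEST_FIXED:
        raise ValueError("session is not in the posttest phase")
    if len(responses) != 5:
        raise ValueError("exactly 5 posttest responses required")
    events = []
    for prompt, response in zip(session.config.posttest_prompts, responses):
        label = session.coder.classify_cached(response)
        events.append(session._emit("posttest", phase=Phase.POSTTEST_FIXED.value,
                                    prompt=prompt, text=response, label=label.value))
    session.completed = True
    return events


def record_satisfaction(session: Session, answers: dict[str, int]) -> None:
    """Attach 1–5 satisfaction item scores to the log."""
    for item, score in answers.items():
        if score not in (1, 2, 3, 4, 5):
            raise ValueError(f"satisfaction score for {item!r} must be 1..5")
    session.log.satisfaction = dict(answers)


# -- log I/O ----------------------------------------------------------------

def write_session_log(log: SessionLog, path: str | Path) -> None:
    """JSONL: one header line, then one event per line."""
    with open(path, "w", encoding="utf-8") as fh:
        header = {"session_id": log.session_id, "arm": log.arm.value, "seed": log.seed,
                  "satisfaction": log.satisfaction}
        fh.write(json.dumps({"kind": "header", **header}) + "\n")
        for event in log.events:
            fh.write(json.dumps(event) + "\n")


def read_session_log(path: str | Path) -> SessionLog:
    with open(path, encoding="utf-8") as fh:
        lines = [json.loads(l) for l in fh if l.strip()]
    if not lines or lines[0].get("kind") != "header":
        raise ValueError("missing session log header")
    head = lines[0]
    return SessionLog(session_id=head["session_id"], arm=Arm(head["arm"]),
                      seed=head["seed"], events=lines[1:],
                      satisfaction=head.get("satisfaction"))
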