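import numpy as np
import pytest

from clientbot.coder import SkillLabel
from clientbot.curriculum import (
    Arm,
    CONVERSATIONAL_PHASES,
    CurriculumConfig,
    Phase,
    PHASE_ORDER,
    advance_phase,
    check_feedback,
    handle_trainee_turn,
    init_session,
    read_session_log,
    run_posttest,
    run_quiz,
    write_session_log,
)
from clientbot.synthetic import TraineeAgent, TraineeAgentConfig, simulate_rct

O, R, X = SkillLabel.OPEN_QUESTION, SkillLabel.REFLECTION, SkillLabel.OTHER

REFLECTION_TEXT = "it sounds like you are worried about work ."
OTHER_TEXT = "ok ."
OPEN_TEXT = "what has been going on with work ?"


@pytest.fixture
def small_config():
    return CurriculumConfig.reduced(training_turns=6, test_turns=6)


def _start(arm, config, coder, seed=0):
    session = init_session(arm, config, None, coder, seed)
    run_quiz(session, [q["answer"] for q in config.quiz_questions])
    return session


class TestSessionSetup:
    def test_both_arms_identical_introduction_and_prompts(self, small_config, trained_coder):
        t = _start(Arm.TREATMENT, small_config, trained_coder)
        c = _start(Arm.CONTROL, small_config, trained_coder)
        t_sys = [e["text"] for e in t.log.events if e["kind"] == "system"]
        c_sys = [e["text"] for e in c.log.events if e["kind"] == "system"]
        assert t_sys == c_sys
        assert t.config.posttest_prompts == c.config.posttest_prompts

    def test_same_seed_same_system_sequence(self, small_config, trained_coder):
        a = _start(Arm.TREATMENT, small_config, trained_coder, seed=3)
        b = _start(Arm.TREATMENT, small_config, trained_coder, seed=3)
        assert a.log.events == b.log.events

    def test_starts_in_intro_then_before_training(self, small_config, trained_coder):
        session = init_session(Arm.CONTROL, small_config, None, trained_coder, 0)
        assert session.phase is Phase.INTRO
        run_quiz(session, [0, 0, 0])
        assert session.phase is Phase.BEFORE_TRAINING


class TestQuiz:
    def test_all_correct(self, small_config, trained_coder):
        session = init_session(Arm.CONTROL, small_config, None, trained_coder, 0)
        result = run_quiz(session, [q["answer"] for q in small_config.quiz_questions])
        assert result.correct == [True, True, True]

    def test_wrong_answers_do_not_block_progress(self, small_config, trained_coder):
        session = init_session(Arm.CONTROL, small_config, None, trained_coder, 0)
        result = run_quiz(session, [99, 99, 99])
        assert result.correct == [False, False, False]
        assert session.phase is Phase.BEFORE_TRAINING  # progressed anyway
        assert handle_trainee_turn(session, OTHER_TEXT) is not None

    def test_partial_credit_in_question_order(self, small_config, trained_coder):
        session = init_session(Arm.CONTROL, small_config, None, trained_coder, 0)
        answers = [q["answer"] for q in small_config.quiz_questions]
        answers[2] = answers[2] + 1
        assert run_quiz(session, answers).correct == [True, True, False]

    def test_wrong_answer_count_rejected(self, small_config, trained_coder):
        session = init_session(Arm.CONTROL, small_config, None, trained_coder, 0)
        with pytest.raises(ValueError):
            run_quiz(session, [0, 0])


class TestCheckFeedback:
    def _spec(self, config):
        return config.phase_specs()[Phase.REFLECTION_TRAINING]

    def test_fires_on_low_rate(self, small_config):
        window = [X] * 5
        fb = check_feedback(window, self._spec(small_config), Arm.TREATMENT,
                            small_config, None, turn=5)
        assert fb is not None
        assert fb.skill is R
        assert "reflection" in fb.prompt and "example" in fb.prompt

    def test_never_fires_at_full_rate(self, small_config):
        fb = check_feedback([R] * 5, self._spec(small_config), Arm.TREATMENT,
                            small_config, None, turn=5)
        assert fb is None

    def test_suppressed_within_cooldown(self, small_config):
        args = ([X] * 5, self._spec(small_config), Arm.TREATMENT, small_config)
        assert check_feedback(*args, small_config.feedback_cooldown - 1, 6) is None
        assert check_feedback(*args, small_config.feedback_cooldown, 6) is not None

    def test_control_arm_never_fires(self, small_config):
        fb = check_feedback([X] * 5, self._spec(small_config), Arm.CONTROL,
                            small_config, None, turn=5)
        assert fb is None

    def test_disabled_phase_never_fires(self, small_config):
        spec = small_config.phase_specs()[Phase.TEST]
        fb = check_feedback([X] * 5, spec, Arm.TREATMENT, small_config, None, 5)
        assert fb is None

    def test_short_window_never_fires(self, small_config):
        fb = check_feedback([X] * 3, self._spec(small_config), Arm.TREATMENT,
                            small_config, None, turn=3)
        assert fb is None


class TestTurnsAndPhases:
    def test_five_nonreflections_trigger_feedback(self, small_config, trained_coder):
        session = _start(Arm.TREATMENT, small_config, trained_coder)
        while session.phase is not Phase.REFLECTION_TRAINING:
            handle_trainee_turn(session, OTHER_TEXT)
        for _ in range(5):
            handle_trainee_turn(session, OTHER_TEXT)
        feedback = [e for e in session.log.events if e["kind"] == "feedback"
                    and e["phase"] == Phase.REFLECTION_TRAINING.value]
        assert feedback and feedback[0]["skill"] == "reflection"

    def test_event_order_label_bot_feedback(self, small_config, trained_coder):
        session = _start(Arm.TREATMENT, small_config, trained_coder)
        handle_trainee_turn(session, OTHER_TEXT)
        kinds = [e["kind"] for e in session.log.events if e["kind"] in ("trainee", "bot")]
        assert kinds[:2] == ["trainee", "bot"]

    def test_empty_text_logs_nothing(self, small_config, trained_coder):
        session = _start(Arm.CONTROL, small_config, trained_coder)
        before = len(session.log.events)
        assert handle_trainee_turn(session, "   ") is None
        assert len(session.log.events) == before

    def test_phase_order_traversed(self, small_config, trained_coder):
        session = _start(Arm.CONTROL, small_config, trained_coder)
        while session.phase in CONVERSATIONAL_PHASES:
            handle_trainee_turn(session, OTHER_TEXT)
        phases = [e["phase"] for e in session.log.events if e["kind"] == "phase"]
        assert phases == [p.value for p in PHASE_ORDER]

    def test_turn_budget_honored(self, small_config, trained_coder):
        session = _start(Arm.CONTROL, small_config, trained_coder)
        for _ in range(small_config.phase_turns[Phase.BEFORE_TRAINING]):
            handle_trainee_turn(session, OTHER_TEXT)
        assert session.phase is Phase.OPEN_QUESTION_TRAINING

    def test_advancing_completed_session_rejected(self, small_config, trained_coder):
        session = _start(Arm.CONTROL, small_config, trained_coder)
        while session.phase in CONVERSATIONAL_PHASES:
            handle_trainee_turn(session, OTHER_TEXT)
        run_posttest(session, [REFLECTION_TEXT] * 5)
        with pytest.raises(ValueError):
            advance_phase(session)


class TestPosttest:
    def _to_posttest(self, config, coder, arm=Arm.CONTROL):
        session = _start(arm, config, coder)
        while session.phase in CONVERSATIONAL_PHASES:
            handle_trainee_turn(session, OTHER_TEXT)
        return session

    def test_identical_prompts_across_sessions_and_arms(self, small_config, trained_coder):
        a = self._to_posttest(small_config, trained_coder, Arm.TREATMENT)
        b = self._to_posttest(small_config, trained_coder, Arm.CONTROL)
        run_posttest(a, [OTHER_TEXT] * 5)
        run_posttest(b, [OTHER_TEXT] * 5)
        pa = [e["prompt"] for e in a.log.events if e["kind"] == "posttest"]
        pb = [e["prompt"] for e in b.log.events if e["kind"] == "posttest"]
        assert pa == pb == list(small_config.posttest_prompts)

    def test_reflection_responses_labeled_reflection(self, small_config, trained_coder):
        session = self._to_posttest(small_config, trained_coder)
        events = run_posttest(session, [REFLECTION_TEXT] * 5)
        assert [e["label"] for e in events] == ["reflection"] * 5

    def test_wrong_response_count_rejected(self, small_config, trained_coder):
        session = self._to_posttest(small_config, trained_coder)
        with pytest.raises(ValueError):
            run_posttest(session, [OTHER_TEXT] * 4)

    def test_posttest_outside_phase_rejected(self, small_config, trained_coder):
        session = _start(Arm.CONTROL, small_config, trained_coder)
        with pytest.raises(ValueError):
            run_posttest(session, [OTHER_TEXT] * 5)


@pytest.fixture(scope="module")
def rct_logs(trained_coder):
    config = CurriculumConfig.reduced(training_turns=6, test_turns=6)
    agent = TraineeAgentConfig(responsiveness=1.0)
    return simulate_rct(10, agent, config, seed=42, coder=trained_coder)


class TestSimulatedSessionInvariants:
    def test_control_sessions_have_zero_feedback(self, rct_logs):
        for log in rct_logs:
            if log.arm is Arm.CONTROL:
                assert not [e for e in log.events if e["kind"] == "feedback"]

    def test_no_feedback_outside_training_phases(self, rct_logs):
        allowed = {Phase.OPEN_QUESTION_TRAINING.value, Phase.REFLECTION_TRAINING.value,
                   Phase.TRAINING_BOTH.value}
        for log in rct_logs:
            for e in log.events:
                if e["kind"] == "feedback":
                    assert e["phase"] in allowed

    def test_event_times_strictly_ordered(self, rct_logs):
        for log in rct_logs:
            ts = [e["t"] for e in log.events]
            assert ts == sorted(ts) and len(set(ts)) == len(ts)

    def test_every_trainee_event_labeled(self, rct_logs):
        for log in rct_logs:
            for e in log.events:
                if e["kind"] in ("trainee", "posttest"):
                    assert e["label"] in {l.value for l in SkillLabel}


class TestLogIO:
    def test_round_trip(self, small_config, trained_coder, tmp_path):
        session = _start(Arm.TREATMENT, small_config, trained_coder, seed=11)
        for _ in range(4):
            handle_trainee_turn(session, OPEN_TEXT)
        path = tmp_path / "log.jsonl"
        write_session_log(session.log, path)
        back = read_session_log(path)
        assert back.session_id == session.log.session_id
        assert back.arm == session.log.arm
        assert back.seed == session.log.seed
        assert back.events == session.log.events
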