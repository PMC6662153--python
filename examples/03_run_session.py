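"""Walk one treatment-arm curriculum session with a scripted trainee and
show where the adaptive feedback fires.

Run:  python examples/03_run_session.py
"""

from clientbot.curriculum import (Arm, CONVERSATIONAL_PHASES, CurriculumConfig,
                                  handle_trainee_turn, init_session, run_posttest,
                                  run_quiz)
from clientbot.synthetic import default_coder

coder = default_coder(seed=0)
config = CurriculumConfig.reduced(training_turns=6, test_turns=6)
session = init_session(Arm.TREATMENT, config, models=None, coder=coder, seed=3)
run_quiz(session, [1, 1, 1])  # the quiz records answers but never blocks

# a trainee who never reflects: feedback should fire in reflection training
while session.phase in CONVERSATIONAL_PHASES:
    handle_trainee_turn(session, "ok , i see .")
run_posttest(session, ["it sounds like you are worried about work ."] * 5)

for e in session.log.events:
    if e["kind"] == "phase":
        print(f"--- phase: {e['phase']}")
    elif e["kind"] == "feedback":
        print(f"    FEEDBACK (recent {e['skill']} rate {e['window_rate']:.0f}%):"
              f" {e['prompt']}")

n_fb = sum(e["kind"] == "feedback" for e in session.log.events)
labels = [e["label"] for e in session.log.events if e["kind"] == "posttest"]
print(f"\nfeedback events: {n_fb} (only in training phases, only for treatment)")
print(f"posttest labels: {labels} (5 fixed prompts, coded automatically)")
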