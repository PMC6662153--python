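# Methods

This note describes the models, procedures and design choices behind
`clientbot`: a desk-scale re-creation of a chat-based simulated patient that
lets a trainee practice two basic counseling skills — open questions and
reflections — while an automated coder labels every trainee utterance and a
curriculum engine delivers (or withholds) real-time feedback, and a
statistics layer compares skill acquisition between randomized arms.

## The conversational models

The simulated client combines two recurrent models with complementary
strengths.

**Seq2seq encoder–decoder.** An LSTM encoder reads the trainee's statement;
a second LSTM, initialized with the encoder's final hidden and cell state,
is trained by teacher forcing to emit the client's reply followed by an
end-of-sequence token. Decoding is beam search. This model produces short,
plausible, small-talk-like replies and is used for the opening of a session.

**Tagged language model.** A single LSTM layer trained on a flat token
stream of whole transcripts, in which the special tokens `<p>` and `<t>`
mark each change of speaker (one tag per speaker run). Training uses
truncated backpropagation through time over fixed-length windows (50 tokens
at full scale). At chat time the model is conditioned on the tagged history
(truncated to the window length, ending in `<p>` so it continues in the
client role) and decoded by per-step sampling, which yields longer,
symptom-laden and non-deterministic turns.

Both models are trained with Adagrad — per-parameter learning rates from
the accumulated squared gradient history — under global-norm gradient
clipping. The layers are plain numpy with hand-derived backward passes in
float64; at the scale this package targets (tens of hidden units, corpora
of a few thousand tokens) this is fast, exactly reproducible under a seed,
and dependency-free. The configuration defaults record the full-scale
hyperparameters of the system this package re-creates (1024 LM /
3000 seq2seq hidden units, vocabulary 15 000, learning rates .05/.01,
clip 5); every test and example runs far smaller instances of the same
architecture, chosen so the whole suite trains in seconds.

**Perplexity** is exp of the mean negative log-probability per predicted
token. Padding positions are excluded; speaker-tag positions count as
predicted positions (the stream contains them, so the choice must be fixed
for results to be well-defined). Loss is cross-entropy in nats and PP uses
exp, making PP base-independent.

The output projection is initialized to zero, so an untrained model emits
the uniform distribution; the LSTM forget-gate bias starts at 1 to ease
early gradient flow.

### Decoding policy

Responses 1 through `switch_after` (default 5) come from beam search on the
seq2seq model (beam 10 at full scale); later responses are sampled from the
tagged LM. Two response filters act on the detokenized lowercase text with
substring semantics: candidates containing a banned phrase (default
`"i love you"`, an artifact of movie-dialogue training data) are removed
unconditionally; candidates containing an undersampled phrase (default
`"i don't know"`) are removed independently with probability
`undersample_prob` (default 0.9 — the original description gives no rate,
so it is configurable). If every candidate is filtered away, a neutral
configurable fallback (`"mm-hmm"`) is emitted. Beam scores are raw sums of
log-probabilities (no length normalization), matching the era of models
re-created here and keeping ranking deterministic.

The beam searcher uses a *nested selection rule*: slot *b* of the next beam
may only draw extensions of the current top-*b* beams, and eos competes for
slots like any other token (a beam whose winning extension is eos retires
to the completed pool). Consequences: at width 1 the search is exactly
greedy decoding; widening the beam never lowers the best returned score;
and with a beam at least as wide as the number of live prefixes the search
is exhaustive. Ties are broken lexicographically on the token-id sequence.

## The skill coder

Each trainee utterance receives exactly one of four MISC-style codes: open
question, closed question, reflection, other. The classifier is an
L2-regularized multinomial logistic regression (scikit-learn) over discrete
sentence features: unigram and bigram counts, an ends-with-question-mark
indicator, the first token's identity, and a coarse length bucket. Exact
posterior ties are broken in the fixed label order open_question <
closed_question < reflection < other. Agreement between label sequences is
Cohen's kappa, computed from the confusion matrix with chance agreement
from the marginal products; the degenerate case (both raters constant on
the same label) is defined as kappa 1.

The "other" category is explicit rather than implied; the remaining MISC
codes and session-level ratings (empathy, MI spirit) are out of scope.

## The curriculum

A session is: introduction text → 3-question quiz (an engagement check that
never gates progression) → six phases in fixed order — before training,
open-question training, reflection training, combined training, test, and a
fixed posttest. Treatment and control arms receive byte-identical
introduction, prompts and posttest; the only difference is feedback.
Feedback fires when, in a feedback-enabled phase of a treatment session,
the share of the last `feedback_window` (default 5) trainee utterances
using the phase's target skill falls below `feedback_threshold` percent
(default 20) and at least `feedback_cooldown` (default 3) turns have passed
since the previous prompt. The prompt names the under-used skill and gives
an example. Feedback is disabled in the before-training, test and posttest
phases for both arms, and everywhere for control.

Phase durations are turn counts by default (10 trainee turns per
conversational phase) for deterministic desk testing; the original test
phase was wall-clock (5 minutes), which at a conversational pace of roughly
two turns per minute corresponds to about 10 turns. The posttest presents 5
fixed client statements, identical for every participant; the texts are
artifact-authored in the style of client talk (the originals are not
published), as are the introduction, quiz and feedback prompt wording.

Sessions can run against the neural client or, for large simulation
studies, against a canned template client (`models=None`). The template
client affects only the bot's text; the simulated trainee's behavior (and
hence every outcome statistic) is independent of it, so simulation results
are unchanged while running orders of magnitude faster. The neural path is
exercised end to end by its own tests. Skill-coder predictions are memoized
per normalized utterance text inside simulation loops — template utterances
form a finite set, and caching a deterministic classifier cannot change any
label.

## The analysis

Primary outcomes are per-participant percentages: skill codes tabulated and
divided by the number of utterances in each phase, for open questions,
reflections, and their union ("listening skills"). Arms are compared with
the two-sample Wilcoxon rank-sum test, two-sided, reported as the rank sum
W of the first sample with midranks for ties. With 12 or fewer total
observations the p-value is exact (full enumeration of rank assignments,
doubling the smaller tail and capping at 1); otherwise the normal
approximation with tie correction and a 0.5 continuity correction is used.
Dropout uses Pearson's chi-square on the 2×2 table without continuity
correction (a correction flag exists). Satisfaction items are coded 1–5
(strongly disagree 1, disagree 2, agree 4, strongly agree 5, with 3
reserved for neutral — the published scale lists four options but a 1–5
coding, so the mapping is an artifact decision) and tested with a
one-sample t against neutral 3 and a pooled two-sample t by arm, with
Cohen's d as effect size. No multiple-testing correction is applied,
matching the analysis this package re-creates.

The headline "X% more" arithmetic is
`trunc(100 · (treatment − control) / control)`, truncated toward zero:
truncation reproduces all three published integers (91, 76, 31) from their
printed means, whereas rounding would not (it gives 32 for the third).

Uniqueness of a participant's utterances is the percentage of distinct
texts after normalization (tokenize, rejoin), guarding against trainees
repeating one successful response.

## Synthetic data

The proprietary training corpora and the human participants are replaced by
generators, all bit-reproducible under seeds.

**Corpus generator.** Alternating therapist/client transcripts from
template grammars. Therapist turns are questions/reflections; client turns
mix short small talk with longer symptom talk carrying numerals (masked to
`<number>` by the tokenizer) and spoken-language disfluencies ("uh ,",
"you know ,") at configured rates, so generated text exercises every
tokenizer path. No claim of clinical realism is made — the generator
reproduces the *structural* features the models need (turn alternation,
short vs long turns, numerals, disfluencies), not the content distribution
of real therapy.

**Labeled utterances.** Stems × topics per class, with class membership
true by construction (open stems end in "?", reflection stems are
declarative restatements, and so on) and separable by the coder's feature
set. This is deliberate: acceptance checks need ground-truth labels, so the
generator trades realism for label validity. A consequence worth stating:
the coder's ≥95% held-out accuracy on this set shows the pipeline recovers
a separable class structure, not that it would match trained human raters
on real transcripts.

**Simulated trainee.** A multinomial-with-shift model. The baseline skill
distribution defaults to roughly the pre-training rates of the population
emulated (24% open questions, 15% closed, 9% reflections, 52% other). A
feedback event adds `responsiveness` (ρ) to a boost toward the prompted
skill; a `retention` share (default 0.6) of each increment persists
indefinitely, the rest decays by 10% per turn; the total boost is capped at
0.85. Retention is part of the emulated conditions: the study this package
mirrors found elevated reflection use *after* feedback was removed, which a
fully decaying boost could not express. ρ = 0 makes feedback inert, so arm
assignment cannot influence behavior — the null configuration for
calibration. Effect size is an input of the simulator, never a finding.

**Simulated trial.** `simulate_rct` runs full curriculum sessions for n
treatment and n control trainees drawn from one agent configuration and
feeds the logs to the analysis. Large simulation studies use a reduced
session (6 turns per training phase, 10 test turns) so a 1000-replicate
null calibration completes in minutes on one CPU; these sizes are the
package's stated desk-scale conditions, not tunables of the claims.

## Numerical and degenerate-input conventions

- Tokenization: lowercase, punctuation split off, maximal digit runs
  replaced by `<number>`; idempotent on its own rejoined output.
- Vocabulary truncation breaks frequency ties lexicographically, so equal
  corpora give equal vocabularies regardless of transcript order.
- Train/test splitting is at transcript level (no utterance leakage), test
  size `round(n·frac)` with a minimum of 1.
- Consecutive same-speaker utterances are merged into one statement before
  seq2seq pairing (spoken transcripts contain such runs; the pairing needs
  whole statements).
- Zero-variance t-tests raise rather than return NaN; an identical-groups
  two-sample comparison returns t = 0.
- Kappa with expected agreement 1 and observed agreement below 1 raises
  (it is undefined); this cannot occur for real confusion matrices.
- All random components accept explicit seeds; every seed derived
  internally stays below 2^31.

## Known limitations

- The models have no attention and no long-range topic tracking; the LM
  conditions only on a truncated recent history.
- Training at the original scale (thousands of hidden units, 15k
  vocabulary, hundreds of thousands of statement pairs) is out of scope, as
  is reproducing the original held-out perplexities — those depend on
  proprietary corpora.
- The coder's published agreement range against human MISC raters cannot
  be checked here for the same reason.
- The simulated trainee is a testing construct; nothing about human
  learning should be inferred from simulation outcomes.
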