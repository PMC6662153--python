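"""Train the two conversational models on a synthetic therapy corpus and
talk to the combined client for a few turns.

Run:  python examples/01_train_dialogue_models.py
"""

import numpy as np

from clientbot import corpus
from clientbot.decoding import DialogueState, PolicyConfig, respond
from clientbot.models import LMConfig, Seq2SeqConfig, perplexity, train_lm, train_seq2seq
from clientbot.synthetic import CorpusGenConfig, generate_corpus

transcripts = generate_corpus(CorpusGenConfig(n_transcripts=40, seed=7))
train, test = corpus.split_train_test(transcripts, test_frac=0.05, seed=7)
vocab = corpus.build_vocab(train, max_size=400)
print(f"corpus: {len(train)} train / {len(test)} test transcripts, "
      f"vocabulary {len(vocab)} tokens")

lm = train_lm(corpus.make_lm_stream(train), vocab,
              LMConfig(hidden_units=48, embed_dim=16, sequence_length=30,
                       learning_rate=0.2, epochs=4, seed=0),
              eval_stream=corpus.make_lm_stream(test))
print(f"tagged LM held-out perplexity: {lm.report.heldout_perplexity:.1f} "
      f"(uniform baseline would be {len(vocab)}; lower = better next-word fit)")

s2s = train_seq2seq(corpus.make_seq2seq_pairs(train), vocab,
                    Seq2SeqConfig(hidden_units=48, embed_dim=16, learning_rate=0.2,
                                  epochs=4, vocab_size=400, seed=0),
                    eval_pairs=corpus.make_seq2seq_pairs(test) or None)
if s2s.report.heldout_perplexity:
    print(f"seq2seq held-out perplexity:  {s2s.report.heldout_perplexity:.1f}")

# chat: first 5 replies come from the seq2seq beam, later ones are sampled
# from the tagged LM (longer, non-deterministic turns)
state = DialogueState(rng=np.random.default_rng(1))
config = PolicyConfig(beam_size=5, max_decode_len=12)
for line in ["hello", "how are you feeling today ?", "tell me more about work",
             "do you sleep well ?", "what has changed lately ?",
             "it sounds like a lot is going on .", "you feel stuck ."]:
    reply, state = respond(state, line, (s2s, lm), config)
    print(f"  you: {line}\n  client [{reply.source}]: {reply.text}")
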