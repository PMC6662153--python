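import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from clientbot import corpus, models, synthetic
from clientbot.corpus import Seq2SeqPair, Speaker, Transcript, Utterance, tokenize


@pytest.fixture(scope="session")
def trained_coder():
    """Skill classifier fit on the default synthetic labeled set."""
    return synthetic.default_coder(seed=0)


MEMOR_SENTENCE = "i have been feeling tired all day ."


@pytest.fixture(scope="session")
def memorized_lm():
    """Tiny LM trained on a single repeated sentence (a memorizable corpus)."""
    tr = Transcript("m", [Utterance(Speaker.CLIENT, MEMOR_SENTENCE)] * 200)
    vocab = corpus.build_vocab([tr], 50)
    stream = corpus.make_lm_stream([tr])
    config = models.LMConfig(hidden_units=32, embed_dim=16, sequence_length=16,
                             learning_rate=0.3, epochs=4, seed=0)
    model = models.train_lm(stream, vocab, config, eval_stream=stream[: len(stream) // 4])
    return model, stream


FIXED_PAIRS = [
    ("how are you ?", "i am fine ."),
    ("do you sleep ?", "not much lately ."),
    ("tell me about work", "work has been hard ."),
    ("hello", "hi there ."),
    ("what happened ?", "i missed my appointment ."),
]


@pytest.fixture(scope="session")
def memorized_seq2seq():
    """Tiny seq2seq trained to convergence on 5 fixed statement pairs."""
    pairs = [Seq2SeqPair(tokenize(s), tokenize(t)) for s, t in FIXED_PAIRS]
    tokens = sorted({w for p in pairs for w in p.source + p.target})
    vocab = corpus.Vocabulary(tokens, 100)
    config = models.Seq2SeqConfig(hidden_units=32, embed_dim=16, learning_rate=0.3,
                                  epochs=150, vocab_size=100, seed=0)
    return models.train_seq2seq(pairs, vocab, config), pairs


@pytest.fixture(scope="session")
def tiny_dialogue_models(trained_coder):
    """Small seq2seq + LM trained on one synthetic corpus, for policy tests."""
    cfg = synthetic.CorpusGenConfig(n_transcripts=20, seed=3)
    transcripts = synthetic.generate_corpus(cfg)
    vocab = corpus.build_vocab(transcripts, 300)
    lm = models.train_lm(
        corpus.make_lm_stream(transcripts), vocab,
        models.LMConfig(hidden_units=24, embed_dim=12, sequence_length=30,
                        learning_rate=0.2, epochs=2, seed=0))
    s2s = models.train_seq2seq(
        corpus.make_seq2seq_pairs(transcripts), vocab,
        models.Seq2SeqConfig(hidden_units=24, embed_dim=12, learning_rate=0.2,
                             epochs=2, vocab_size=300, seed=0))
    return s2s, lm


class TabularToyModel:
    """Deterministic toy decoder: the next-token distribution for each prefix
    is derived by hashing (seed, prefix), so repeated queries agree exactly.
    Token 0 is eos."""

    def __init__(self, vocab_n: int, seed: int):
        self.vocab_n = vocab_n
        self.eos_index = 0
        self.seed = seed

    def dist(self, prefix: tuple) -> np.ndarray:
        rng = np.random.default_rng(abs(hash((self.seed,) + prefix)) % (2**31))
        p = np.exp(rng.normal(size=self.vocab_n) * 2)
        return np.log(p / p.sum())

    def decoder_start(self, source):
        return (), self.dist(())

    def decoder_step(self, state, tok):
        s = state + (tok,)
        return s, self.dist(s)


@pytest.fixture
def toy_model_cls():
    return TabularToyModel
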