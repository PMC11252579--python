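"""Coherence checks against a deliberately naive reference implementation.

The reference below recomputes everything from first principles — explicit
window enumeration, plain-math NPMI, hand-rolled cosine — sharing no code
with the package's vectorized implementation.
"""

import math

import numpy as np
import pytest

from crisislda.coherence import CoherenceScore, coherence, select_num_topics
from crisislda.preprocess import TokenDoc

EPS = 1e-12


# ---------------------------------------------------------------- reference
def _ref_windows(docs, window):
    out = []
    for doc in docs:
        toks = list(doc.tokens)
        if not toks:
            continue
        if len(toks) <= window:
            out.append(set(toks))
        else:
            for i in range(len(toks) - window + 1):
                out.append(set(toks[i:i + window]))
    return out


def _ref_p(windows, *terms):
    hits = sum(1 for w in windows if all(t in w for t in terms))
    return hits / len(windows)


def _ref_npmi(windows, a, b):
    pa, pb = max(_ref_p(windows, a), EPS), max(_ref_p(windows, b), EPS)
    pab = _ref_p(windows, a, b)
    if pab >= 1.0:
        return 1.0
    pab = max(pab, EPS)
    return math.log(pab / (pa * pb)) / -math.log(pab)


def _ref_c_npmi(topics, docs, window):
    windows = _ref_windows(docs, window)
    scores = []
    for topic in topics:
        pair_scores = []
        for i in range(len(topic)):
            for j in range(i + 1, len(topic)):
                pair_scores.append(_ref_npmi(windows, topic[i], topic[j]))
        scores.append(sum(pair_scores) / len(pair_scores))
    return sum(scores) / len(scores)


def _ref_c_v(topics, docs, window):
    windows = _ref_windows(docs, window)
    topic_scores = []
    for topic in topics:
        vecs = []
        for w1 in topic:
            vecs.append([_ref_npmi(windows, w1, w2) for w2 in topic])
        set_vec = [sum(col) for col in zip(*vecs)]
        sims = []
        for v in vecs:
            dot = sum(x * y for x, y in zip(v, set_vec))
            na = math.sqrt(sum(x * x for x in v))
            nb = math.sqrt(sum(y * y for y in set_vec))
            sims.append(dot / (na * nb) if na * nb > 0 else 0.0)
        topic_scores.append(sum(sims) / len(sims))
    return sum(topic_scores) / len(topic_scores)


# ---------------------------------------------------------------- tests
class TestNpmiLimits:
    def test_perfectly_cooccurring_pair_scores_exactly_one(self):
        docs = [TokenDoc(("sun", "moon", f"pad{i}")) for i in range(4)]
        docs.append(TokenDoc(("padx", "pady", "padz")))
        score = coherence([["sun", "moon"]], docs, measure="c_npmi", window=5)
        assert score.value == 1.0

    def test_never_cooccurring_pair_is_negative(self):
        docs = [TokenDoc(("sun", "a", "b"))] * 3 + [TokenDoc(("moon", "c", "d"))] * 3
        score = coherence([["sun", "moon"]], docs, measure="c_npmi", window=5)
        assert score.value < -0.5

    def test_absent_term_uses_epsilon_floor_without_crash(self):
        docs = [TokenDoc(("sun", "moon"))] * 3
        score = coherence([["sun", "ghost"]], docs, measure="c_npmi", window=5)
        assert np.isfinite(score.value)


class TestAgainstReference:
    @pytest.fixture
    def topics(self):
        return [["apple", "banana", "cherry"], ["date", "fig", "grape"]]

    @pytest.mark.parametrize("window", [2, 3, 5])
    def test_c_npmi_matches_reference(self, topics, toy_token_docs, window):
        mine = coherence(topics, toy_token_docs, "c_npmi", window=window)
        ref = _ref_c_npmi(topics, toy_token_docs, window)
        assert mine.value == pytest.approx(ref, abs=1e-12)

    @pytest.mark.parametrize("window", [2, 3, 5])
    def test_c_v_matches_reference(self, topics, toy_token_docs, window):
        mine = coherence(topics, toy_token_docs, "c_v", window=window)
        ref = _ref_c_v(topics, toy_token_docs, window)
        assert mine.value == pytest.approx(ref, abs=1e-12)
        assert mine.value == pytest.approx(np.mean(mine.per_topic))

    def test_value_is_mean_of_per_topic_and_ranges(self, topics, toy_token_docs):
        cv = coherence(topics, toy_token_docs, "c_v", window=3)
        cn = coherence(topics, toy_token_docs, "c_npmi", window=3)
        assert all(-1.0 <= v <= 1.0 for v in cn.per_topic)
        assert all(0.0 <= v <= 1.0 for v in cv.per_topic)

    def test_rejects_degenerate_inputs(self, toy_token_docs):
        with pytest.raises(ValueError):
            coherence([["solo"]], toy_token_docs)
        with pytest.raises(ValueError):
            coherence([["a", "b"]], [])


class TestTopicCountSelection:
    def test_single_variant_sweep_shape(self):
        rng = np.random.default_rng(0)
        texts = [" ".join(f"w{rng.integers(0, 30):03d}" for _ in range(10))
                 for _ in range(40)]
        table, best = select_num_topics(
            texts, [2, 3], variants=("unigram",), sweeps=30, burn_in=10,
            window=10, top_n=4, seed=0)
        assert len(table) == 2
        assert set(table["K"]) == {2, 3}
        assert best[0] in (2, 3) and best[1] == "unigram"

    def test_two_variants_reported_side_by_side(self):
        texts = ["stay home stay safe every day " + f"w{i % 7}"
                 for i in range(30)]
        table, _ = select_num_topics(
            texts, [2, 3], variants=("bigram", "trigram"), sweeps=20,
            burn_in=5, window=10, top_n=3, min_count=2, threshold=0.1, seed=1)
        assert sorted(set(table["variant"])) == ["bigram", "trigram"]
        assert len(table) == 4

    def test_recovers_true_topic_count_on_synthetic_sharp_corpus(self):
        # stochastic model-selection property: argmax-coherence K equals the
        # generating K in a clear majority of seeded replicates
        from crisislda.synthetic import GeneratorConfig, sample_corpus
        hits = 0
        n_rep = 5
        for rep in range(n_rep):
            cfg = GeneratorConfig(n_topics=5, vocab_size=150, n_docs=250,
                                  alpha=0.01, separability="disjoint",
                                  doc_length_lambda=12, n_hashtags_max=0,
                                  p_pos=0.0, p_neg=0.0, seed=100 + rep)
            bundle = sample_corpus(cfg)
            texts = [t.text for t in bundle.tweets]
            table, best = select_num_topics(
                texts, [2, 5, 10], variants=("unigram",), sweeps=60,
                burn_in=20, window=20, top_n=5, seed=rep)
            hits += best[0] == 5
        assert hits >= 4
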