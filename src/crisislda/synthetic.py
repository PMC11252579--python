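"""Synthetic tweet corpora from a known LDA generative process.

The generator emulates the kind of corpus the pipeline targets — millions of
short English posts with hashtags, country metadata and polarity words —
at desk scale and with exact ground truth: topic-word distributions φ*,
document-topic proportions θ*, each document's dominant topic, its injected
sentiment class and its country.  Documents are pseudo-word token sequences
("w0042"-style), so the lexical stages stay exactly invertible; small
hand-written English fixtures exercise lemmatization and phrase detection
separately, and the generator can optionally plant fixed adjacent token
pairs to feed the collocation detector.

Everything is drawn from a single seeded generator, so a bundle regenerates
bit-identically from (config, seed).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np

from ._lexicons import DEFAULT_KEYWORDS, SENTIMENT_LEXICON
from .corpus_io import Corpus, Tweet

__all__ = ["GeneratorConfig", "SyntheticBundle", "sample_corpus",
           "write_bundle", "DEFAULT_COUNTRIES"]

# code -> (population, sampling weight); "" emulates geotag-less accounts.
DEFAULT_COUNTRIES: dict[str, tuple[float, float]] = {
    "US": (331e6, 0.25),
    "GB": (67e6, 0.15),
    "IN": (1380e6, 0.15),
    "BR": (213e6, 0.10),
    "DE": (83e6, 0.08),
    "FR": (67e6, 0.07),
    "ZA": (59e6, 0.05),
    "AU": (26e6, 0.05),
    "CA": (38e6, 0.05),
    "": (float("nan"), 0.05),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic corpus.

    ``alpha`` scales the document-topic Dirichlet: the concentration vector
    is α·K·w with w the (normalized) topic prior weights, so uniform weights
    give the symmetric Dirichlet(α).  Small α (e.g. 0.01) yields sharp
    single-topic documents.  ``separability="disjoint"`` gives each topic a
    disjoint vocabulary block (maximally separated classes); the default
    draws φ* ~ Dirichlet(β) over the full vocabulary.

    Document lengths are Poisson(λ) clipped to [3, 50] — the short-text
    regime of 280-character posts.  Each document gets 0–2 hashtags from the
    crisis keyword list, a country drawn from the country table, and with
    per-topic probabilities (p_pos, p_neg) an injected positive/negative
    sentiment class realized by appending 1–2 matching lexicon words.
    """

    n_topics: int = 10
    vocab_size: int = 300
    n_docs: int = 2000
    alpha: float = 0.1
    beta: float = 0.01
    doc_length_lambda: float = 20.0
    doc_length_range: tuple[int, int] = (3, 50)
    topic_weights: tuple[float, ...] | None = None
    separability: str = "dirichlet"
    countries: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COUNTRIES))
    p_pos: float | tuple[float, ...] = 0.25
    p_neg: float | tuple[float, ...] = 0.15
    n_hashtags_max: int = 2
    plant_pairs: tuple[tuple[str, str], ...] = ()
    plant_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.doc_length_lambda <= 0:
            raise ValueError("doc_length_lambda must be > 0")
        if self.topic_weights is not None:
            w = np.asarray(self.topic_weights, np.float64)
            if len(w) != self.n_topics or np.any(w < 0) or w.sum() <= 0:
                raise ValueError("topic_weights must be K non-negative "
                                 "values with positive sum")
        for p in np.atleast_1d(self.p_pos).tolist() + np.atleast_1d(self.p_neg).tolist():
            if not (0.0 <= p <= 1.0):
                raise ValueError("sentiment probabilities must lie in [0, 1]")
        if self.separability not in ("dirichlet", "disjoint"):
            raise ValueError(f"unknown separability {self.separability!r}")


@dataclass(frozen=True)
class SyntheticBundle:
    """A generated corpus plus its complete ground truth, aligned by index."""

    corpus: Corpus
    docs: tuple[np.ndarray, ...]          # per-doc ground-truth token ids
    phi: np.ndarray                       # (K, V) true topic-word rows
    theta: np.ndarray                     # (D, K) true topic proportions
    dominant_topic: np.ndarray            # argmax θ*_d
    sentiment: tuple[str, ...]            # injected class per doc
    country: tuple[str, ...]
    config: GeneratorConfig

    @property
    def tweets(self):
        return self.corpus.tweets


def _per_topic(p, k: int) -> np.ndarray:
    arr = np.asarray(p, np.float64)
    return np.full(k, float(arr)) if arr.ndim == 0 else arr


def sample_corpus(config: GeneratorConfig) -> SyntheticBundle:
    """Draw one corpus from the configured LDA process."""
    k, v, d = config.n_topics, config.vocab_size, config.n_docs
    if v < 10 * k:
        import logging
        logging.getLogger(__name__).warning(
            "vocab_size %d < 10·K (%d): topics may separate poorly", v, 10 * k)
    rng = np.random.Generator(np.random.PCG64(int(config.seed)))

    if config.separability == "disjoint":
        phi = np.zeros((k, v))
        bounds = np.linspace(0, v, k + 1).astype(int)
        for t in range(k):
            lo, hi = bounds[t], bounds[t + 1]
            phi[t, lo:hi] = rng.dirichlet(np.full(hi - lo, 1.0))
    else:
        phi = rng.dirichlet(np.full(v, config.beta), size=k)

    weights = (np.full(k, 1.0 / k) if config.topic_weights is None
               else np.asarray(config.topic_weights, np.float64))
    weights = weights / weights.sum()
    concentration = np.maximum(config.alpha * k * weights, 1e-8)
    theta = rng.dirichlet(concentration, size=d)

    pos_terms = sorted(t for t, s in SENTIMENT_LEXICON.items() if s > 0)
    neg_terms = sorted(t for t, s in SENTIMENT_LEXICON.items() if s < 0)
    p_pos = _per_topic(config.p_pos, k)
    p_neg = _per_topic(config.p_neg, k)

    codes = list(config.countries)
    cweights = np.array([config.countries[c][1] for c in codes], np.float64)
    cweights = cweights / cweights.sum()

    lo, hi = config.doc_length_range
    lengths = np.clip(rng.poisson(config.doc_length_lambda, size=d), lo, hi)
    dominant = theta.argmax(axis=1)
    cum_phi = np.cumsum(phi, axis=1)
    cum_phi[:, -1] = 1.0  # guard against rounding in searchsorted draws

    tweets = []
    docs = []
    sentiments = []
    countries = []
    pad = max(4, len(str(v - 1)))
    keyword_pool = list(DEFAULT_KEYWORDS)
    for i in range(d):
        z = rng.choice(k, size=int(lengths[i]), p=theta[i])
        u = rng.random(len(z))
        w = np.array([np.searchsorted(cum_phi[zi], ui, side="right")
                      for zi, ui in zip(z, u)], np.int64)
        docs.append(w)
        words = [f"w{int(t):0{pad}d}" for t in w]

        if config.plant_pairs and rng.random() < config.plant_prob:
            a, b = config.plant_pairs[int(rng.integers(len(config.plant_pairs)))]
            pos = int(rng.integers(0, len(words) + 1))
            words[pos:pos] = [a, b]

        topic = int(dominant[i])
        u = rng.random()
        if u < p_pos[topic]:
            sent = "positive"
            pool = pos_terms
        elif u < p_pos[topic] + p_neg[topic]:
            sent = "negative"
            pool = neg_terms
        else:
            sent = "neutral"
            pool = None
        if pool is not None:
            for _ in range(int(rng.integers(1, 3))):
                words.append(pool[int(rng.integers(len(pool)))])
        sentiments.append(sent)

        n_tags = int(rng.integers(0, config.n_hashtags_max + 1))
        tags = [keyword_pool[int(j)]
                for j in rng.choice(len(keyword_pool), size=n_tags,
                                    replace=False)]
        country = codes[int(rng.choice(len(codes), p=cweights))]
        countries.append(country)

        text = " ".join(words + [f"#{t}" for t in tags])
        day = int(rng.integers(0, 240))
        stamp = (_dt.datetime(2020, 12, 1) + _dt.timedelta(days=day)).isoformat()
        tweets.append(Tweet(
            id=f"t{i:06d}",
            text=text,
            lang="en",
            country=country,
            created_at=stamp,
            hashtags=tuple(tags),
            retweet_count=int(rng.poisson(1.0)),
        ))

    return SyntheticBundle(
        corpus=Corpus(tuple(tweets), provenance=f"synthetic seed={config.seed}"),
        docs=tuple(docs),
        phi=phi,
        theta=theta,
        dominant_topic=dominant,
        sentiment=tuple(sentiments),
        country=tuple(countries),
        config=config,
    )


def write_bundle(bundle: SyntheticBundle, out_dir: str) -> dict[str, str]:
    """Write tweets.jsonl, truth sidecars, populations.csv and lexicon.csv."""
    import csv
    import os

    from .corpus_io import write_tweets

    os.makedirs(out_dir, exist_ok=True)
    paths = {}

    paths["tweets"] = os.path.join(out_dir, "tweets.jsonl")
    write_tweets(bundle.corpus, paths["tweets"])

    paths["phi"] = os.path.join(out_dir, "truth_phi.npy")
    np.save(paths["phi"], bundle.phi)
    paths["theta"] = os.path.join(out_dir, "truth_theta.npy")
    np.save(paths["theta"], bundle.theta)

    paths["labels"] = os.path.join(out_dir, "truth_labels.csv")
    with open(paths["labels"], "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["doc_index", "tweet_id", "dominant_topic",
                         "sentiment", "country"])
        for i, tw in enumerate(bundle.tweets):
            writer.writerow([i, tw.id, int(bundle.dominant_topic[i]),
                             bundle.sentiment[i], bundle.country[i]])

    paths["populations"] = os.path.join(out_dir, "populations.csv")
    with open(paths["populations"], "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["country", "population"])
        for code, (pop, _) in bundle.config.countries.items():
            if code and pop == pop:
                writer.writerow([code, int(pop)])

    paths["lexicon"] = os.path.join(out_dir, "lexicon.csv")
    with open(paths["lexicon"], "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["term", "polarity"])
        for term in sorted(SENTIMENT_LEXICON):
            writer.writerow([term, "pos" if SENTIMENT_LEXICON[term] > 0 else "neg"])

    return paths
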