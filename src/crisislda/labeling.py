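"""Dominant-topic labeling: tf-idf-weighted topic affinity ranking.

Each document d is scored against every topic k as

    score(d, k) = Σ_w tfidf(w, d) · φ_kw

with tf(w, d) = count / N_d and idf(w) = ln(M / df(w)) (natural log, no
smoothing, so a term present in every document contributes nothing).  The
argmax topic becomes the document's class label; ties break to the smallest
topic index.  A document whose score vector is identically zero (empty, or
all terms have idf 0) is flagged unlabelable: it keeps label 0 for storage
but is excluded from classifier training sets.

The ranking uses φ only, not θ: the label is a property of the document's
distinctive words, independent of the topic mixture inferred for it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from ._lexicons import DEFAULT_TOPIC_NAMES
from .preprocess import BowDocument

__all__ = [
    "TfidfWeights",
    "LabeledCorpus",
    "fit_tfidf",
    "dominant_topic",
    "label_corpus",
    "DominantTopicLabeler",
]


@dataclass(frozen=True)
class TfidfWeights:
    """Inverse document frequencies: term id → ln(M/df)."""

    idf: dict[int, float]
    n_docs: int
    scheme: str = "tf=count/N_d, idf=ln(M/df), no smoothing"


def fit_tfidf(corpus: list[BowDocument], vocab=None) -> TfidfWeights:
    """Compute idf over a bag-of-words corpus.

    ``vocab`` only fixes the id range; document frequencies always come from
    the corpus itself so that idf(term present everywhere) is exactly 0.
    """
    m = len(corpus)
    if m < 1:
        raise ValueError("fit_tfidf requires at least one document")
    df: dict[int, int] = {}
    for doc in corpus:
        for w in doc.counts:
            df[w] = df.get(w, 0) + 1
    idf = {w: float(np.log(m / c)) for w, c in df.items()}
    return TfidfWeights(idf=idf, n_docs=m)


def _score_vector(doc: BowDocument, phi: np.ndarray,
                  weights: TfidfWeights) -> np.ndarray:
    n_d = doc.n_tokens
    scores = np.zeros(phi.shape[0], np.float64)
    if n_d == 0:
        return scores
    for w, c in doc.counts.items():
        if w >= phi.shape[1]:
            raise ValueError(
                f"term id {w} outside model vocabulary of size {phi.shape[1]}")
        tfidf = (c / n_d) * weights.idf.get(w, 0.0)
        if tfidf != 0.0:
            scores += tfidf * phi[:, w]
    return scores


def dominant_topic(doc: BowDocument, model, weights: TfidfWeights):
    """Return ``(label, topic_scores, labelable)`` for one document.

    ``model`` is a fitted LDA model (uses its ``components_``) or a (K, V)
    row-stochastic matrix.
    """
    phi = model if isinstance(model, np.ndarray) else model.components_
    scores = _score_vector(doc, phi, weights)
    labelable = bool(np.any(scores != 0.0))
    label = int(np.argmax(scores))  # argmax takes the smallest index on ties
    return label, scores, labelable


@dataclass(frozen=True)
class LabeledCorpus:
    """Tweets with dominant-topic labels, score vectors and class names."""

    tweets: tuple
    labels: np.ndarray
    topic_scores: np.ndarray
    labelable: np.ndarray
    label_names: tuple[str, ...]

    def summary(self):
        """Per-class counts and shares over the labelable subset."""
        import pandas as pd
        k = len(self.label_names)
        mask = self.labelable.astype(bool)
        counts = np.bincount(self.labels[mask], minlength=k)
        total = counts.sum()
        shares = counts / total if total else np.zeros(k)
        return pd.DataFrame({
            "label": np.arange(k),
            "label_name": list(self.label_names),
            "count": counts,
            "share": shares,
        })


def label_corpus(tweets, bows: list[BowDocument], model,
                 weights: TfidfWeights,
                 name_table: tuple[str, ...] | None = None) -> LabeledCorpus:
    """Label every document by its dominant topic."""
    phi = model if isinstance(model, np.ndarray) else model.components_
    k = phi.shape[0]
    if name_table is None:
        name_table = (DEFAULT_TOPIC_NAMES if k == len(DEFAULT_TOPIC_NAMES)
                      else tuple(f"Topic {i + 1}" for i in range(k)))
    if len(name_table) != k:
        raise ValueError(f"name table has {len(name_table)} entries for K={k}")
    if len(tweets) != len(bows):
        raise ValueError("tweets and bag-of-words lists differ in length")
    labels = np.empty(len(bows), np.int64)
    scores = np.empty((len(bows), k), np.float64)
    labelable = np.empty(len(bows), bool)
    for i, doc in enumerate(bows):
        labels[i], scores[i], labelable[i] = dominant_topic(doc, phi, weights)
    return LabeledCorpus(tuple(tweets), labels, scores, labelable,
                         tuple(name_table))


class DominantTopicLabeler(BaseEstimator):
    """Estimator wrapper: fit() learns idf from bag-of-words documents,
    predict() assigns dominant-topic labels under a fitted LDA model.

    Parameters
    ----------
    lda : fitted LDA model (``components_`` attribute) or a (K, V) φ matrix.
    name_table : optional K class names.
    """

    def __init__(self, lda=None, name_table=None):
        self.lda = lda
        self.name_table = name_table

    def _phi(self) -> np.ndarray:
        if self.lda is None:
            raise ValueError("DominantTopicLabeler requires a fitted LDA model")
        return self.lda if isinstance(self.lda, np.ndarray) else self.lda.components_

    def fit(self, X, y=None):
        self.weights_ = fit_tfidf(list(X))
        self.n_topics_ = self._phi().shape[0]
        return self

    def predict(self, X) -> np.ndarray:
        phi = self._phi()
        return np.array([dominant_topic(d, phi, self.weights_)[0] for d in X],
                        np.int64)

    def predict_scores(self, X) -> np.ndarray:
        phi = self._phi()
        return np.stack([dominant_topic(d, phi, self.weights_)[1] for d in X])

    def label_corpus(self, tweets, X) -> LabeledCorpus:
        return label_corpus(tweets, list(X), self._phi(), self.weights_,
                            self.name_table)
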