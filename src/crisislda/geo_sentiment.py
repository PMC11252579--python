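"""Lexicon sentiment scoring and per-country population-normalized
aggregation, plus per-topic share summaries.

Sentiment of a token document is the mean polarity of its lexicon matches:
raw = Σ polarities / max(1, #matches); the document is positive if raw
exceeds the neutral band, negative below its negation, else neutral (no
matches ⇒ raw = 0 ⇒ neutral under the default band of 0).

Country aggregation emits one row per (country, topic) cell that actually
contains tweets, with raw counts, a per-capita tweet rate
(n_total / population) and a count-free net score
(n_pos − n_neg) / n_total ∈ [−1, 1].  Tweets with an empty country code pool
under "??"; a country missing from the population table keeps its counts but
has no per-capita rate (flagged as NaN).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._lexicons import SENTIMENT_LEXICON
from .preprocess import TokenDoc

__all__ = ["score_sentiment", "aggregate_by_country", "topic_shares",
           "CountrySentiment"]


@dataclass(frozen=True)
class CountrySentiment:
    country: str
    topic: int
    n_pos: int
    n_neg: int
    n_neu: int
    population: float
    per_capita_rate: float
    net_score: float


def score_sentiment(doc, lexicon: dict[str, int] | None = None,
                    neutral_band: float = 0.0) -> str:
    """Classify one token document as positive / negative / neutral."""
    if lexicon is None:
        lexicon = SENTIMENT_LEXICON
    if not lexicon:
        raise ValueError("sentiment lexicon is empty")
    toks = doc.tokens if isinstance(doc, TokenDoc) else tuple(doc)
    matched = [lexicon[t] for t in toks if t in lexicon]
    raw = sum(matched) / max(1, len(matched))
    if raw > neutral_band:
        return "positive"
    if raw < -neutral_band:
        return "negative"
    return "neutral"


def aggregate_by_country(records, populations: dict[str, float]) -> pd.DataFrame:
    """Aggregate sentiment-labeled records into (country, topic) rows.

    ``records`` is a DataFrame (or iterable of mappings) with columns
    ``country``, ``topic``, ``sentiment``.  Row order is (country, topic)
    lexicographic; totals across rows conserve the input tweet count.
    """
    df = pd.DataFrame(records)
    if df.empty:
        return pd.DataFrame(columns=["country", "topic", "n_pos", "n_neg",
                                     "n_neu", "population", "per_capita_rate",
                                     "net_score"])
    df = df.copy()
    df["country"] = df["country"].fillna("").replace("", "??")
    rows = []
    for (country, topic), group in df.groupby(["country", "topic"], sort=True):
        n_pos = int((group["sentiment"] == "positive").sum())
        n_neg = int((group["sentiment"] == "negative").sum())
        n_neu = int((group["sentiment"] == "neutral").sum())
        total = n_pos + n_neg + n_neu
        pop = populations.get(country, float("nan"))
        if not (pop > 0):
            pop = float("nan")
        rows.append({
            "country": country,
            "topic": int(topic),
            "n_pos": n_pos, "n_neg": n_neg, "n_neu": n_neu,
            "population": pop,
            "per_capita_rate": total / pop if pop == pop else float("nan"),
            "net_score": (n_pos - n_neg) / total if total else 0.0,
        })
    return pd.DataFrame(rows)


def topic_shares(labels, n_topics: int | None = None,
                 name_table=None) -> pd.DataFrame:
    """Per-topic label shares; percentages sum to 100 up to rounding.

    ``labels`` may be a label array or a LabeledCorpus (labelable subset
    used).
    """
    if hasattr(labels, "labels"):
        lc = labels
        arr = np.asarray(lc.labels)[np.asarray(lc.labelable, bool)]
        n_topics = len(lc.label_names)
        name_table = lc.label_names
    else:
        arr = np.asarray(labels, np.int64)
        if n_topics is None:
            n_topics = int(arr.max()) + 1 if arr.size else 0
    if arr.size and (arr.min() < 0 or arr.max() >= n_topics):
        raise ValueError(f"labels outside [0, {n_topics})")
    counts = np.bincount(arr, minlength=n_topics)
    total = counts.sum()
    shares = counts / total if total else np.zeros(n_topics)
    out = pd.DataFrame({
        "topic": np.arange(n_topics),
        "count": counts,
        "share": shares,
        "percent": 100.0 * shares,
    })
    if name_table is not None:
        out.insert(1, "name", list(name_table))
    return out
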