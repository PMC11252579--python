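"""Reading, filtering and writing tweet-like corpora and tabular side data.

Corpora are exchanged as JSONL (one object per line) or RFC-4180 CSV with a
header row.  The only required field is ``text``; every other field is
defaulted on read.  Malformed records are skipped with a logged reason, but a
file in which more than half of the records are malformed is rejected.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass

from ._lexicons import DEFAULT_KEYWORDS

logger = logging.getLogger(__name__)

__all__ = [
    "Tweet",
    "Corpus",
    "FilterSpec",
    "read_tweets",
    "filter_corpus",
    "write_tweets",
    "write_labeled",
    "read_population_table",
    "read_sentiment_lexicon",
]


@dataclass(frozen=True)
class Tweet:
    """One short post with the metadata fields the pipeline consumes."""

    id: str
    text: str
    lang: str = "en"
    country: str = ""
    created_at: str = ""
    hashtags: tuple[str, ...] = ()
    retweet_count: int = 0
    is_retweet: bool = False
    is_reply: bool = False
    is_quote: bool = False

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError("tweet text must be non-empty")
        if self.retweet_count < 0:
            raise ValueError("retweet_count must be >= 0")
        for tag in self.hashtags:
            if any(ch.isspace() for ch in tag):
                raise ValueError(f"hashtag contains whitespace: {tag!r}")


@dataclass(frozen=True)
class Corpus:
    """An ordered collection of tweets with provenance metadata."""

    tweets: tuple[Tweet, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [t.id for t in self.tweets]
        if len(set(ids)) != len(ids):
            raise ValueError("tweet ids must be unique within a corpus")

    def __len__(self) -> int:
        return len(self.tweets)

    def __iter__(self):
        return iter(self.tweets)


@dataclass(frozen=True)
class FilterSpec:
    """Corpus filter: language, reply/retweet/quote exclusion, keywords, dates.

    An empty ``keywords`` set disables the keyword filter.  ``date_range`` is
    ``(start, end)`` in ISO-8601, inclusive of start and exclusive of end.
    Records with an empty ``lang`` never match an active language filter.
    """

    languages: frozenset[str] = frozenset({"en"})
    exclude_retweets: bool = True
    exclude_replies: bool = True
    exclude_quotes: bool = True
    keywords: frozenset[str] = frozenset(k.lower() for k in DEFAULT_KEYWORDS)
    date_range: tuple[str, str] | None = None
    match_text_substring: bool = True

    def describe(self) -> str:
        parts = [f"languages={sorted(self.languages)}"]
        for name in ("exclude_retweets", "exclude_replies", "exclude_quotes"):
            parts.append(f"{name}={getattr(self, name)}")
        parts.append(f"keywords={len(self.keywords)} terms")
        if self.date_range:
            parts.append(f"dates=[{self.date_range[0]}, {self.date_range[1]})")
        return ", ".join(parts)


_BOOL_TRUE = {"1", "true", "t", "yes", "y"}


def _as_bool(value: object) -> bool:
    if isinstance(value, bool):
        return value
    if value is None:
        return False
    return str(value).strip().lower() in _BOOL_TRUE


def _as_hashtags(value: object) -> tuple[str, ...]:
    if value is None:
        return ()
    if isinstance(value, (list, tuple)):
        raw = [str(v) for v in value]
    else:
        raw = str(value).replace(";", " ").split()
    return tuple(t.lstrip("#").lower() for t in raw if t.lstrip("#"))


def _record_to_tweet(record: dict, index: int) -> Tweet:
    text = record.get("text")
    if text is None or str(text) == "":
        raise ValueError("missing required field `text`")
    rc = record.get("retweet_count", 0)
    return Tweet(
        id=str(record.get("id", index)),
        text=str(text),
        lang=str(record.get("lang") or ""),
        country=str(record.get("country") or ""),
        created_at=str(record.get("created_at") or ""),
        hashtags=_as_hashtags(record.get("hashtags")),
        retweet_count=int(rc) if str(rc).strip() else 0,
        is_retweet=_as_bool(record.get("is_retweet")),
        is_reply=_as_bool(record.get("is_reply")),
        is_quote=_as_bool(record.get("is_quote")),
    )


def read_tweets(path: str, format: str | None = None) -> Corpus:
    """Read a corpus from JSONL or CSV.

    ``format`` is ``"jsonl"`` or ``"csv"``; when omitted it is inferred from
    the file extension.  Records lacking ``text`` (or otherwise malformed)
    are counted and skipped; if more than half of the records are malformed
    the file is rejected as a whole.
    """
    if format is None:
        format = "csv" if str(path).lower().endswith(".csv") else "jsonl"
    if format not in ("jsonl", "csv"):
        raise ValueError(f"unknown corpus format: {format!r}")

    records: list[dict] = []
    if format == "jsonl":
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                try:
                    records.append(json.loads(line))
                except json.JSONDecodeError:
                    records.append({"__parse_error__": line})
    else:
        with open(path, encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                raise ValueError(f"CSV file has no header row: {path}")
            records = [dict(row) for row in reader]

    tweets: list[Tweet] = []
    n_skipped = 0
    seen_ids: set[str] = set()
    for i, record in enumerate(records):
        try:
            if "__parse_error__" in record:
                raise ValueError("unparseable JSON line")
            tweet = _record_to_tweet(record, i)
            if tweet.id in seen_ids:
                raise ValueError(f"duplicate id {tweet.id!r}")
        except (ValueError, TypeError) as exc:
            n_skipped += 1
            logger.warning("skipping record %d of %s: %s", i, path, exc)
            continue
        seen_ids.add(tweet.id)
        tweets.append(tweet)

    if records and n_skipped > len(records) / 2:
        raise ValueError(
            f"{path}: {n_skipped}/{len(records)} records malformed; refusing to continue"
        )
    return Corpus(tuple(tweets), provenance=f"read from {path} ({n_skipped} skipped)")


def _keyword_match(tweet: Tweet, keywords: frozenset[str], match_text: bool) -> bool:
    if not keywords:
        return True
    tags = set(tweet.hashtags)
    text_lc = tweet.text.lower() if match_text else ""
    for kw in keywords:
        kw = kw.lstrip("#").lower()
        if kw in tags or (match_text and kw in text_lc):
            return True
    return False


def filter_corpus(corpus: Corpus, spec: FilterSpec | None = None) -> Corpus:
    """Apply a :class:`FilterSpec`, preserving tweet order.  Idempotent."""
    spec = spec if spec is not None else FilterSpec()
    kept = []
    for tw in corpus:
        if spec.languages and tw.lang.lower() not in spec.languages:
            continue
        if spec.exclude_retweets and tw.is_retweet:
            continue
        if spec.exclude_replies and tw.is_reply:
            continue
        if spec.exclude_quotes and tw.is_quote:
            continue
        if spec.date_range is not None:
            start, end = spec.date_range
            if not tw.created_at or not (start <= tw.created_at < end):
                continue
        if not _keyword_match(tw, spec.keywords, spec.match_text_substring):
            continue
        kept.append(tw)
    return Corpus(tuple(kept), provenance=f"{corpus.provenance}; filtered [{spec.describe()}]")


def write_tweets(corpus: Corpus, path: str) -> None:
    """Write a corpus back to JSONL (round-trip inverse of :func:`read_tweets`)."""
    with open(path, "w", encoding="utf-8") as fh:
        for tw in corpus:
            fh.write(json.dumps({
                "id": tw.id, "text": tw.text, "lang": tw.lang,
                "country": tw.country, "created_at": tw.created_at,
                "hashtags": list(tw.hashtags), "retweet_count": tw.retweet_count,
                "is_retweet": tw.is_retweet, "is_reply": tw.is_reply,
                "is_quote": tw.is_quote,
            }) + "\n")


def write_labeled(labeled, path: str) -> None:
    """Write a labeled corpus as JSONL: original fields + ``label`` (int),
    ``label_name`` (str) and ``topic_scores`` (K floats).

    ``labeled`` is any object with ``tweets``, ``labels``, ``topic_scores``
    and ``label_names`` attributes (see :mod:`crisislda.labeling`).
    """
    n_topics = len(labeled.label_names)
    with open(path, "w", encoding="utf-8") as fh:
        for tw, label, scores in zip(labeled.tweets, labeled.labels, labeled.topic_scores):
            scores = list(map(float, scores))
            if len(scores) != n_topics:
                raise ValueError(
                    f"topic_scores length {len(scores)} != K={n_topics} for tweet {tw.id}"
                )
            if not (0 <= int(label) < n_topics):
                raise ValueError(f"label {label} outside [0, {n_topics}) for tweet {tw.id}")
            fh.write(json.dumps({
                "id": tw.id, "text": tw.text, "lang": tw.lang,
                "country": tw.country, "created_at": tw.created_at,
                "hashtags": list(tw.hashtags), "retweet_count": tw.retweet_count,
                "is_retweet": tw.is_retweet, "is_reply": tw.is_reply,
                "is_quote": tw.is_quote,
                "label": int(label),
                "label_name": labeled.label_names[int(label)],
                "topic_scores": scores,
            }) + "\n")


def read_population_table(path: str) -> dict[str, float]:
    """Read a country→population CSV (columns ``country``, ``population``)."""
    table: dict[str, float] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            table[row["country"].strip()] = float(row["population"])
    return table


def read_sentiment_lexicon(path: str) -> dict[str, int]:
    """Read a term→polarity CSV (columns ``term``, ``polarity`` ∈ {pos, neg})."""
    lex: dict[str, int] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            term = row["term"].strip().lower()
            polarity = row["polarity"].strip().lower()
            if polarity not in ("pos", "neg"):
                raise ValueError(f"polarity must be pos/neg, got {polarity!r}")
            value = +1 if polarity == "pos" else -1
            if lex.get(term, value) != value:
                raise ValueError(f"term {term!r} mapped to both polarities")
            lex[term] = value
    return lex
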