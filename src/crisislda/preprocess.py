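"""Text preprocessing: tokenization, lexicon lemmatization with POS
filtering, bigram/trigram phrase detection, vocabulary construction and
bag-of-words conversion.

The token rules are fixed and documented rather than delegated to a tagger:
text is lowercased; URLs and @-mentions are removed; ``#`` is stripped from
hashtags but the tag word kept; tokens are maximal runs of letters, digits,
underscore and apostrophe containing at least one letter or digit (so hyphens
split and standalone punctuation vanishes); a configurable stopword list is
removed.  Lemmatization is a lookup in a surface→(lemma, POS) table with an
identity/noun fallback, and only tokens whose POS survives the filter
(default: nouns, adjectives, verbs) are kept.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from sklearn.base import BaseEstimator, TransformerMixin

from ._lexicons import LEMMA_LEXICON, STOPWORDS

__all__ = [
    "TokenDoc",
    "PhraseModel",
    "Vocabulary",
    "BowDocument",
    "tokenize",
    "lemmatize",
    "fit_phrases",
    "apply_phrases",
    "build_vocabulary",
    "to_bow",
    "TextPreprocessor",
]

DEFAULT_POS_FILTER = frozenset({"noun", "adjective", "verb"})

_URL_RE = re.compile(r"(?:https?://\S+|www\.\S+)", re.IGNORECASE)
_MENTION_RE = re.compile(r"@\w+")
_TOKEN_RE = re.compile(r"[a-z0-9_']+")
_ALNUM_RE = re.compile(r"[a-z0-9]")


@dataclass(frozen=True)
class TokenDoc:
    """Ordered lowercase tokens for one source document."""

    tokens: tuple[str, ...]
    source_id: str = ""

    def __post_init__(self) -> None:
        for t in self.tokens:
            if any(ch.isspace() for ch in t):
                raise ValueError(f"token contains whitespace: {t!r}")

    def __len__(self) -> int:
        return len(self.tokens)


def tokenize(text: str, stopwords: frozenset[str] | None = None,
             source_id: str = "") -> TokenDoc:
    """Tokenize one text under the module's fixed rules."""
    if stopwords is None:
        stopwords = STOPWORDS
    text = _URL_RE.sub(" ", text)
    text = _MENTION_RE.sub(" ", text)
    text = text.lower().replace("#", " ")
    tokens = [
        t for t in _TOKEN_RE.findall(text)
        if _ALNUM_RE.search(t) and t not in stopwords
    ]
    return TokenDoc(tuple(tokens), source_id=source_id)


def lemmatize(doc: TokenDoc,
              lemma_lexicon: dict[str, tuple[str, str]] | None = None,
              pos_filter: frozenset[str] | None = None) -> TokenDoc:
    """Replace tokens by lexicon lemmas and drop tokens whose POS is filtered.

    Tokens absent from the lexicon are treated as (token, "noun"), so the
    default filter keeps them unchanged.
    """
    if lemma_lexicon is None:
        lemma_lexicon = LEMMA_LEXICON
    if pos_filter is None:
        pos_filter = DEFAULT_POS_FILTER
    out = []
    for tok in doc.tokens:
        lemma, pos = lemma_lexicon.get(tok, (tok, "noun"))
        if pos in pos_filter:
            out.append(lemma)
    return TokenDoc(tuple(out), source_id=doc.source_id)


@dataclass(frozen=True)
class PhraseModel:
    """Collocation model: adjacent pairs scoring above threshold merge to "a_b".

    ``order="trigram"`` chains a first bigram pass (``first_stage``) before the
    second pass whose scores live in ``phrase_scores``.
    """

    order: str
    min_count: int
    threshold: float
    phrase_scores: dict[tuple[str, str], float]
    first_stage: "PhraseModel | None" = None

    def __post_init__(self) -> None:
        if self.order not in ("bigram", "trigram"):
            raise ValueError(f"order must be bigram/trigram, got {self.order!r}")
        if self.order == "trigram" and self.first_stage is None:
            raise ValueError("trigram model requires a first bigram stage")


def _fit_bigram_scores(docs: list[TokenDoc], min_count: int,
                       threshold: float) -> dict[tuple[str, str], float]:
    unigram: dict[str, int] = {}
    pair: dict[tuple[str, str], int] = {}
    for doc in docs:
        toks = doc.tokens
        for t in toks:
            unigram[t] = unigram.get(t, 0) + 1
        for a, b in zip(toks, toks[1:]):
            pair[(a, b)] = pair.get((a, b), 0) + 1
    v_tok = len(unigram)
    scores = {}
    for (a, b), c_ab in pair.items():
        score = (c_ab - min_count) * v_tok / (unigram[a] * unigram[b])
        if score >= threshold:
            scores[(a, b)] = score
    return scores


def fit_phrases(docs: list[TokenDoc], min_count: int = 5,
                threshold: float = 10.0, order: str = "bigram") -> PhraseModel:
    """Learn a collocation model over adjacent token pairs.

    The score of a pair is ``(count(a,b) − min_count) · V / (count(a)·count(b))``
    with ``V`` the number of distinct tokens; pairs scoring at or above
    ``threshold`` merge.  A trigram model is a second bigram pass over the
    bigram-transformed corpus.
    """
    if not docs:
        raise ValueError("fit_phrases requires a non-empty document list")
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    bigram_scores = _fit_bigram_scores(docs, min_count, threshold)
    bigram_model = PhraseModel("bigram", min_count, threshold, bigram_scores)
    if order == "bigram":
        return bigram_model
    transformed = [apply_phrases(bigram_model, d) for d in docs]
    second = _fit_bigram_scores(transformed, min_count, threshold)
    return PhraseModel("trigram", min_count, threshold, second,
                       first_stage=bigram_model)


def apply_phrases(model: PhraseModel, doc: TokenDoc) -> TokenDoc:
    """Greedy left-to-right non-overlapping merge of detected pairs."""
    if model.first_stage is not None:
        doc = apply_phrases(model.first_stage, doc)
    toks = doc.tokens
    out: list[str] = []
    i = 0
    while i < len(toks):
        if i + 1 < len(toks) and (toks[i], toks[i + 1]) in model.phrase_scores:
            out.append(toks[i] + "_" + toks[i + 1])
            i += 2
        else:
            out.append(toks[i])
            i += 1
    return TokenDoc(tuple(out), source_id=doc.source_id)


@dataclass(frozen=True)
class Vocabulary:
    """Term→id bijection onto [0, V) with document frequencies."""

    id_of: dict[str, int]
    df: dict[str, int]

    @property
    def V(self) -> int:
        return len(self.id_of)

    @property
    def terms(self) -> list[str]:
        inv = sorted(self.id_of, key=self.id_of.get)
        return inv

    def __contains__(self, term: str) -> bool:
        return term in self.id_of


def build_vocabulary(docs: list[TokenDoc], min_df: int = 1,
                     max_df_frac: float = 1.0) -> Vocabulary:
    """Build a vocabulary keeping terms with ``min_df ≤ df`` and
    ``df/M ≤ max_df_frac``; ids are assigned in lexicographic term order."""
    m = len(docs)
    if m == 0:
        raise ValueError("cannot build a vocabulary from zero documents")
    df: dict[str, int] = {}
    for doc in docs:
        for term in set(doc.tokens):
            df[term] = df.get(term, 0) + 1
    kept = {t: c for t, c in df.items()
            if c >= min_df and c / m <= max_df_frac}
    if not kept:
        raise ValueError(
            f"empty vocabulary: no term satisfies min_df={min_df}, "
            f"max_df_frac={max_df_frac} over {m} documents"
        )
    id_of = {t: i for i, t in enumerate(sorted(kept))}
    return Vocabulary(id_of=id_of, df=kept)


@dataclass(frozen=True)
class BowDocument:
    """Sparse bag of words: term-id → positive count."""

    counts: dict[int, int]
    source_id: str = ""

    @property
    def n_tokens(self) -> int:
        return sum(self.counts.values())


def to_bow(doc: TokenDoc, vocab: Vocabulary) -> BowDocument:
    """Count in-vocabulary tokens; out-of-vocabulary tokens are dropped."""
    counts: dict[int, int] = {}
    for tok in doc.tokens:
        idx = vocab.id_of.get(tok)
        if idx is not None:
            counts[idx] = counts.get(idx, 0) + 1
    return BowDocument(counts, source_id=doc.source_id)


class TextPreprocessor(BaseEstimator, TransformerMixin):
    """End-to-end text → bag-of-words transformer.

    fit() learns the phrase model and vocabulary from raw texts; transform()
    maps texts to :class:`BowDocument` lists.  ``transform_tokens`` exposes the
    intermediate token documents (used for coherence reference corpora).

    Parameters
    ----------
    phrase_order : "none" | "bigram" | "trigram"
    min_count, threshold : collocation scoring parameters.
    min_df, max_df_frac : vocabulary pruning.
    pos_filter : POS tags retained by lemmatization.
    """

    def __init__(self, phrase_order: str = "bigram", min_count: int = 5,
                 threshold: float = 10.0, min_df: int = 1,
                 max_df_frac: float = 1.0, pos_filter: frozenset | None = None,
                 stopwords: frozenset | None = None,
                 lemma_lexicon: dict | None = None):
        self.phrase_order = phrase_order
        self.min_count = min_count
        self.threshold = threshold
        self.min_df = min_df
        self.max_df_frac = max_df_frac
        self.pos_filter = pos_filter
        self.stopwords = stopwords
        self.lemma_lexicon = lemma_lexicon

    def _tokenize_all(self, texts, ids=None) -> list[TokenDoc]:
        ids = ids if ids is not None else ["" for _ in texts]
        docs = [lemmatize(tokenize(t, self.stopwords, source_id=i),
                          self.lemma_lexicon, self.pos_filter)
                for t, i in zip(texts, ids)]
        return docs

    def fit(self, X, y=None, ids=None):
        docs = self._tokenize_all(X, ids)
        if self.phrase_order != "none":
            self.phrase_model_ = fit_phrases(
                docs, self.min_count, self.threshold, self.phrase_order)
            docs = [apply_phrases(self.phrase_model_, d) for d in docs]
        else:
            self.phrase_model_ = None
        self.vocabulary_ = build_vocabulary(docs, self.min_df, self.max_df_frac)
        return self

    def transform_tokens(self, X, ids=None) -> list[TokenDoc]:
        docs = self._tokenize_all(X, ids)
        if self.phrase_model_ is not None:
            docs = [apply_phrases(self.phrase_model_, d) for d in docs]
        return docs

    def transform(self, X, ids=None) -> list[BowDocument]:
        return [to_bow(d, self.vocabulary_) for d in self.transform_tokens(X, ids)]
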