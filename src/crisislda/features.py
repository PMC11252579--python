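"""Embedding features for the neural classifiers.

Two providers share one interface: ``hashed`` derives every row
deterministically from a keyed hash of the term (no downloads, unit L2 norm,
identical across vocabularies), and ``file`` loads word2vec-text-format
vectors with hashed fallback rows for missing terms.  Contextual providers
can be plugged in by constructing an :class:`EmbeddingMatrix` directly.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass

import numpy as np

from .preprocess import TokenDoc, Vocabulary

logger = logging.getLogger(__name__)

__all__ = ["EmbeddingMatrix", "EncodedBatch", "build_embeddings", "encode",
           "hashed_vector"]


@dataclass(frozen=True)
class EmbeddingMatrix:
    """V×dim real matrix aligned to vocabulary ids."""

    vectors: np.ndarray
    provider: str

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("embedding matrix contains non-finite values")


def hashed_vector(term: str, dim: int, seed: int) -> np.ndarray:
    """Deterministic unit-norm vector keyed by (term, seed) only."""
    digest = hashlib.blake2b(f"{seed}\x00{term}".encode(), digest_size=8).digest()
    rng = np.random.Generator(np.random.PCG64(int.from_bytes(digest, "big")))
    v = rng.standard_normal(dim)
    norm = np.linalg.norm(v)
    return v / norm if norm > 0 else v


def _load_word2vec_text(path: str, dim: int) -> dict[str, np.ndarray]:
    vectors: dict[str, np.ndarray] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path}:1: expected 'count dim' header")
        file_dim = int(header[1])
        if file_dim != dim:
            raise ValueError(
                f"{path}: file dimension {file_dim} != requested {dim}")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split(" ")
            if len(parts) != dim + 1:
                raise ValueError(
                    f"{path}:{lineno}: expected term + {dim} values, "
                    f"got {len(parts)} fields")
            try:
                vectors[parts[0]] = np.array(parts[1:], np.float64)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return vectors


def build_embeddings(vocab: Vocabulary, provider: str = "hashed",
                     dim: int = 300, seed: int = 0,
                     path: str | None = None) -> EmbeddingMatrix:
    """Build a V×dim embedding matrix for a vocabulary."""
    terms = vocab.terms
    if provider == "hashed":
        rows = [hashed_vector(t, dim, seed) for t in terms]
        return EmbeddingMatrix(np.stack(rows), provider="hashed")
    if provider == "file":
        if path is None:
            raise ValueError("file provider requires a path")
        loaded = _load_word2vec_text(path, dim)
        rows = []
        n_fallback = 0
        for t in terms:
            if t in loaded:
                rows.append(loaded[t])
            else:
                rows.append(hashed_vector(t, dim, seed))
                n_fallback += 1
        if n_fallback:
            logger.info("embedding file missing %d/%d vocabulary terms; "
                        "hashed fallback rows used", n_fallback, len(terms))
        return EmbeddingMatrix(np.stack(rows), provider="external-file")
    raise ValueError(f"unknown embedding provider {provider!r}")


@dataclass(frozen=True)
class EncodedBatch:
    """Fixed-length id sequences with pad mask and one-hot labels.

    The pad id is V (one past the largest vocabulary id); ``mask`` is 1.0
    exactly at non-pad positions.  ``labels`` may be ``None`` for
    prediction-only batches.
    """

    ids: np.ndarray
    mask: np.ndarray
    labels: np.ndarray | None
    pad_id: int


def encode(docs: list[TokenDoc], vocab: Vocabulary, max_len: int = 50,
           labels=None, n_classes: int | None = None) -> EncodedBatch:
    """Encode token docs as right-padded/truncated id sequences.

    Out-of-vocabulary tokens are dropped before padding.  Labels, when given,
    become one-hot rows of length ``n_classes``.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    pad_id = vocab.V
    b = len(docs)
    ids = np.full((b, max_len), pad_id, np.int64)
    mask = np.zeros((b, max_len), np.float64)
    for i, doc in enumerate(docs):
        toks = doc.tokens if isinstance(doc, TokenDoc) else tuple(doc)
        seq = [vocab.id_of[t] for t in toks if t in vocab.id_of][:max_len]
        ids[i, :len(seq)] = seq
        mask[i, :len(seq)] = 1.0
    onehot = None
    if labels is not None:
        labels = np.asarray(labels, np.int64)
        if n_classes is None:
            n_classes = int(labels.max()) + 1
        onehot = np.zeros((b, n_classes), np.float64)
        onehot[np.arange(b), labels] = 1.0
    return EncodedBatch(ids=ids, mask=mask, labels=onehot, pad_id=pad_id)


def decode(batch: EncodedBatch) -> list[list[int]]:
    """Recover id sequences (drop pads); inverse of :func:`encode` up to
    truncation and OOV removal."""
    out = []
    for row, m in zip(batch.ids, batch.mask):
        out.append([int(i) for i, keep in zip(row, m) if keep > 0])
    return out
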