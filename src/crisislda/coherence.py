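"""Topic coherence: C_V and pairwise NPMI over boolean sliding windows.

Probabilities are estimated from virtual documents: every token document
contributes its sliding windows of a fixed size (a document shorter than the
window is a single window), and P(w) / P(wi, wj) are the fractions of windows
containing the word / both words (boolean counting, multiplicity ignored).

NPMI(wi, wj) = ln(P(wi,wj) / (P(wi)·P(wj))) / (−ln P(wi,wj)), with an ε floor
(1e-12) substituted for zero probabilities only, so a pair that co-occurs in
every window where either appears scores exactly +1 and a never-co-occurring
pair approaches −1.

c_npmi averages NPMI over the pairs (wi, wj), i < j, of each topic's top
words, then over topics.  c_v uses one-set segmentation: each top word w' is
represented by its NPMI context vector over the whole top-word set, compared
by cosine similarity against the set's summed context vector, averaged over
words then topics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import TokenDoc

__all__ = ["CoherenceScore", "coherence", "npmi_matrix", "select_num_topics"]

EPSILON = 1e-12


@dataclass(frozen=True)
class CoherenceScore:
    measure: str
    value: float
    per_topic: tuple[float, ...]
    top_n: int
    window: int


def _window_statistics(reference_docs, terms: list[str], window: int):
    """Count windows containing each term / each term pair (boolean)."""
    term_ids = {t: i for i, t in enumerate(terms)}
    n = len(terms)
    occ = np.zeros(n, np.int64)
    pair = np.zeros((n, n), np.int64)
    n_windows = 0
    for doc in reference_docs:
        toks = doc.tokens if isinstance(doc, TokenDoc) else tuple(doc)
        if not toks:
            continue
        spans = [toks] if len(toks) <= window else [
            toks[i:i + window] for i in range(len(toks) - window + 1)]
        for span in spans:
            n_windows += 1
            present = sorted({term_ids[t] for t in span if t in term_ids})
            for a_idx, a in enumerate(present):
                occ[a] += 1
                for b in present[a_idx:]:
                    pair[a, b] += 1
                    if a != b:
                        pair[b, a] += 1
    return occ, pair, n_windows


def _npmi(p_a: float, p_b: float, p_ab: float) -> float:
    p_a = max(p_a, EPSILON)
    p_b = max(p_b, EPSILON)
    if p_ab >= 1.0:
        return 1.0
    p_ab = max(p_ab, EPSILON)
    # separate logs so that p_ab == p_a == p_b cancels to exactly 1.0
    log_ab = np.log(p_ab)
    return float((log_ab - np.log(p_a) - np.log(p_b)) / -log_ab)


def npmi_matrix(topic_terms: list[str], occ: np.ndarray, pair: np.ndarray,
                n_windows: int, term_index: dict[str, int]) -> np.ndarray:
    """Symmetric NPMI matrix over one topic's top words."""
    n = len(topic_terms)
    out = np.empty((n, n), np.float64)
    ids = [term_index[t] for t in topic_terms]
    for i in range(n):
        for j in range(n):
            a, b = ids[i], ids[j]
            out[i, j] = _npmi(occ[a] / n_windows, occ[b] / n_windows,
                              pair[a, b] / n_windows)
    return out


def coherence(topics: list[list[str]], reference_docs, measure: str = "c_v",
              window: int = 110, top_n: int | None = None) -> CoherenceScore:
    """Score topics (lists of top terms) against a reference token corpus.

    ``top_n`` truncates each topic's term list; ``None`` keeps all terms.
    """
    if measure not in ("c_v", "c_npmi"):
        raise ValueError(f"unknown coherence measure {measure!r}")
    if not topics or any(len(t) < 2 for t in topics):
        raise ValueError("every topic needs at least 2 terms")
    reference_docs = list(reference_docs)
    if not reference_docs:
        raise ValueError("reference corpus is empty")
    if top_n is not None:
        topics = [list(t)[:top_n] for t in topics]
    else:
        top_n = max(len(t) for t in topics)

    all_terms = sorted({t for topic in topics for t in topic})
    occ, pair, n_windows = _window_statistics(reference_docs, all_terms, window)
    if n_windows == 0:
        raise ValueError("reference corpus produced zero windows")
    term_index = {t: i for i, t in enumerate(all_terms)}

    per_topic = []
    for topic in topics:
        mat = npmi_matrix(list(topic), occ, pair, n_windows, term_index)
        n = mat.shape[0]
        if measure == "c_npmi":
            iu = np.triu_indices(n, k=1)
            per_topic.append(float(mat[iu].mean()))
        else:
            set_vec = mat.sum(axis=0)
            sims = []
            for i in range(n):
                v = mat[i]
                denom = np.linalg.norm(v) * np.linalg.norm(set_vec)
                sims.append(float(v @ set_vec / denom) if denom > 0 else 0.0)
            per_topic.append(float(np.mean(sims)))
    return CoherenceScore(measure=measure, value=float(np.mean(per_topic)),
                          per_topic=tuple(per_topic), top_n=top_n, window=window)


def select_num_topics(texts, candidate_Ks, variants=("unigram", "bigram"),
                      measure: str = "c_v", window: int = 110, top_n: int = 10,
                      sweeps: int = 200, burn_in: int = 50, beta: float = 0.01,
                      min_count: int = 5, threshold: float = 10.0,
                      min_df: int = 1, max_df_frac: float = 1.0,
                      seed: int = 0) -> tuple[pd.DataFrame, tuple[int, str]]:
    """Sweep (K, n-gram variant) combinations and score each fit's coherence.

    Returns the sweep table (one row per combination: K, variant, coherence,
    per-topic scores or an error message) and the argmax-coherence (K, variant)
    pair.  Deterministic given ``seed``: each row derives its own fit seed from
    its position in the grid.
    """
    from .lda import LatentDirichletAllocationGibbs
    from .preprocess import TextPreprocessor

    candidate_Ks = list(candidate_Ks)
    if len(candidate_Ks) < 2:
        raise ValueError("need at least 2 candidate topic counts")
    rows = []
    best = (None, -np.inf)
    for vi, variant in enumerate(variants):
        phrase_order = "none" if variant == "unigram" else variant
        prep = TextPreprocessor(phrase_order=phrase_order, min_count=min_count,
                                threshold=threshold, min_df=min_df,
                                max_df_frac=max_df_frac)
        try:
            bows = prep.fit(texts).transform(texts)
            token_docs = prep.transform_tokens(texts)
        except ValueError as exc:
            for K in candidate_Ks:
                rows.append({"K": K, "variant": variant, "coherence": np.nan,
                             "per_topic": (), "error": str(exc)})
            continue
        vocab = prep.vocabulary_
        for ki, K in enumerate(candidate_Ks):
            row_seed = (int(seed) + 10007 * vi + 101 * ki) % (2 ** 31)
            try:
                model = LatentDirichletAllocationGibbs(
                    n_topics=K, beta=beta, sweeps=sweeps, burn_in=burn_in,
                    random_state=row_seed).fit(bows, n_features=vocab.V)
                topics = [[t for t, _ in model.top_words(k, top_n, vocab)]
                          for k in range(K)]
                score = coherence(topics, token_docs, measure, window, top_n)
                rows.append({"K": K, "variant": variant,
                             "coherence": score.value,
                             "per_topic": score.per_topic, "error": ""})
                if score.value > best[1]:
                    best = ((K, variant), score.value)
            except ValueError as exc:
                rows.append({"K": K, "variant": variant, "coherence": np.nan,
                             "per_topic": (), "error": str(exc)})
    table = pd.DataFrame(rows)
    if best[0] is None:
        raise ValueError("every sweep row failed; see the table's error column")
    return table, best[0]
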