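"""Latent Dirichlet Allocation fitted by collapsed Gibbs sampling.

The generative model: each document d draws topic proportions
θ_d ~ Dirichlet(α); each topic k draws a word distribution
φ_k ~ Dirichlet(β); each token draws a topic z ~ Multinomial(θ_d) and a word
w ~ Multinomial(φ_z).  Collapsed Gibbs sampling integrates θ and φ out and
resamples every token's topic assignment from the full conditional

    P(z_i = k | ·) ∝ (n_dk + α) · (n_kw + β) / (n_k + V·β)

where the counts exclude token i.  Point estimates are the posterior means
φ_kw = (n_kw + β)/(n_k + V·β) and θ_dk = (n_dk + α)/(N_d + K·α), from either
the final sweep's counts (default) or counts averaged after burn-in.

The inner loop is JIT-compiled with numba; the sampler's RNG is numba's own
Mersenne Twister seeded per call, so fits are bit-reproducible.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from numba import njit
from sklearn.base import BaseEstimator, TransformerMixin

from .preprocess import BowDocument, Vocabulary

__all__ = ["LatentDirichletAllocationGibbs", "fit_lda", "infer_theta", "top_words"]


@njit(cache=True)
def _gibbs_fit_kernel(tokens, doc_ids, D, K, V, alpha, beta,
                      sweeps, burn_in, average, anneal_sweeps,
                      anneal_start_temp, seed):
    np.random.seed(seed)
    n = tokens.shape[0]
    z = np.empty(n, np.int64)
    n_dk = np.zeros((D, K), np.int64)
    n_kw = np.zeros((K, V), np.int64)
    n_k = np.zeros(K, np.int64)
    for i in range(n):
        k = np.random.randint(0, K)
        z[i] = k
        n_dk[doc_ids[i], k] += 1
        n_kw[k, tokens[i]] += 1
        n_k[k] += 1
    acc_dk = np.zeros((D, K), np.float64)
    acc_kw = np.zeros((K, V), np.float64)
    n_acc = 0
    p = np.empty(K, np.float64)
    vb = V * beta
    for s in range(sweeps):
        # annealing: temperature decays linearly to 1 over anneal_sweeps,
        # flattening the full conditional early so chains escape the
        # merge/split modes of sharply separated corpora
        if anneal_sweeps > 0 and s < anneal_sweeps:
            temp = anneal_start_temp - (anneal_start_temp - 1.0) * s / anneal_sweeps
            inv_temp = 1.0 / temp
        else:
            inv_temp = 1.0
        for i in range(n):
            d = doc_ids[i]
            w = tokens[i]
            k_old = z[i]
            n_dk[d, k_old] -= 1
            n_kw[k_old, w] -= 1
            n_k[k_old] -= 1
            tot = 0.0
            for k in range(K):
                pk = (n_dk[d, k] + alpha) * (n_kw[k, w] + beta) / (n_k[k] + vb)
                if inv_temp != 1.0:
                    pk = pk ** inv_temp
                p[k] = pk
                tot += pk
            u = np.random.random() * tot
            k_new = K - 1
            acc = 0.0
            for k in range(K):
                acc += p[k]
                if u < acc:
                    k_new = k
                    break
            z[i] = k_new
            n_dk[d, k_new] += 1
            n_kw[k_new, w] += 1
            n_k[k_new] += 1
        if average and s >= burn_in:
            for a in range(D):
                for b in range(K):
                    acc_dk[a, b] += n_dk[a, b]
            for a in range(K):
                for b in range(V):
                    acc_kw[a, b] += n_kw[a, b]
            n_acc += 1
    return z, n_dk, n_kw, n_k, acc_dk, acc_kw, n_acc


@njit(cache=True)
def _gibbs_infer_kernel(tokens, K, V, alpha, beta, n_kw, n_k, sweeps, seed):
    # Fold-in inference: global topic-word counts stay fixed.
    np.random.seed(seed)
    n = tokens.shape[0]
    z = np.empty(n, np.int64)
    n_dk = np.zeros(K, np.int64)
    for i in range(n):
        k = np.random.randint(0, K)
        z[i] = k
        n_dk[k] += 1
    p = np.empty(K, np.float64)
    vb = V * beta
    for s in range(sweeps):
        for i in range(n):
            w = tokens[i]
            k_old = z[i]
            n_dk[k_old] -= 1
            tot = 0.0
            for k in range(K):
                pk = (n_dk[k] + alpha) * (n_kw[k, w] + beta) / (n_k[k] + vb)
                p[k] = pk
                tot += pk
            u = np.random.random() * tot
            k_new = K - 1
            acc = 0.0
            for k in range(K):
                acc += p[k]
                if u < acc:
                    k_new = k
                    break
            z[i] = k_new
            n_dk[k_new] += 1
    return n_dk


def _corpus_log_likelihood(tokens, doc_ids, phi, theta) -> float:
    """In-sample token log-likelihood Σ log(θ_d · φ_{·,w})."""
    per_token = np.einsum("ij,ij->i", theta[doc_ids], phi[:, tokens].T)
    return float(np.log(per_token).sum())


def _expand_tokens(X, n_features=None):
    """Expand documents to flat (token_ids, doc_ids) arrays.

    Accepts a list of :class:`BowDocument`, a scipy sparse matrix or a dense
    count array.  Token order within a document is ascending term id, which
    makes the expansion (and hence the seeded fit) deterministic.
    """
    tok_list: list[np.ndarray] = []
    doc_list: list[np.ndarray] = []
    if isinstance(X, (sp.spmatrix, np.ndarray)) or sp.issparse(X):
        mat = sp.csr_matrix(X)
        n_features = mat.shape[1] if n_features is None else n_features
        for d in range(mat.shape[0]):
            row = mat.getrow(d)
            ids = np.repeat(row.indices.astype(np.int64), row.data.astype(np.int64))
            order = np.argsort(ids, kind="stable")
            tok_list.append(ids[order])
            doc_list.append(np.full(ids.shape[0], d, np.int64))
        n_docs = mat.shape[0]
    else:
        docs = list(X)
        n_docs = len(docs)
        max_id = -1
        for d, doc in enumerate(docs):
            counts = doc.counts if isinstance(doc, BowDocument) else dict(doc)
            ids = np.array(sorted(counts), dtype=np.int64)
            reps = np.array([counts[i] for i in sorted(counts)], dtype=np.int64)
            flat = np.repeat(ids, reps)
            tok_list.append(flat)
            doc_list.append(np.full(flat.shape[0], d, np.int64))
            if len(ids):
                max_id = max(max_id, int(ids[-1]))
        if n_features is None:
            n_features = max_id + 1
    tokens = np.concatenate(tok_list) if tok_list else np.empty(0, np.int64)
    doc_ids = np.concatenate(doc_list) if doc_list else np.empty(0, np.int64)
    return tokens, doc_ids, n_docs, int(n_features)


class LatentDirichletAllocationGibbs(BaseEstimator, TransformerMixin):
    """LDA topic model fitted by collapsed Gibbs sampling.

    Parameters
    ----------
    n_topics : int
        Number of topics K (must be >= 2).
    alpha : float or None
        Symmetric document-topic Dirichlet concentration; ``None`` means 1/K.
    beta : float
        Symmetric topic-word Dirichlet concentration.
    sweeps, burn_in : int
        Gibbs sweeps over the whole corpus and the burn-in prefix.
    average_after_burn_in : bool
        Estimate φ/θ from counts averaged over post-burn-in sweeps instead of
        the final sweep's counts.
    n_restarts : int
        Number of independent chains; the fit with the highest in-sample
        log-likelihood is kept.  Collapsed Gibbs can settle into merge/split
        local modes on sharply separated corpora; a few restarts selected by
        likelihood make the fit robust to them.
    anneal_sweeps, anneal_start_temp : int, float
        Optional simulated annealing: for the first ``anneal_sweeps`` sweeps
        the full conditional is raised to 1/T with the temperature T decaying
        linearly from ``anneal_start_temp`` to 1, which flattens the
        distribution early and greatly improves mode escape on sharp
        corpora.  0 disables annealing (plain collapsed Gibbs).
    infer_sweeps : int
        Sweeps used by :meth:`transform` to fold in unseen documents.
    random_state : int
        Seed; identical inputs and seed give bit-identical fits (restart
        chains derive their seeds from it deterministically).

    Attributes
    ----------
    components_ : (K, V) array — row-stochastic topic-word matrix φ.
    topic_word_counts_, topic_totals_ : final count statistics n_kw, n_k.
    doc_topic_ : (D, K) array — row-stochastic training θ.
    doc_topic_counts_ : (D, K) count matrix n_dk.
    n_features_in_ : vocabulary size V.
    """

    def __init__(self, n_topics: int = 10, alpha: float | None = None,
                 beta: float = 0.01, sweeps: int = 500, burn_in: int = 100,
                 average_after_burn_in: bool = False, n_restarts: int = 1,
                 anneal_sweeps: int = 0, anneal_start_temp: float = 3.0,
                 infer_sweeps: int = 100, random_state: int = 0):
        self.n_topics = n_topics
        self.alpha = alpha
        self.beta = beta
        self.sweeps = sweeps
        self.burn_in = burn_in
        self.average_after_burn_in = average_after_burn_in
        self.n_restarts = n_restarts
        self.anneal_sweeps = anneal_sweeps
        self.anneal_start_temp = anneal_start_temp
        self.infer_sweeps = infer_sweeps
        self.random_state = random_state

    @property
    def _alpha(self) -> float:
        return (1.0 / self.n_topics) if self.alpha is None else float(self.alpha)

    def fit(self, X, y=None, n_features: int | None = None):
        K = int(self.n_topics)
        if K < 2:
            raise ValueError(f"n_topics must be >= 2, got {K}")
        if self._alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be > 0")
        tokens, doc_ids, n_docs, V = _expand_tokens(X, n_features)
        if n_docs == 0 or tokens.shape[0] == 0:
            raise ValueError("cannot fit LDA on an empty corpus (no tokens)")
        if V < K:
            raise ValueError(f"vocabulary size {V} smaller than n_topics {K}")
        best = None
        for restart in range(max(1, int(self.n_restarts))):
            seed = (int(self.random_state) + 7919 * restart) % (2 ** 31)
            z, n_dk, n_kw, n_k, acc_dk, acc_kw, n_acc = _gibbs_fit_kernel(
                tokens, doc_ids, n_docs, K, V, self._alpha, float(self.beta),
                int(self.sweeps), int(self.burn_in),
                bool(self.average_after_burn_in), int(self.anneal_sweeps),
                float(self.anneal_start_temp), seed)
            if self.average_after_burn_in and n_acc > 0:
                kw = acc_kw / n_acc
                dk = acc_dk / n_acc
            else:
                kw = n_kw.astype(np.float64)
                dk = n_dk.astype(np.float64)
            phi = (kw + self.beta) / (
                kw.sum(axis=1, keepdims=True) + V * self.beta)
            theta = (dk + self._alpha) / (
                dk.sum(axis=1, keepdims=True) + K * self._alpha)
            ll = _corpus_log_likelihood(tokens, doc_ids, phi, theta)
            if best is None or ll > best[0]:
                best = (ll, z, n_dk, n_kw, n_k, phi, theta)
        ll, z, n_dk, n_kw, n_k, phi, theta = best
        self.n_features_in_ = V
        self.topic_word_counts_ = n_kw
        self.topic_totals_ = n_k
        self.doc_topic_counts_ = n_dk
        self.assignments_ = z
        self._token_doc_ids = doc_ids
        self.components_ = phi
        self.doc_topic_ = theta
        self.log_likelihood_ = float(ll)
        return self

    def transform(self, X, seed: int | None = None) -> np.ndarray:
        """Infer θ for documents by Gibbs fold-in with fixed topic-word counts.

        Empty documents get the uniform distribution (flagged via a warning).
        """
        from sklearn.utils.validation import check_is_fitted
        check_is_fitted(self, "components_")
        K = int(self.n_topics)
        V = self.n_features_in_
        base_seed = int(self.random_state if seed is None else seed) % (2 ** 31)
        if isinstance(X, BowDocument):
            X = [X]
        tokens, doc_ids, n_docs, _ = _expand_tokens(X, V)
        out = np.empty((n_docs, K), np.float64)
        for d in range(n_docs):
            toks = tokens[doc_ids == d]
            if toks.shape[0] == 0:
                import logging
                logging.getLogger(__name__).warning(
                    "empty document at index %d: returning uniform theta", d)
                out[d] = 1.0 / K
                continue
            n_dk = _gibbs_infer_kernel(
                toks, K, V, self._alpha, float(self.beta),
                self.topic_word_counts_, self.topic_totals_,
                int(self.infer_sweeps), (base_seed + d) % (2 ** 31))
            out[d] = (n_dk + self._alpha) / (toks.shape[0] + K * self._alpha)
        return out

    def top_words(self, k: int, n: int = 10,
                  vocab: Vocabulary | None = None) -> list[tuple]:
        """Top-n terms of topic ``k`` by descending φ, ties by ascending id."""
        from sklearn.utils.validation import check_is_fitted
        check_is_fitted(self, "components_")
        if not (0 <= k < self.n_topics):
            raise ValueError(f"topic id {k} outside [0, {self.n_topics})")
        phi_k = self.components_[k]
        n = min(n, phi_k.shape[0])
        # stable sort on -phi gives descending probability, ascending id ties
        order = np.argsort(-phi_k, kind="stable")[:n]
        if vocab is not None:
            terms = vocab.terms
            return [(terms[i], float(phi_k[i])) for i in order]
        return [(int(i), float(phi_k[i])) for i in order]


def fit_lda(corpus, K: int, alpha: float | None = None, beta: float = 0.01,
            sweeps: int = 500, burn_in: int = 100, seed: int = 0,
            average_after_burn_in: bool = False):
    """Functional wrapper: fit and return ``(model, theta)``."""
    model = LatentDirichletAllocationGibbs(
        n_topics=K, alpha=alpha, beta=beta, sweeps=sweeps, burn_in=burn_in,
        average_after_burn_in=average_after_burn_in, random_state=seed,
    ).fit(corpus)
    return model, model.doc_topic_


def infer_theta(model: LatentDirichletAllocationGibbs, doc,
                sweeps: int | None = None, seed: int | None = None) -> np.ndarray:
    """Infer the topic distribution of a single document."""
    if sweeps is not None:
        old = model.infer_sweeps
        try:
            model.infer_sweeps = sweeps
            return model.transform([doc], seed=seed)[0]
        finally:
            model.infer_sweeps = old
    return model.transform([doc], seed=seed)[0]


def top_words(model: LatentDirichletAllocationGibbs, k: int, n: int = 10,
              vocab: Vocabulary | None = None):
    """Functional wrapper over :meth:`LatentDirichletAllocationGibbs.top_words`."""
    return model.top_words(k, n, vocab)
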