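# Methods

This note documents the models and procedures implemented in `crisislda`,
the parameters that matter, the numerical choices, and what the synthetic
test bed does and does not establish about real social-media data.

## Corpus model and filtering

A post is a record with `text`, an ISO-639-1 `lang`, an optional ISO-3166
country, hashtags, a retweet count and reply/retweet/quote flags.  The
default filter keeps English posts, drops replies, retweets and quotes, and
(optionally) requires at least one keyword from a crisis hashtag list,
matched case-insensitively against hashtags **or** as a text substring; the
substring match maximizes recall and mirrors how keyword collection behaves
at the API level, and can be turned off (`match_text_substring=False`).
Records with an empty `lang` never match an active language filter.  CSV
input follows RFC 4180 with a header row; JSONL is one object per line.
Malformed records are skipped and logged; a file more than half malformed is
rejected outright, on the theory that it is the wrong file rather than a
noisy one.

## Preprocessing

Tokenization is rule-based and deterministic: lowercase; remove URLs and
@-mentions; strip `#` but keep the tag word; tokens are maximal runs of
letters/digits/underscore/apostrophe containing at least one alphanumeric
(hyphens split, standalone punctuation disappears); stopwords from a bundled
~170-word English list (extensible via config) are removed.  The rules are
declared rather than inherited from a tagger so that the whole pipeline is
reproducible without model downloads.  Lemmatization is a lookup in a
surface→(lemma, POS) table — a small bundled table, extensible by CSV — with
identity/noun fallback, and keeps only nouns, adjectives and verbs by
default, the POS classes that carry topical content.  This is deliberately
weaker than a full tagger: out-of-lexicon inflections pass through
unlemmatized.  On the pseudo-word synthetic corpora this is exact; on real
English it is an approximation the lexicon size controls.

Collocations use the plain count-based scoring rule
`score(a,b) = (count(a,b) − min_count) · V / (count(a) · count(b))` with
defaults `min_count=5`, `threshold=10` (the canonical defaults of that
scoring family); pairs at or above threshold merge greedily left-to-right
into `a_b`, and a trigram model is literally a second bigram pass over the
bigram-transformed corpus.  Vocabulary pruning keeps terms with
`min_df ≤ df` and `df/M ≤ max_df_frac`; ids are assigned in lexicographic
order so that every downstream artifact is byte-stable.

## LDA by collapsed Gibbs sampling

Documents mix K topics (θ_d ~ Dir(α), default α = 1/K symmetric); topics are
word distributions (φ_k ~ Dir(β), default β = 0.01).  Inference integrates θ
and φ out and resamples each token's topic from

    P(z_i = k | ·) ∝ (n_dk + α)(n_kw + β) / (n_k + V β)

with the counts excluding token i.  Defaults: 500 sweeps, burn-in 100,
point estimates φ = (n_kw+β)/(n_k+Vβ), θ = (n_dk+α)/(N_d+Kα) from the final
sweep's counts; `average_after_burn_in=True` switches to post-burn-in count
averaging.  The inner loop is numba-compiled; the RNG is seeded per call, so
a fit is a pure function of (corpus, parameters, seed), bit for bit.  Token
order within a document is fixed (ascending term id) to keep the expansion
deterministic; exchangeability makes this statistically irrelevant.

Two optional robustness devices address a real failure mode we observed on
sharply separated corpora (every document essentially single-topic): chains
fall into merge/split modes — two true topics fused, another split — and
stay there, because escaping requires moving an entire topic's tokens
through a low-probability valley.  `n_restarts` runs several independent
chains and keeps the one with the highest in-sample token log-likelihood
Σ log(θ_d·φ_·w) (the good mode is typically thousands of nats better, so the
selection is unambiguous), and `anneal_sweeps`/`anneal_start_temp` raise the
full conditional to 1/T with T decaying linearly from 3 to 1, flattening the
landscape early.  Both default off, preserving the textbook sampler; the
end-to-end labeling pipeline enables `n_restarts=3, anneal_sweeps=200`,
which on sharp synthetic corpora lifts ground-truth label agreement from
≈0.88 (worst seeds) to ≥0.96 across every seed we measured.

Held-out documents are folded in by Gibbs sampling with the global
topic-word counts frozen; an empty document gets the uniform distribution
and a logged warning.

## Topic coherence and model selection

Both measures estimate probabilities from boolean sliding windows (default
size 110) over a reference token corpus; a document shorter than the window
contributes one window.  NPMI(a,b) = ln(P(ab)/(P(a)P(b))) / (−ln P(ab)),
computed with separate logs so the perfect-co-occurrence case cancels to
exactly 1.0 in floating point; an ε = 1e-12 floor replaces zero
probabilities only (a pair that never co-occurs approaches −1; a term absent
from all windows is floored rather than crashing); P(ab) = 1 is defined as
NPMI 1.  `c_npmi` averages NPMI over the pairs i<j of each topic's top-N
words (default N = 10), then over topics.  `c_v` uses one-set segmentation:
each top word is represented by its NPMI context vector over the topic's
top-word set and compared by cosine against the set's summed vector,
averaged over words then topics.  Both are exposed because the field's usage
oscillates between them; `c_v` is the default.  Model selection
(`select_num_topics`) fits one model per (K, n-gram variant) on a grid with
per-cell seeds derived from the master seed, records coherence per cell
(failures recorded, not fatal), and reports the argmax cell.  Perplexity is
deliberately not offered as a selection criterion.

## Dominant-topic weak labels

idf(w) = ln(M/df(w)) with no smoothing — a term in every document scores
exactly 0, a clean invariant — and tf(w,d) = count/N_d.  The document's
score for topic k is Σ_w tfidf(w,d)·φ_kw: the tf-idf mass of the document
projected through the topic-word matrix.  The ranking uses φ only, not the
inferred θ_d, so the label depends on the document's distinctive words
rather than on the sampler's per-document state; this is the simplest
definition consistent with ranking topics per document by a tf-idf
criterion, and it is isolated behind `dominant_topic` so alternatives can be
swapped.  Ties break to the smallest topic index.  A document with an
all-zero score vector (empty after preprocessing, or containing only
zero-idf terms) is flagged unlabelable: it keeps label 0 for serialization
but is excluded from classifier training sets while remaining in aggregate
counts.  Labels are scale-invariant in the tf-idf weights by construction.

## Embedding features

The `hashed` provider derives each row from a keyed hash of the term alone
(plus the global seed), expanded through a counter-based RNG and
L2-normalized — deterministic, identical across vocabularies, no downloads.
The `file` provider reads word2vec text format with hashed fallback rows for
missing terms.  Dimension defaults to 300, the conventional static-embedding
width; the classifier tests and acceptance runs use 64 (and 16 for the
smallest harnesses) since hashed vectors carry no semantics beyond identity
and the synthetic classes are lexically separable.  Contextual embeddings
can be plugged in by constructing an `EmbeddingMatrix` directly; none are
bundled.  Sequences are right-padded/truncated to `max_len` (default 50,
ample for 280-character posts) with a dedicated pad id whose embedding row
is held at zero.

## Neural classifiers

All three architectures share  embed → body → dense(ReLU) → dropout →
K sigmoid units  with binary cross-entropy on one-hot targets — a multilabel
head: scores are per-class Bernoulli probabilities and do not sum to 1, and
the hard label is the argmax (ties to the smallest index).

* **FFNN**: mask-aware mean pool → dense stack (default 128, 64).
* **CNN**: valid 1D convolution (default 128 filters, kernel 3) → ReLU →
  global max pool over valid window positions → dense 64.
* **BiLSTM**: masked LSTM run in both directions (default 64 units per
  direction, forget-gate bias 1), final states concatenated → dense 64.
  Masking carries state across pad positions, so the "final" state is the
  state at each sequence's true end.

Training: Adam (lr 1e-3), batch 64, dropout 0.5, Glorot-uniform init, all
driven by one `numpy.random.Generator` seeded from `random_state` — epoch
shuffling, dropout masks and init are reproducible, and single-threaded
training is bitwise so.  Everything is hand-written NumPy with
backpropagation verified against numeric differentiation (relative error
< 1e-9 away from ReLU/max-pool kinks).  Embeddings are frozen by default;
`trainable_embedding=True` backpropagates into the table (pad row pinned at
zero).  `epochs=0` yields the initialized, untrained model with empty
history — used as the "random-guess" baseline in the t-test harness.

## Evaluation

Per-class counts come from the C×C confusion matrix by one-vs-rest
decomposition; precision, recall, F1, accuracy, FPR and specificity follow
the standard formulas, with zero-denominator cases reported as 0 and
flagged.  Macro = unweighted class mean; micro pools TP/FP/FN first.  For
single-label data the pooled FP and FN totals coincide, so micro-P =
micro-R; the implementation returns that common value directly as micro-F1,
which keeps the micro-F1 = accuracy identity exact in floating point.
Published tables sometimes print "FPR" for 1 − FP/(TN+FP) — which is the
specificity — so both quantities are reported explicitly.  ROC/PR curves
sweep thresholds over the observed scores (score ≥ threshold counts
positive) with trapezoidal AUC, via scikit-learn; a class absent from the
truth has undefined AUC and is excluded from the macro mean with a flag.

The classifier comparison is the Dietterich-style repeated paired test:
r = 5 repetitions; per repetition one random split, both models trained and
scored, roles swapped, giving the accuracy-difference pair (p⁽¹⁾, p⁽²⁾);
s² = the pair's variance about its mean; t = p₁⁽¹⁾/√(Σs²/r) with df = r.
At α = 0.05, df = 5 the two-sided critical value is 2.571.  The split
fraction defaults to 0.5 (the classic two-fold form) and is configurable
down to a 30/70 split.  Zero pooled variance (identical builders) defines
t = 0 with a flag rather than dividing by zero.  No multiple-testing
correction is applied.

## Sentiment and country aggregation

Sentiment is a transparent lexicon scorer: raw = mean polarity of matched
tokens, positive/negative outside a symmetric neutral band (default 0, i.e.
a sign rule; no matches ⇒ neutral).  The bundled ~50-term lexicon is a seed;
real analyses should supply a curated CSV.  A trainable 3-class head reusing
the classifier module is the documented alternative when labeled sentiment
data exists.  Aggregation emits one row per non-empty (country, topic) cell
with counts, a per-capita rate n/population (population normalization), and
the count-free net score (n₊ − n₋)/n ∈ [−1, 1]; both normalizations are
reported explicitly because "normalized sentiment" is ambiguous in the
wild.  Posts without a country pool under "??"; a country missing from the
population table keeps counts but gets a NaN rate.

## Synthetic data

The generator draws φ* ~ Dir(β) (or disjoint per-topic vocabulary blocks
when `separability="disjoint"`), θ*_d ~ Dir(α·K·w) where w are topic prior
weights (uniform default — so uniform weights give the symmetric Dir(α)),
document lengths Poisson(λ = 20) clipped to [3, 50], tokens by the LDA
process, pseudo-words `w0042`.  Each document gets 0–2 hashtags from the
crisis keyword list, a country from a 10-entry table (including an
empty-country slot), and with per-topic probabilities an injected sentiment
class realized by appending lexicon words; fixed adjacent token pairs can be
planted to exercise the collocation detector.  Everything derives from one
seeded generator, so bundles regenerate bit-identically.

What passing on this test bed shows: the sampler recovers generating topics,
the ranking recovers generating labels, the classifiers separate lexically
separable classes, and every metric agrees with brute-force enumeration.
What it does not show: robustness to real-language phenomena — morphology
beyond the lexicon, sarcasm, code-switching, topic drift over time, bot
traffic, and the heavy class imbalance of real crisis corpora are all
outside the generator's model.  Results on real data depend on lexicon
coverage and embedding quality in ways these tests cannot certify.

## Problem sizes and defaults used in the checks

The shipped checks run at desk scale, chosen to exercise the asymptotics
that matter while staying comfortable on one CPU: topic recovery at
K=5/V=300/D=1500 (≈30k tokens, 500 sweeps), end-to-end labeling at
K=10/D=2000, classifier sanity at D=2000 with 70/30 splits and 10 epochs,
t-test power at D=400 with 20-replicate rejection rates, and a
D=5000 draw for share recovery.  The acceptance script reports each
quantity with the problem size it used.
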