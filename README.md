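# crisislda

Weakly supervised topic labeling and neural classification of short
crisis-related social-media posts, with country-level sentiment aggregation.

## The problem

During a fast-moving public-health crisis, millions of short posts (tweets)
carry signal about what the public is worried about — government
restrictions, the economy, vaccines, misinformation — but hand-labeling them
for supervised classification is hopeless at that scale.  `crisislda`
implements an automatic-annotation pipeline for this setting:

1. **Corpus filtering** — keep English posts matching a crisis keyword list,
   drop replies/retweets/quotes.
2. **Preprocessing** — tokenize, lemmatize with a lookup lexicon restricted
   to nouns/adjectives/verbs, and detect bigram/trigram collocations with the
   scoring rule `score(a,b) = (count(a,b) − min_count) · V / (count(a)·count(b))`.
3. **Topic model** — Latent Dirichlet Allocation fitted by collapsed Gibbs
   sampling: θ_d ~ Dir(α), φ_k ~ Dir(β), tokens resampled from
   P(z=k|·) ∝ (n_dk+α)(n_kw+β)/(n_k+Vβ).  The number of topics K is chosen by
   topic coherence (C_V or pairwise NPMI over boolean sliding windows).
4. **Weak labels** — each post's *dominant topic* under the tf-idf-weighted
   topic-affinity ranking  score(d,k) = Σ_w tfidf(w,d)·φ_kw, argmax over k.
   The label names default to a ten-class crisis taxonomy ("Conspiracy
   Theory" … "Vaccine/Cure").
5. **Classifiers** — FFNN, 1D-CNN and BiLSTM over static word embeddings
   (hashed deterministic provider or external word2vec-format vectors), each
   ending in K sigmoid units trained with binary cross-entropy (pure NumPy,
   bitwise reproducible given a seed).
6. **Evaluation** — confusion matrix, one-vs-rest precision/recall/F1/
   accuracy/FPR/specificity with micro/macro averaging, ROC and PR curves
   with AUC, and the repeated paired-split t-test
   t = p₁⁽¹⁾ / √(Σᵢ sᵢ²/r) with df = r = 5 (two-sided critical value 2.571
   at α = 0.05) for comparing classifiers.
7. **Geo-sentiment** — lexicon polarity per post, aggregated per
   (country, topic) with a per-capita rate and a net score
   (n₊ − n₋)/n ∈ [−1, 1].

A synthetic-data module generates tweet-like corpora from a known LDA
process (with hashtags, countries and injected sentiment) so every stage is
testable offline against exact ground truth.

## Worked example

```python
import numpy as np
from crisislda import (GeneratorConfig, sample_corpus, TextPreprocessor,
                       LatentDirichletAllocationGibbs, DominantTopicLabeler,
                       topic_shares)

bundle = sample_corpus(GeneratorConfig(n_topics=5, vocab_size=300,
                                       n_docs=1500, alpha=0.01, seed=11))
texts = [t.text for t in bundle.tweets]
prep = TextPreprocessor(phrase_order="none", min_df=2, max_df_frac=0.5)
bows = prep.fit(texts).transform(texts)
lda = LatentDirichletAllocationGibbs(n_topics=5, alpha=0.1, sweeps=400,
                                     n_restarts=3, anneal_sweeps=200,
                                     random_state=3)
lda.fit(bows, n_features=prep.vocabulary_.V)
labels = DominantTopicLabeler(lda=lda).fit(bows).predict(bows)
print(topic_shares(labels, n_topics=5)[["topic", "count", "percent"]])
```

prints (topic identities are arbitrary up to permutation):

```
   topic  count    percent
0      0    284  18.933333
1      1    305  20.333333
2      2    312  20.800000
3      3    288  19.200000
4      4    311  20.733333
```

i.e. the five generating topics are recovered with roughly the uniform
shares they were sampled with; matching the labels against the generator's
ground truth gives 98.9% agreement after permutation alignment.

The same pipeline is available from the shell:

```bash
crisislda simulate data/ --seed 5
crisislda preprocess data/tweets.jsonl tokens.jsonl
crisislda topics tokens.jsonl model.json --seed 2
crisislda label data/tweets.jsonl model.json labeled.jsonl
crisislda aggregate labeled.jsonl data/populations.csv sentiment.csv
```

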