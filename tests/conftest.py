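import json

import numpy as np
import pytest

from crisislda.corpus_io import Corpus, Tweet
from crisislda.preprocess import TokenDoc


@pytest.fixture
def tiny_tweets():
    """Ten tweets: 4 retweets, 2 with '#vaccine' in the text, mixed langs."""
    rows = []
    for i in range(10):
        rows.append(Tweet(
            id=f"t{i}",
            text=(f"post number {i} about #vaccine rollout" if i in (1, 5)
                  else f"post number {i} about the outbreak"),
            lang="fr" if i == 9 else "en",
            country="US" if i % 2 else "GB",
            created_at=f"2021-01-{i + 1:02d}T00:00:00",
            hashtags=("vaccine",) if i in (1, 5) else (),
            is_retweet=i in (2, 3, 6, 8),
        ))
    return Corpus(tuple(rows))


@pytest.fixture
def jsonl_corpus(tmp_path):
    """Three well-formed JSONL records plus one lacking `text`."""
    path = tmp_path / "tweets.jsonl"
    records = [
        {"id": "a", "text": "masks work", "lang": "en", "country": "US",
         "hashtags": ["covid19"], "retweet_count": 3},
        {"id": "b", "text": "vaccines save lives", "lang": "en"},
        {"id": "c", "text": "stay home stay safe", "lang": "en",
         "is_reply": True},
    ]
    with open(path, "w") as fh:
        for r in records:
            fh.write(json.dumps(r) + "\n")
    return path, records


@pytest.fixture
def toy_token_docs():
    """Five short token docs used as a coherence reference corpus."""
    texts = [
        ["apple", "banana", "apple", "cherry", "date"],
        ["apple", "banana", "cherry", "fig", "grape"],
        ["banana", "cherry", "date", "fig", "grape", "apple"],
        ["date", "fig", "grape", "apple", "banana"],
        ["cherry", "date", "grape", "banana", "fig", "apple", "date"],
    ]
    return [TokenDoc(tuple(t), source_id=str(i)) for i, t in enumerate(texts)]


@pytest.fixture(scope="session")
def sharp_bundle():
    """A sharp-topic synthetic bundle shared by labeling/pipeline tests."""
    from crisislda.synthetic import GeneratorConfig, sample_corpus
    cfg = GeneratorConfig(n_topics=5, vocab_size=250, n_docs=600, alpha=0.01,
                          beta=0.01, doc_length_lambda=15, seed=77)
    return sample_corpus(cfg)


def align_labels(pred, truth, n_classes):
    """Map predicted cluster ids onto truth ids by Hungarian matching."""
    from scipy.optimize import linear_sum_assignment
    c = np.zeros((n_classes, n_classes))
    np.add.at(c, (np.asarray(pred), np.asarray(truth)), 1)
    rows, cols = linear_sum_assignment(-c)
    mapping = dict(zip(rows, cols))
    return np.array([mapping[p] for p in pred])
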