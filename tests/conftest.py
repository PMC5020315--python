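import numpy as np
import pytest

from commalign import (
    Corpus,
    ProcessedDoc,
    load_stopwords,
)


@pytest.fixture(scope="session")
def stopwords():
    return load_stopwords()


def make_disjoint_corpus(
    n_docs_per_topic: int = 50,
    words_per_topic: int = 20,
    doc_len: int = 5,
    n_topics: int = 2,
    seed: int = 0,
):
    """Planted corpus with fully disjoint per-topic vocabularies.

    Returns (Corpus, planted labels array). Topic t draws uniformly from its
    own block of ``words_per_topic`` word types.
    """
    rng = np.random.default_rng(seed)
    docs, labels = [], []
    for t in range(n_topics):
        block = [f"w{t}_{j}" for j in range(words_per_topic)]
        for i in range(n_docs_per_topic):
            tokens = tuple(rng.choice(block, size=doc_len))
            docs.append(ProcessedDoc(f"t{t}d{i}", f"u{t}", tokens))
            labels.append(t)
    return Corpus.from_docs(docs), np.asarray(labels)


def best_label_match_rate(pred, truth) -> float:
    """Fraction of documents whose predicted label matches the planted one
    under the best one-to-one relabeling (Hungarian assignment)."""
    from scipy.optimize import linear_sum_assignment

    pred = np.asarray(pred)
    truth = np.asarray(truth)
    p_ids = np.unique(pred)
    t_ids = np.unique(truth)
    cost = np.zeros((len(p_ids), len(t_ids)))
    for i, p in enumerate(p_ids):
        for j, t in enumerate(t_ids):
            cost[i, j] = -np.sum((pred == p) & (truth == t))
    rows, cols = linear_sum_assignment(cost)
    return -cost[rows, cols].sum() / len(truth)
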