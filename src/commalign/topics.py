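"""Collapsed-Gibbs topic inference: LDA and the Dirichlet Multinomial Mixture.

Both samplers integrate out the multinomial parameters and resample discrete
topic indicators from their count-based full conditionals.

LDA is the standard admixture model: each token carries its own topic
indicator ``z`` resampled with probability

    p(z = t) ∝ (n_dt + α) · (n_tw + β) / (n_t + Vβ)

where the counts exclude the token being resampled. Documents are labeled
afterwards by the maximum of the smoothed document-topic distribution.

DMM (the mixture-of-unigrams model for short documents) assigns exactly one
topic per document; a document's topic is resampled with probability

    p(z_d = t) ∝ (m_t + α) · ∏_{w∈d} ∏_{j=1..f_wd} (n_tw + β + j − 1)
                            / ∏_{i=1..N_d} (n_t + Vβ + i − 1)

with all counts excluding document d (``m_t`` documents in topic t, ``n_tw``
occurrences of word w in topic t, ``n_t`` total tokens in topic t, ``f_wd``
the in-document frequency of w). The product-over-occurrences form supports
repeated words within a document.

Short documents never enter inference; they receive a reserved extra topic
label (the integer ``T``, one past the largest model topic) when unique-
document labels are expanded back onto the full corpus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

from .ingest import ProcessedDoc

__all__ = [
    "Corpus",
    "TopicModelParams",
    "FittedModel",
    "fit_dmm",
    "fit_lda",
    "label_documents",
    "expand_labels",
    "save_model",
    "load_assignments",
    "save_assignments",
]


@dataclass
class Corpus:
    """Integer-encoded documents over a shared vocabulary."""

    vocabulary: dict[str, int]
    docs: list[np.ndarray]          # token-id sequence per document
    doc_ids: list[str]

    @classmethod
    def from_docs(cls, docs: Sequence[ProcessedDoc]) -> "Corpus":
        vocab: dict[str, int] = {}
        encoded = []
        for d in docs:
            if not d.tokens:
                raise ValueError(f"empty document {d.post_id!r}")
            ids = [vocab.setdefault(t, len(vocab)) for t in d.tokens]
            encoded.append(np.asarray(ids, dtype=np.int64))
        return cls(vocab, encoded, [d.post_id for d in docs])

    @property
    def n_docs(self) -> int:
        return len(self.docs)

    @property
    def n_words(self) -> int:
        return len(self.vocabulary)


@dataclass
class TopicModelParams:
    """Sampler settings. ``alpha=None`` uses the model's conventional default
    (0.1 for DMM, 50/T for LDA)."""

    n_topics: int
    alpha: float | None = None
    beta: float = 0.01
    n_iter: int | None = None
    seed: int = 0
    model_kind: Literal["lda", "dmm"] = "dmm"
    #: independent chains for DMM; the one with the highest collapsed joint
    #: log-likelihood is kept (mixture samplers can stick in merged-topic
    #: modes; restarting is the standard remedy)
    n_restarts: int = 1

    def resolved(self) -> tuple[float, float, int]:
        if self.n_topics < 1:
            raise ValueError("n_topics must be >= 1")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        alpha = self.alpha
        if alpha is None:
            alpha = 0.1 if self.model_kind == "dmm" else 50.0 / self.n_topics
        if alpha <= 0:
            raise ValueError("alpha must be > 0")
        n_iter = self.n_iter
        if n_iter is None:
            n_iter = 1000 if self.model_kind == "dmm" else 2000
        if n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        return alpha, self.beta, n_iter


@dataclass
class FittedModel:
    """Final sampler state.

    ``topic_word_counts`` is the T×V count matrix shared by both models.
    LDA additionally stores token-level assignments and document-topic
    counts; DMM stores one label per document plus per-topic document
    counts ``doc_counts`` (m_t) and token totals ``token_totals`` (n_t).
    """

    model_kind: str
    params: TopicModelParams
    topic_word_counts: np.ndarray
    doc_labels: np.ndarray                     # DMM: sampled; LDA: argmax
    doc_topic_counts: np.ndarray | None = None  # LDA only (D×T)
    token_topics: list[np.ndarray] | None = None  # LDA only
    doc_counts: np.ndarray | None = None        # DMM only (m_t)
    token_totals: np.ndarray = field(default_factory=lambda: np.zeros(0))  # n_t

    def topic_word_distributions(self) -> np.ndarray:
        """Smoothed topic-word probabilities φ_tw ∝ n_tw + β."""
        _, beta, _ = self.params.resolved()
        phi = self.topic_word_counts + beta
        return phi / phi.sum(axis=1, keepdims=True)


def _sample_index(rng: np.random.Generator, probs: np.ndarray) -> int:
    cdf = np.cumsum(probs)
    return int(np.searchsorted(cdf, rng.random() * cdf[-1], side="right"))


def _dmm_log_joint(
    model: "FittedModel", alpha: float, beta: float, n_words: int
) -> float:
    """Collapsed joint log-likelihood log p(w, z) of a DMM state (up to a
    z-independent constant); used to select among independent chains."""
    from scipy.special import gammaln

    m = model.doc_counts
    ntw = model.topic_word_counts
    nt = model.token_totals
    t_count = m.size
    score = float(gammaln(m + alpha).sum() - gammaln(m.sum() + t_count * alpha))
    score += float(
        gammaln(ntw + beta).sum()
        - gammaln(nt + n_words * beta).sum()
        + t_count * gammaln(n_words * beta)
        - t_count * n_words * gammaln(beta)
    )
    return score


def fit_dmm(corpus: Corpus, params: TopicModelParams) -> FittedModel:
    """Collapsed-Gibbs inference for the Dirichlet Multinomial Mixture.

    With ``params.n_restarts > 1``, that many independent chains are run
    (seeds derived deterministically from ``params.seed``) and the final
    state with the highest collapsed joint log-likelihood is returned.
    """
    alpha, beta, _ = params.resolved()
    if params.n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    if params.n_restarts == 1:
        return _fit_dmm_chain(corpus, params, params.seed)
    chain_seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(params.seed).spawn(params.n_restarts)
    ]
    chains = [_fit_dmm_chain(corpus, params, s) for s in chain_seeds]
    scores = [_dmm_log_joint(c, alpha, beta, corpus.n_words) for c in chains]
    return chains[int(np.argmax(scores))]


def _fit_dmm_chain(corpus: Corpus, params: TopicModelParams, seed: int) -> FittedModel:
    alpha, beta, n_iter = params.resolved()
    if corpus.n_docs == 0:
        raise ValueError("corpus is empty")
    T, V, D = params.n_topics, corpus.n_words, corpus.n_docs
    rng = np.random.default_rng(seed)

    # per-doc unique words + multiplicities, precomputed once
    doc_words, doc_freqs, doc_lens = [], [], np.empty(D, dtype=np.int64)
    for i, doc in enumerate(corpus.docs):
        w, f = np.unique(doc, return_counts=True)
        doc_words.append(w)
        doc_freqs.append(f)
        doc_lens[i] = len(doc)

    z = rng.integers(0, T, size=D)
    m = np.bincount(z, minlength=T).astype(np.int64)
    ntw = np.zeros((T, V), dtype=np.int64)
    nt = np.zeros(T, dtype=np.int64)
    for i in range(D):
        ntw[z[i], doc_words[i]] += doc_freqs[i]
        nt[z[i]] += doc_lens[i]

    for _ in range(n_iter):
        for i in range(D):
            t_old, w, f = z[i], doc_words[i], doc_freqs[i]
            m[t_old] -= 1
            ntw[t_old, w] -= f
            nt[t_old] -= doc_lens[i]

            logp = np.log(m + alpha)
            for k in range(len(w)):
                cw = ntw[:, w[k]] + beta
                if f[k] == 1:
                    logp += np.log(cw)
                else:
                    logp += np.log(
                        cw[:, None] + np.arange(f[k])[None, :]
                    ).sum(axis=1)
            denom = nt[:, None] + V * beta + np.arange(doc_lens[i])[None, :]
            logp -= np.log(denom).sum(axis=1)

            probs = np.exp(logp - logp.max())
            t_new = _sample_index(rng, probs)
            z[i] = t_new
            m[t_new] += 1
            ntw[t_new, w] += f
            nt[t_new] += doc_lens[i]

    return FittedModel(
        model_kind="dmm",
        params=params,
        topic_word_counts=ntw,
        doc_labels=z.copy(),
        doc_counts=m,
        token_totals=nt,
    )


def fit_lda(corpus: Corpus, params: TopicModelParams) -> FittedModel:
    """Collapsed-Gibbs inference for Latent Dirichlet Allocation."""
    alpha, beta, n_iter = params.resolved()
    if corpus.n_docs == 0:
        raise ValueError("corpus is empty")
    T, V, D = params.n_topics, corpus.n_words, corpus.n_docs
    rng = np.random.default_rng(params.seed)

    zs = [rng.integers(0, T, size=len(doc)) for doc in corpus.docs]
    ndt = np.zeros((D, T), dtype=np.int64)
    ntw = np.zeros((T, V), dtype=np.int64)
    nt = np.zeros(T, dtype=np.int64)
    for d, (doc, z) in enumerate(zip(corpus.docs, zs)):
        for w, t in zip(doc, z):
            ndt[d, t] += 1
            ntw[t, w] += 1
            nt[t] += 1

    vbeta = V * beta
    for _ in range(n_iter):
        for d, (doc, z) in enumerate(zip(corpus.docs, zs)):
            row = ndt[d]
            for j in range(len(doc)):
                w, t_old = doc[j], z[j]
                row[t_old] -= 1
                ntw[t_old, w] -= 1
                nt[t_old] -= 1
                probs = (row + alpha) * (ntw[:, w] + beta) / (nt + vbeta)
                t_new = _sample_index(rng, probs)
                z[j] = t_new
                row[t_new] += 1
                ntw[t_new, w] += 1
                nt[t_new] += 1

    # argmax of the smoothed doc-topic distribution; np.argmax takes the
    # lowest index on ties
    labels = np.argmax(ndt + alpha, axis=1)
    return FittedModel(
        model_kind="lda",
        params=params,
        topic_word_counts=ntw,
        doc_labels=labels,
        doc_topic_counts=ndt,
        token_topics=zs,
        token_totals=nt,
    )


def label_documents(model: FittedModel, corpus: Corpus) -> dict[str, int]:
    """One topic per unique document: the sampled topic (DMM) or the argmax
    of the smoothed document-topic distribution (LDA, ties to the lowest
    topic index)."""
    if len(model.doc_labels) != corpus.n_docs:
        raise ValueError("model and corpus disagree on document count")
    return {pid: int(t) for pid, t in zip(corpus.doc_ids, model.doc_labels)}


def expand_labels(
    unique_assignment: dict[str, int],
    dedup_map: dict[tuple[str, ...], list[str]],
    short_docs: Iterable[ProcessedDoc | str],
    extra_label: int,
) -> dict[str, int]:
    """Map unique-document topics back onto the full corpus.

    Every duplicate inherits its representative's label; every short
    document receives ``extra_label`` (conventionally T, one past the
    largest model topic).
    """
    rep_label: dict[str, int] = dict(unique_assignment)
    full: dict[str, int] = {}
    for post_ids in dedup_map.values():
        rep = next((p for p in post_ids if p in rep_label), None)
        if rep is None:
            raise ValueError(f"no labeled representative among {post_ids!r}")
        for pid in post_ids:
            full[pid] = rep_label[rep]
    for d in short_docs:
        pid = d if isinstance(d, str) else d.post_id
        full[pid] = extra_label
    return full


def save_model(model: FittedModel, corpus: Corpus, prefix: str | Path) -> None:
    """Dump topic-word counts as MatrixMarket plus a vocabulary sidecar TSV."""
    from scipy.io import mmwrite
    from scipy.sparse import csr_matrix

    prefix = Path(prefix)
    mmwrite(str(prefix.with_suffix(".mtx")), csr_matrix(model.topic_word_counts))
    with prefix.with_suffix(".vocab.tsv").open("w", encoding="utf-8") as fh:
        for word, idx in sorted(corpus.vocabulary.items(), key=lambda kv: kv[1]):
            fh.write(f"{idx}\t{word}\n")


def save_assignments(assignment: dict[str, int], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("post_id\ttopic\n")
        for pid, t in assignment.items():
            fh.write(f"{pid}\t{t}\n")


def load_assignments(path: str | Path) -> dict[str, int]:
    out: dict[str, int] = {}
    with Path(path).open(encoding="utf-8") as fh:
        fh.readline()
        for line in fh:
            pid, t = line.rstrip("\n").split("\t")
            out[pid] = int(t)
    return out
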