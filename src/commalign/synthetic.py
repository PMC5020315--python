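"""Seeded synthetic follower networks and short-post corpora.

The generator emulates the study conditions end to end without any external
data: a planted-partition follower graph (communities denser inside than
between) and a short-document corpus whose topics are drawn per post from a
community-level topic distribution. The concentration parameter ``gamma``
interpolates that distribution between uniform over topics (gamma = 0,
topics independent of communities) and a community-specific point mass
(gamma → ∞, every community posts about a single topic), so the
topic-community alignment of the generated data is tunable from none to
perfect. Post texts are synthetic token strings ("w0 w17 ...") that
round-trip unchanged through the ingest pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

from .graph import Partition, modularity
from .ingest import RawPost

__all__ = [
    "GAMMA_MAX",
    "NetworkScenario",
    "CorpusScenario",
    "make_network",
    "make_corpus",
    "scenario_presets",
    "simulate_to_dir",
]

#: gamma values at or above this are treated as infinite (exact point mass).
GAMMA_MAX = 1e6


@dataclass(frozen=True)
class NetworkScenario:
    """Planted-partition follower graph parameters.

    ``community_sizes`` overrides the equal split of ``n_users`` into
    ``n_communities`` blocks (used for size-skewed scenarios).
    """

    n_users: int = 250
    n_communities: int = 10
    p_in: float = 0.3
    p_out: float = 0.01
    seed: int = 0
    community_sizes: tuple[int, ...] | None = None

    def sizes(self) -> list[int]:
        if self.community_sizes is not None:
            return list(self.community_sizes)
        base, rem = divmod(self.n_users, self.n_communities)
        return [base + (1 if i < rem else 0) for i in range(self.n_communities)]

    def validate(self) -> None:
        if not 0 <= self.p_out <= self.p_in <= 1:
            raise ValueError("require 0 <= p_out <= p_in <= 1")
        if self.n_users < 1 or self.n_communities < 1:
            raise ValueError("n_users and n_communities must be >= 1")
        if sum(self.sizes()) != self.n_users:
            raise ValueError("community sizes must sum to n_users")


@dataclass(frozen=True)
class CorpusScenario:
    """Short-post corpus parameters.

    ``gamma`` controls topic-community concentration (0 = independent,
    >= GAMMA_MAX = one topic block per community); ``doc_length_mean`` is the
    Poisson mean of the non-short document length (floored at 3 tokens, short
    documents are emitted separately at rate ``short_frac`` with 1-2 tokens);
    ``posts_per_user_mean`` is the mean of the 1-shifted Poisson post count.
    """

    n_topics: int = 10
    vocab_size: int = 400
    topic_word_concentration: float = 0.05
    doc_length_mean: float = 8.0
    posts_per_user_mean: float = 2.8
    gamma: float = 0.0
    short_frac: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_topics < 1 or self.vocab_size < 1:
            raise ValueError("n_topics and vocab_size must be >= 1")
        if self.topic_word_concentration <= 0:
            raise ValueError("topic_word_concentration must be > 0")
        if self.doc_length_mean < 3 or self.posts_per_user_mean < 1:
            raise ValueError("doc_length_mean >= 3 and posts_per_user_mean >= 1 required")
        if self.gamma < 0 or not 0 <= self.short_frac < 1:
            raise ValueError("gamma >= 0 and 0 <= short_frac < 1 required")
        if self.vocab_size < 2 * self.n_topics:
            import warnings

            warnings.warn(
                "vocabulary may be too small for the requested topic separation",
                stacklevel=2,
            )


def make_network(scenario: NetworkScenario) -> tuple[nx.Graph, Partition]:
    """Planted-partition random graph plus its ground-truth communities.

    Node ids are strings "u0", "u1", ...; community ids follow block order.
    """
    scenario.validate()
    sizes = scenario.sizes()
    k = len(sizes)
    p = [
        [scenario.p_in if i == j else scenario.p_out for j in range(k)]
        for i in range(k)
    ]
    g_int = nx.stochastic_block_model(sizes, p, seed=scenario.seed)
    membership_int = {}
    node = 0
    for c, size in enumerate(sizes):
        for _ in range(size):
            membership_int[node] = c
            node += 1
    g = nx.relabel_nodes(g_int, {n: f"u{n}" for n in g_int.nodes()})
    membership = {f"u{n}": c for n, c in membership_int.items()}
    q = modularity(g, membership) if g.number_of_edges() else float("nan")
    return g, Partition(membership=membership, q=q)


def make_corpus(
    scenario: CorpusScenario, partition: Partition
) -> tuple[list[RawPost], dict[str, int]]:
    """Generate posts for every user in ``partition``.

    Returns the raw posts and the planted topic label per post; short posts
    (fewer than 3 tokens) are labeled ``n_topics``, the reserved extra topic.
    Community c prefers topic c mod n_topics with weight gamma/(1+gamma).
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    n_t, vocab = scenario.n_topics, scenario.vocab_size
    topic_word = rng.dirichlet(
        np.full(vocab, scenario.topic_word_concentration), size=n_t
    )

    comm_ids = sorted(set(partition.membership.values()))
    uniform = np.full(n_t, 1.0 / n_t)
    comm_topic_dist: dict[int, np.ndarray] = {}
    for c in comm_ids:
        point = np.zeros(n_t)
        point[c % n_t] = 1.0
        if scenario.gamma >= GAMMA_MAX:
            comm_topic_dist[c] = point
        else:
            w = scenario.gamma / (1.0 + scenario.gamma)
            comm_topic_dist[c] = (1.0 - w) * uniform + w * point

    posts: list[RawPost] = []
    truth: dict[str, int] = {}
    pid = 0
    for user in sorted(partition.membership, key=lambda u: (len(u), u)):
        dist = comm_topic_dist[partition.membership[user]]
        n_posts = 1 + rng.poisson(scenario.posts_per_user_mean - 1.0)
        for _ in range(n_posts):
            post_id = f"p{pid}"
            pid += 1
            if scenario.short_frac and rng.random() < scenario.short_frac:
                length = int(rng.integers(1, 3))
                topic = int(rng.choice(n_t, p=dist))
                words = rng.choice(vocab, size=length, p=topic_word[topic])
                truth[post_id] = n_t  # reserved extra topic
            else:
                topic = int(rng.choice(n_t, p=dist))
                length = max(3, int(rng.poisson(scenario.doc_length_mean)))
                words = rng.choice(vocab, size=length, p=topic_word[topic])
                truth[post_id] = topic
            text = " ".join(f"w{w}" for w in words)
            posts.append(RawPost(post_id, user, text))
    return posts, truth


@dataclass(frozen=True)
class Scenario:
    """A named bundle of network and corpus parameters."""

    name: str
    network: NetworkScenario
    corpus: CorpusScenario

    def with_seed(self, seed: int) -> "Scenario":
        return Scenario(
            self.name,
            replace(self.network, seed=seed),
            replace(self.corpus, seed=seed + 1),
        )


def _log_spread_sizes(n_users: int, n_communities: int, smallest: int = 3) -> tuple[int, ...]:
    # community sizes geometrically spread between `smallest` and the implied
    # largest size, rescaled to sum exactly to n_users
    raw = np.exp(np.linspace(0.0, np.log(n_users / smallest), n_communities))
    sizes = np.maximum(smallest, np.round(raw * n_users / raw.sum()).astype(int))
    sizes[-1] += n_users - sizes.sum()
    return tuple(int(s) for s in sizes)


def scenario_presets() -> dict[str, Scenario]:
    """Reproducible named scenarios.

    * ``perfect_alignment`` — 10 communities × 25 users, one topic per
      community (gamma = ∞): every topic concentrates in one community.
    * ``no_alignment`` — same shape with gamma = 0: topics independent of
      communities.
    * ``partial_alignment`` — gamma = 1.5, in between.
    * ``realistic_small`` — a 1/100-scale analogue of a large follower
      corpus: 1000 users in 38 log-spread communities, 30 topics, ~2850
      posts including a small fraction of short posts.
    """
    base_net = NetworkScenario(n_users=250, n_communities=10, p_in=0.3, p_out=0.01)
    base_corpus = CorpusScenario(
        n_topics=10, vocab_size=400, posts_per_user_mean=4.0
    )
    return {
        "perfect_alignment": Scenario(
            "perfect_alignment", base_net, replace(base_corpus, gamma=GAMMA_MAX)
        ),
        "no_alignment": Scenario(
            "no_alignment", base_net, replace(base_corpus, gamma=0.0)
        ),
        "partial_alignment": Scenario(
            "partial_alignment", base_net, replace(base_corpus, gamma=1.5)
        ),
        "realistic_small": Scenario(
            "realistic_small",
            NetworkScenario(
                n_users=1000,
                n_communities=38,
                p_in=0.25,
                p_out=0.004,
                community_sizes=_log_spread_sizes(1000, 38),
            ),
            CorpusScenario(
                n_topics=30,
                vocab_size=1500,
                posts_per_user_mean=2.85,
                gamma=4.0,
                short_frac=0.004,
            ),
        ),
    }


def simulate_to_dir(preset: str, seed: int, out_dir: str | Path) -> dict[str, Path]:
    """Materialize a preset as plain-text fixtures: posts.jsonl, edges.tsv,
    truth_topics.tsv, truth_partition.tsv."""
    import json

    scenario = scenario_presets()[preset].with_seed(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    g, partition = make_network(scenario.network)
    posts, truth = make_corpus(scenario.corpus, partition)

    paths = {
        "posts": out / "posts.jsonl",
        "edges": out / "edges.tsv",
        "truth_topics": out / "truth_topics.tsv",
        "truth_partition": out / "truth_partition.tsv",
    }
    with paths["posts"].open("w", encoding="utf-8") as fh:
        for p in posts:
            fh.write(
                json.dumps(
                    {"post_id": p.post_id, "author_id": p.author_id,
                     "text": p.text, "urls": list(p.urls)}
                )
                + "\n"
            )
    with paths["edges"].open("w", encoding="utf-8") as fh:
        for u, v in g.edges():
            fh.write(f"{u}\t{v}\n")
    with paths["truth_topics"].open("w", encoding="utf-8") as fh:
        fh.write("post_id\ttopic\n")
        for pid, t in truth.items():
            fh.write(f"{pid}\t{t}\n")
    with paths["truth_partition"].open("w", encoding="utf-8") as fh:
        fh.write("node\tcommunity\n")
        for node, c in partition.membership.items():
            fh.write(f"{node}\t{c}\n")
    return paths
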