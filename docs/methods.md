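# Methods

This note documents the models, statistics and numerical choices behind
`commalign`, in the order the pipeline runs them.

## Preprocessing

Tokens are produced by whitespace splitting. Tokens beginning with `#` or
`@` are kept verbatim (they are meaningful identifiers, not words). All
other tokens are stripped of surrounding punctuation, lowercased, and
dropped if they are stop words, the standalone retweet marker `rt` (matched
case-insensitively anywhere in the post, since retweet markers are not
always leading), purely numeric (digits with optional `.,%` separators —
alphanumeric tokens like `2day` are kept), or in-text URLs. Surviving
tokens are Porter-stemmed with a from-scratch implementation of the classic
five-step suffix-stripping algorithm (`commalign.stem`); words of length
≤ 2 are left unchanged. Each entry of a post's expanded-URL list
contributes its registered domain (host, lowercased, `www.` stripped) as a
token, unless the domain is a generic shortener (default set: bit.ly, t.co,
ow.ly, goo.gl, tinyurl.com, buff.ly, dlvr.it — configurable); shortened
URLs carry no usable domain signal.

The default stop-word list is the standard built-in English list from
scikit-learn; any newline-separated word file can be supplied instead.

Posts with fewer than 3 tokens after normalization are too short for
co-occurrence-based topic inference; they bypass the models and are
assigned a reserved *extra topic* whose label is the integer `T` (one past
the largest model topic). The remaining posts are deduplicated on their
exact normalized token sequence; the models see each distinct sequence
once, and inferred labels are mapped back to all duplicates.

## Topic models

Both models are fitted by collapsed Gibbs sampling (multinomial parameters
integrated out; discrete topic indicators resampled from count-based
conditionals).

**LDA** resamples each token's topic with probability
`(n_dt + α)(n_tw + β)/(n_t + Vβ)`, counts excluding the token. Defaults:
`α = 50/T`, `β = 0.01`, 2000 sweeps — the conventional settings of
reference collapsed-Gibbs implementations. Documents are labeled by
`argmax_t (n_dt + α)`; exact ties go to the lowest topic index so labeling
is deterministic.

**DMM** (Dirichlet Multinomial Mixture) assigns one topic per document and
resamples it with probability proportional to

```
(m_t + α) · Π_{w∈d} Π_{j=1..f_wd} (n_tw + β + j − 1)
          / Π_{i=1..N_d} (n_t + Vβ + i − 1)
```

with all counts excluding the document; the product-over-occurrences form
handles repeated words. Defaults: `α = 0.1`, `β = 0.01`, 1000 sweeps.
Labels are taken from the final sweep state (no sample averaging), matching
the single-label use of the assignments downstream. Empty topics are legal
and are kept in the label space so `T` is stable.

Mixture samplers move whole documents and can stick in modes where two true
topics are merged and another split; we observed such modes on well-
separated synthetic data (minimum pairwise Jensen–Shannon divergence
between planted topics 0.55 of a 0.69 maximum). `TopicModelParams.n_restarts`
therefore runs several independent chains (seeds spawned deterministically
from the base seed via `numpy.random.SeedSequence`) and keeps the state
with the highest collapsed joint log-likelihood

```
log p(w, z) = Σ_t log Γ(m_t + α) − log Γ(D + Tα)
            + Σ_t [ Σ_w log Γ(n_tw + β) − log Γ(n_t + Vβ) ] + const,
```

which separates clean from merged modes by a wide margin in practice
(≈ 600 nats on the 1000-post synthetic preset). One chain is the default;
the test suite and acceptance script use 3–8 chains where mode-trapping
matters. All sampling uses a single `numpy` PCG64 generator per chain, so
the same seed reproduces bit-identical assignments.

## Community detection

The follower relation is symmetrized into a simple undirected graph
(self-follows dropped, reciprocal follows collapsed). Analysis runs on the
largest connected component; size ties are broken toward the component
containing the smallest node id. Modularity is
`Q = Σ_c [e_c/m − (d_c/2m)²]`. Louvain optimization is delegated to
`networkx.community.louvain_partitions` (seeded; resolution exposed,
default 1); the partition object keeps every aggregation level, community
ids are canonicalized by each community's smallest member, and the reported
Q is recomputed independently by our own modularity function. External
partitions (e.g. from Infomap) can be imported from TSV and are validated
to cover every core node.

## Alignment statistics

Communities are represented by the topic distribution of their members'
posts, accumulated in a community × topic contingency table. Every post
counts once (duplicates and retweets included); posts by authors outside
the largest component are excluded from the table but tracked, and the
extra (short-post) topic is excluded by default (flag to include).

* **purity** `(1/N) Σ_c max_t n_ct`;
* **NMI** with geometric-mean normalization `I(C;T)/√(H(C)H(T))` by default
  (arithmetic and max variants selectable); a single cluster on both sides
  is defined as 1, on one side only as 0 (matching scikit-learn, against
  which the implementation is cross-checked);
* **ARI** in pair-counting form `(Index − E)/(Max − E)`.

**TC_q** for topic *t* sorts communities by their count of *t*-posts
(descending) and returns the smallest k whose cumulative count reaches the
exact real threshold `(q/100)·n_t` (comparison `≥`, no rounding). TC_100 is
the number of communities containing any post of the topic. TC is
non-decreasing in q; community-count ties cannot change the value because
the cumulative sums are identical.

**Permutation test.** Each replicate permutes the topic labels uniformly
across the posts in the table (authorship fixed), which preserves both
margins exactly, and recomputes TC_q per topic. The observed per-topic TC
values are compared against the pooled null (all replicates' values) with
the two-sample KS statistic D; the direction flag is "concentrated" when
the observed median TC is at most the null median. The p-value is
permutation-based rather than asymptotic: each replicate's own TC vector is
scored against the pooled null with the same D, and

```
p = (1 + #{D_r > D_obs} + ½·#{D_r = D_obs}) / (1 + n_perm).
```

The mid-p tie handling matters: TC takes few distinct values under the
null, D is heavily tied, and counting ties fully against the observed value
makes the test severely conservative (near-zero rejection under the null);
with mid-p the null rejection rate at nominal 0.05 is close to nominal,
which the acceptance suite verifies. Default `n_perm = 1000`, seeded.

`sweep_topics` repeats fit → label → align over a grid of topic counts for
both models, reproducing the model-selection experiment at any scale.

## Characterization

**Intrusion tests.** For every ordered pair of distinct topics, k cases
(default 5) of six posts — five sampled without replacement from the base
topic, one intruder at a uniform-random position. Pairs with a topic under
6 posts are skipped with a warning. Scoring reports overall accuracy,
chance level 1/6, and inter- vs intra-group accuracy when topics are
grouped. Human judging is out of scope: the package generates cases,
ingests a response table, and offers an automated distance backend so the
hierarchy pipeline runs end to end without annotators.

**Topic distances.** Intrusion backend: mean detection accuracy per
unordered pair (confusable topics → low accuracy → small distance; missing
pairs imputed at the maximum distance 1, flagged). Automated backend:
Jensen–Shannon divergence (nats; maximum ln 2) between β-smoothed
topic–word distributions. Both are symmetric with zero diagonal.

**Hierarchy.** Classical (Torgerson) MDS — double-centering of squared
distances, eigendecomposition, negative eigenvalues truncated — embeds the
topics (2-D default), then average-linkage agglomeration on the embedded
Euclidean distances merges the closest topics; merge heights are
non-decreasing. Export as Newick (leaf = topic id, branch length = height
difference).

**Profiles and exposure.** Topics map to named groups and groups to themes
via an editable YAML config (the grouping is data, not algorithm; a default
group → theme mapping ships with the package). Community profiles give the
topic histogram, theme proportions (summing to 1 over the community's
posts) and mean posts per user over *all* posts including the extra topic.
A community's majority theme is the plurality theme; exact ties resolve in
the fixed order evidence/advocacy > harms/conspiracies > experiential and
are flagged. The exposure analysis takes every user with ≥ 1 post in a
focal theme (each user counts once regardless of how many such posts) and
tabulates them by their community's majority theme, with a "not connected"
category for users outside the core component; percentages recompute
exactly from the counts.

## Synthetic data

The generator emulates the study conditions, not real language:

* **Network**: planted-partition (stochastic block model) graph, equal
  block sizes by default, `p_in = 0.3`, `p_out = 0.01` — dense enough for
  reliable recovery at a few hundred nodes while clearly sparser between
  blocks; a `community_sizes` override produces skewed-size scenarios.
* **Corpus**: per topic a word distribution drawn from a sparse symmetric
  Dirichlet (concentration 0.05 over a 400-word vocabulary — topics
  overlap little, as distinct discussion themes do); per community a topic
  distribution `(1−w)·uniform + w·δ_topic(c)` with `w = γ/(1+γ)`, so
  `γ = 0` makes topics independent of communities and `γ ≥ 10⁶` (treated
  as ∞) gives one topic block per community; per user `1 + Poisson(μ−1)`
  posts (μ = 2.8 by default, matching a typical posts-per-user rate of a
  topical tweet corpus); per post a topic from the author's community
  distribution and `max(3, Poisson(8))` tokens from the topic's word
  distribution. A `short_frac` option emits 1–2-token posts labeled with
  the extra topic.
* **Presets**: `perfect_alignment` / `partial_alignment` (γ = 1.5) /
  `no_alignment` share one shape (10 communities × 25 users, 10 topics,
  ≈ 1000 posts — about 100 posts per community); `realistic_small` is a
  1/100-scale analogue of a large follower corpus (1000 users, 38
  log-spread communities of sizes ≥ 3, 30 topics, ≈ 2850 posts, 0.4%
  short posts).

What the generator deliberately does **not** emulate: real word semantics,
hashtags/URLs (tokens are synthetic `wK` strings, round-trippable through
ingest), heavy-tailed degree distributions (hubs such as news accounts),
retweet cascades, or temporal dynamics. Passing tests therefore demonstrate
correctness of the statistical machinery under controlled conditions, not
performance on real social-media text.

## Problem sizes and determinism

Tests and the acceptance script run the samplers at reduced scale —
60–200 Gibbs sweeps on ≈ 100–1000 documents, 100–500 permutation
replicates, 50 null datasets for calibration — sizes at which the planted
structure is comfortably recoverable and the whole suite completes in a few
minutes on one CPU. Every stochastic component (samplers, generators,
permutations, case sampling) takes an explicit seed and is reproducible
bit-for-bit; derived seeds stay below 2³¹.

## Known limitations

* DMM/LDA are single-chain MCMC unless `n_restarts` is raised; label
  identifiability is up to permutation only.
* The permutation test conditions on the detected partition; uncertainty in
  community detection is not propagated.
* NMI/ARI degenerate-case conventions (single cluster) follow scikit-learn
  and are conventions, not limits.
* The intrusion-distance backend treats accuracy as a distance directly;
  it is a rank-faithful proxy, not a metric with triangle inequality.
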