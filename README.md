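# commalign

Topic–community alignment analysis for opinion surveillance on social
networks.

When people discuss a public-health topic (vaccines, outbreaks, screening
programs) on a platform like Twitter, two independent structures emerge: the
*social* structure — communities in the follower graph — and the *semantic*
structure — the topics of what they post. `commalign` measures how strongly
these two structures align, which is how one finds online communities where
particular concerns (safety scares, conspiracies, personal experiences)
concentrate, and which users are mostly exposed to them. It is aimed at
computational epidemiologists and social-media researchers who need a
reproducible pipeline rather than a one-off analysis.

## What it computes

The pipeline has five stages, each usable on its own:

1. **Ingest** (`commalign.ingest`) — tweet-style preprocessing: hashtags and
   @-mentions pass through verbatim; other words are lowercased,
   stop words / the retweet marker "rt" / numeric tokens are removed, and the
   rest Porter-stemmed; URLs contribute their registered domain unless they
   come from a shortener. Posts with fewer than 3 tokens are routed to a
   reserved *extra topic*; the rest are deduplicated on their normalized
   token sequence before inference.
2. **Topic inference** (`commalign.topics`) — collapsed-Gibbs samplers for
   LDA and the Dirichlet Multinomial Mixture (DMM, one topic per document —
   the model of choice for short texts). Every post gets exactly one topic
   label: the sampled topic (DMM) or the argmax of the smoothed
   document–topic distribution (LDA).
3. **Community detection** (`commalign.graph`) — the undirected follower
   graph, its largest connected component, and Louvain modularity
   optimization (seeded, with the full aggregation hierarchy). External
   partitions can be imported from TSV.
4. **Alignment** (`commalign.alignment`) — the community × topic contingency
   table and, from it: purity, NMI, ARI, and the **topic concentration**
   statistic

   *TC<sub>q</sub>(t)* = the smallest number of communities whose posts
   jointly cover *q*% of all posts labeled with topic *t*,

   so TC₉₅ = 1 means a topic lives almost entirely inside one community.
   Observed TC values are tested against a margin-preserving permutation
   null (topic labels shuffled across posts, so posts-per-topic and
   posts-per-community margins are exact) with a two-sample
   Kolmogorov–Smirnov statistic D ∈ [0, 1] and a permutation mid-p value.
5. **Characterization** (`commalign.characterize`) — intrusion-test case
   generation and scoring, topic distances (intrusion confusion or
   Jensen–Shannon divergence between topic–word distributions), a
   classical-MDS + agglomerative topic hierarchy, per-community theme
   profiles, and the exposure analysis (which majority-theme communities the
   posters of a focal theme sit in).

A seeded synthetic generator (`commalign.synthetic`) produces
planted-partition follower graphs and short-post corpora whose
topic–community concentration is tunable from independent (`gamma=0`) to
perfectly concentrated (`gamma=∞`), so the whole pipeline is testable
without any data download.

## Worked example

```python
from commalign import *
from commalign.ingest import process_posts

scenario = scenario_presets()["partial_alignment"].with_seed(7)
g, planted = make_network(scenario.network)
posts, truth = make_corpus(scenario.corpus, planted)

docs = process_posts(posts)
kept, short = route_short(docs)
unique_docs, dmap = deduplicate(kept)
corpus = Corpus.from_docs(unique_docs)
model = fit_dmm(corpus, TopicModelParams(n_topics=10, n_iter=60, seed=7, n_restarts=3))
full = expand_labels(label_documents(model, corpus), dmap, short, extra_label=10)

communities = louvain(g, seed=7)
authors = {p.post_id: p.author_id for p in posts}
table = contingency(full, communities, authors, extra_label=10)
scores = alignment_scores(table)
perm = permutation_null(full, communities, authors, q=95, n_perm=500, seed=7,
                        extra_label=10)
```

which prints (via the obvious `print` statements):

```
posts: 979 users: 250 edges: 1239
communities: 10 modularity: 0.672
purity: 0.639  NMI: 0.395  ARI: 0.359
observed TC_95 per topic: [8, 8, 7, 7, 7, 8, 8, 8, 7, 8]
KS D: 1.000  p: 0.0020  direction: concentrated
```

Reading the numbers: Louvain recovers the 10 planted communities
(modularity 0.672). Because this preset is only *partially* aligned
(`gamma = 1.5`), each topic still needs 7–8 of the 10 communities to cover
95% of its posts — but the permutation null says a topic with that many
posts spread by chance would need 9–10, so the observed values sit uniformly
below the null (KS D = 1.0, mid-p ≈ 0.002, direction "concentrated"):
modest but statistically unambiguous concentration of topics inside
communities.

The same pipeline is available from the shell:

```bash
commalign simulate --preset partial_alignment --seed 7 --out-dir work/
commalign preprocess --input work/posts.jsonl --out work/processed.tsv
commalign fit-topics --model dmm --topics 10 --seed 7 --in work/processed.tsv --out work/model
commalign detect-communities --edges work/edges.tsv --seed 7 --out work/partition.tsv
commalign align --assignments work/model.assignments.tsv --partition work/partition.tsv \
    --processed work/processed.tsv --extra-label 10 --seed 7 --out work/report.json
```

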