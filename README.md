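# cooctweets

Keyword co-occurrence networks from per-account collections of short
messages, built for infodemiology: mining what patient communities talk
about on microblogging platforms. Given a corpus of accounts (a free-text
profile plus timestamped tweets), the package selects a disease population
by profile search, reduces each account's tweets to lines of canonical noun
lemmas, and draws the strongest keyword associations as a weighted network
with a spring-embedder layout.

## The statistic at the core

Two words *co-occur* when they appear on the same period-delimited line of
a tweet. The weight of an unordered pair (w₁, w₂) is **the number of
accounts** in which the pair co-occurs at least once:

    count(w₁, w₂) = |{ accounts A : ∃ line ℓ ∈ A with w₁, w₂ ∈ ℓ, w₁ ≠ w₂ }|

counting accounts rather than occurrences, so a single hyper-active account
— or one highly specialized phrase it repeats — contributes each pair at
most once. The top k = 100 pairs by account count become the links of an
undirected network whose nodes are the words themselves.

The drawing is a physical equilibrium: every link is a spring with Hooke's
law force k_s·(d − L), every node a like charge with Coulomb repulsion
k_r/d² against all other nodes, relaxed by damped iteration until the
maximum residual force is below tolerance. For a single linked pair the
equilibrium separation is the positive root of
k_s·d³ − k_s·L·d² − k_r = 0, which the test suite verifies against an
independent root finder.

Upstream of the statistic, text processing follows a standard Japanese
text-mining recipe: tweets are split into lines at "." and "。", lines are
tokenized by a pluggable morphological-analyzer contract (default: greedy
longest-match against a term dictionary), only nouns are kept in lemma
form — verbs and adjectives are deliberately discarded — and synonymous
lemmas are merged onto one canonical noun via a validated flat synonym map.

Because live platform data cannot be redistributed, the package ships a
seeded synthetic-corpus generator that plants known structure: per-disease
account populations (default sizes 313, 158, 134, 87, 64 and 44, emulating
a published profile-search census of cancer-patient accounts in Japan),
tweets of at most 140 characters and at most 200 per account, topical lines
that carry pairs of the topic's keywords at an elevated rate against a
noise vocabulary, and synonym surface variants for the pipeline to undo.

## Worked example

```python
from cooctweets import (
    CooccurrenceNetwork, NounLineTransformer, SpringLayout,
    cap_latest_tweets, default_study_config, generate_corpus, search_profiles,
)

config = default_study_config(seed=1)
corpus = generate_corpus(config)
print(f"corpus: {len(corpus)} accounts")

query = config.query_term_sets()[0]          # "breast cancer"
matched = search_profiles(corpus, query)
print(f"{query.canonical_name}: {len(matched)} accounts matched")

capped = [cap_latest_tweets(a) for a in matched]
noun_lines = NounLineTransformer(
    config.term_dictionary(), config.synonym_map()
).transform(capped)

net = CooccurrenceNetwork(k=100).fit(noun_lines)
print(f"{len(net.pair_counts_)} distinct pairs -> {net.graph_.number_of_edges()} edges")
for pair, count in net.edges_[:3]:
    print(f"  {pair[0]} -- {pair[1]}: {count} accounts")

layout = SpringLayout(random_state=1, max_iterations=2000).fit(net.graph_)
print(f"layout: residual {layout.residual_:.3g} after {layout.n_iter_} iterations")
```

prints

```
corpus: 800 accounts
breast cancer: 313 accounts matched
36131 distinct pairs -> 100 edges
  hormonal treatment -- self-diagnosis: 313 accounts
  lymphedema -- palliative care: 313 accounts
  palliative care -- self-diagnosis: 313 accounts
layout: residual 1.78 after 2000 iterations
```

All 313 breast-cancer accounts mention the planted keyword pairs somewhere
in their tweets, so the strongest links saturate at the population size —
the account-level statistic's intended ceiling — while the 36 000 noise
pairs each occur in only a handful of accounts and fall outside the top
100. (A 60-node drawing stops on its iteration budget; the two-node and
triangle cases in the test suite relax to residuals below 10⁻⁴.)

The same pipeline is available stage by stage from the shell:

```sh
cooc-tweets simulate --config gen.json --seed 1 --out corpus.jsonl --emit-resources res/
cooc-tweets search   --corpus corpus.jsonl --terms res/queries/breast_cancer.txt --out matched.jsonl
cooc-tweets process  --corpus matched.jsonl --dictionary res/terms.tsv --synonyms res/synonyms.tsv --out nl.jsonl
cooc-tweets network  --noun-lines nl.jsonl --k 100 --out edges.tsv
cooc-tweets layout   --edges edges.tsv --seed 1 --out network.graphml
cooc-tweets run      --config run.json --out-dir out/     # all of the above + manifest
```

Corpora are JSON-Lines (one account per line: `account_id`, `profile`,
`tweets[{text, posted_at}]`); dictionaries and synonym/category maps are
TSV; networks are GraphML with `account_count` edge weights and `x`/`y`
node coordinates; every run writes a `manifest.json` with the seed and
per-stage counts.

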