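# Methods

## Pipeline

The analysis is a fixed composition of stages, each exposed as a function
and, where it carries state worth inspecting, as an estimator:

1. **Profile search.** An account belongs to a disease population when its
   profile text contains any query variant as a substring. Both sides are
   NFKC-normalized and case-folded first, so half-width/full-width script
   forms and case differences collapse; this is what makes short variant
   lists sufficient for Japanese, where a disease name is written in
   kanji, hiragana, katakana or Latin script. Matching is deliberately
   bare substring containment — no word boundaries — mirroring how profile
   search services behave.
2. **Harvest cap.** Each selected account keeps only its `tweet_cap`
   newest tweets (default 200, the per-account retrieval ceiling of the
   emulated harvest). Tweets are stably sorted by descending timestamp;
   ties keep the original record order, so the cap is deterministic.
3. **Noun lines.** Tweet text is split into lines at "." and "。" (the
   ideographic full stop is included because Japanese prose overwhelmingly
   uses it; excluding it would leave most real tweets as a single line).
   Lines are tokenized, nouns are kept in lemma form, and synonym variants
   are replaced by their canonical lemma. Verbs and adjectives are tagged
   but always discarded: negation scoping makes their polarity unreliable
   and they are a minority of informative tokens in this setting.
4. **Counting.** A pair's weight is the number of accounts in which it
   co-occurs on at least one line (see README). Self-pairs are excluded —
   a "combination of two words" has distinct members — and within-line
   duplicates are irrelevant because the statistic is a set membership per
   account.
5. **Top-k network.** Pairs are ranked by (account count descending, pair
   lexicographic ascending) and the first k become links. The secondary
   lexicographic key makes a tie at the rank-k boundary deterministic; a
   `ties="include"` mode instead keeps every pair tied with the k-th
   count. k defaults to 100, the conventional size for these drawings.
6. **Layout.** Springs on links, Coulomb repulsion between all node pairs,
   optional centering; damped relaxation to equilibrium, then a greedy
   de-overlap pass (see below).

## Tokenizer contract

Morphological analysis is behind a contract: any callable `line ->
list[Token(surface, lemma, pos)]` may be plugged in (a MeCab/fugashi
wrapper satisfies it directly). The default backend is greedy longest-match
against a term dictionary over the NFKC-casefolded line; unmatched
whitespace-delimited chunks become `pos="other"` tokens and are therefore
dropped from noun lines. This default is exact on the synthetic corpora
(whose dictionary covers every emitted surface) and on any real text whose
vocabulary the dictionary covers; it is *not* a statistical morphological
analyzer and will under-segment out-of-dictionary Japanese text. Multi-word
surfaces ("tumor marker") are supported by the longest-match rule, which is
also why matching is greedy rather than word-by-word.

Synonym maps are validated flat at load time: a canonical lemma never maps
elsewhere, so there are no chains or cycles and application is idempotent.
A chain would make the merge order-dependent; curated synonym lists are
naturally flat, so the validator treats depth as an input error rather than
resolving it silently.

## Synthetic corpus generator

The generator defines the study conditions for every test. It emulates the
structural features of a harvested patient-tweet corpus:

- six disease populations with profile variants in several scripts and
  population sizes 313 / 158 / 134 / 87 / 64 / 44 (the published
  profile-search census this package's default configuration mirrors);
- at most 200 tweets per account (default draw 20–60) and tweets of at
  most 140 characters, each made of 1–3 period-terminated lines of 2–6
  space-delimited words;
- a per-topic `keyword_line_rate` (default 0.6): with this probability a
  line carries two distinct weighted keywords of the topic plus, per extra
  slot, a noise word with probability `noise_rate` (default 0.3) or
  another keyword; otherwise the line is drawn from a 300-word noise
  vocabulary;
- synonym surface variants substituted for canonical keywords with
  probability `synonym_rate` (default 0.3), so synonym integration has
  real work to undo;
- strictly decreasing per-account timestamps, making the harvest cap
  deterministic.

Generation is a pure function of the configuration including its seed.
Lines that would overflow the character limit drop trailing words down to
their minimal core (the planted pair); a configuration whose minimal core
cannot fit raises a configuration error.

What the generator does **not** model: real tweet language (hashtags,
mentions, URLs, spelling noise), out-of-dictionary vocabulary, retweets or
duplicate texts, follower structure, bursty timing, and topic mixture
within one account. Passing tests therefore demonstrate that the pipeline
machinery is correct under known structure — planted pairs are recovered,
counts match a brute-force oracle, runs are reproducible — not that the
default tokenizer would segment arbitrary Japanese tweets correctly.

Every tweet record is treated as-is: no retweet or duplicate-text filtering
is applied anywhere (the account-level statistic already bounds what a
single account can contribute).

## Layout numerics

Parameters (all dimensionless; coordinates share one arbitrary unit):

| parameter | default | role |
|---|---|---|
| `spring_constant` k_s | 1.0 | Hooke force per unit displacement on links |
| `natural_length` L | 1.0 | spring rest length, the target edge length |
| `repulsion_constant` k_r | 1.0 | Coulomb magnitude k_r/d² between all node pairs (0 = uncharged) |
| `step_size` | 0.05 | initial displacement per unit force |
| `force_tolerance` | 1e-4 | convergence threshold on the max per-node force |
| `max_iterations` | 10 000 | accepted-step budget |
| `centering_strength` | auto | 0.01 for disconnected graphs, else 0 |

With k_s = L = k_r = 1 the two-node equilibrium distance is the root of
d³ − d² − 1, ≈ 1.47 — order one, which keeps steps and tolerances on a
common scale. The update is `position += step * force` with backtracking:
a candidate step that would raise the maximum force magnitude is retried
at half the step (60 halvings budgeted per iteration), so the residual
sequence is non-increasing and convergence is testable; an accepted step
regrows the step by 10 % up to its initial value. Coincident points are
regularized by clamping distances at 1e-9, and the random initial
placement in the unit square re-jitters exact collisions. The physical
system alone is translation invariant and, for disconnected graphs,
divergent (components repel forever); the weak centering spring bounds it
and is recorded in the layout metadata. Convergence to a low residual is
guaranteed only for small, symmetric systems; large drawings routinely
stop on the iteration budget at a finite residual, which the `Layout`
reports honestly alongside the iteration count.

The de-overlap pass stands in for the manual adjustments a human makes to
a finished drawing: pairs closer than `min_separation` are pushed apart
symmetrically (overshooting the threshold by 0.1 % so settled pairs stay
above it under any float rounding), up to 100 sweeps. It preserves the
relative arrangement best-effort and makes no claim about link crossings.

## Reporting

Keyword categories (diagnosis / symptoms / treatments / others) ship as a
per-disease TSV fixture rather than code: the assignments reflect expert
judgment, and users can substitute their own. A keyword may carry two
categories for one disease (a drug that is both treatment and a source of
side effects); the fixture keeps both rows and reports list the keyword
under each. Lookups fall back to `unclassified`.

Exports are deterministic byte-for-byte for a given seed: JSON-Lines
corpora and noun lines, TSV edge lists sorted exactly as selected, GraphML
with integer `account_count` edge attributes and decimal `x`/`y` node
coordinates, and a `manifest.json` of per-stage counts written with sorted
keys.

## Problem sizes

The default study configuration (800 accounts, ≈32 000 tweets) generates
in under a second and runs the full per-disease analysis in a few seconds
per query; the test suite uses 8–50 accounts per topic for stage-level
checks and the brute-force counting oracle runs on corpora of at most 20
accounts × 10 lines, where exhaustive triple-loop enumeration is cheap.

## Known limitations

- The default tokenizer is dictionary-bound; real-corpus use requires
  either a comprehensive term dictionary or a plugged morphological
  analyzer.
- Raw account counts carry no significance testing (no PMI or chi-square);
  the ranking is the method, by design.
- The layout reproduces the physical model, not any particular drawing
  tool's numerics, so published figures can be matched in character but
  not pixel-for-pixel.
- Profile search is substring-based and will match mentions of a disease
  that are not self-identification ("my mother has breast cancer").
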