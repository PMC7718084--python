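# Methods

## Pipeline overview

`icfvec` trains skip-gram word embeddings on a community's comments and
validates them with two intrinsic tests before using them for concept
discovery. The package assumes the corpus is *small but topically dense*: a
few hundred thousand tokens from a single community whose vocabulary is
highly domain-specific. Under that assumption, embeddings can be
semantically useful at sizes far below the billion-token corpora word2vec
is usually trained on — the validation machinery exists precisely to check
whether that holds for a given corpus.

## Corpus ingestion

Input is pushshift-style JSON-lines: one object per comment with at least a
`body` field. Bodies that are empty, `[deleted]` or `[removed]` are dropped
before anything else sees them. Tokenization is deliberately simple:
lowercase, URLs removed, any character outside `[a-z0-9']` a separator.
There is no stemming and no stop-word removal — skip-gram needs function
words as context, and the domain's multi-sense tokens (`8am`, `thc`, `cbd`)
must survive intact. Words occurring fewer than `min_count` times (default
5, the word2vec community default) are removed from documents and
vocabulary. Malformed JSONL fails loudly by default (naming the line
number); a lenient mode skips such lines with a warning, for dumps known to
be ragged. Live pushshift crawling is out of scope; a documented stub
(`pushshift_query_url`) shows the query shape.

## Skip-gram training

The trainer follows the original word2vec C implementation, not a
re-derivation:

- **Objective.** Skip-gram: each (center, context) pair within a window
  contributes the log-likelihood of the context word given the center
  word's input vector. With `negative_samples=0` (the default, matching the
  classic `negative=0` + hierarchical-softmax configuration) the output
  distribution is factored over a Huffman tree built from vocabulary
  counts; otherwise negative sampling draws from the unigram distribution
  raised to the 3/4 power.
- **Dynamic window.** The effective radius of each center word is drawn
  uniformly from `[1, window]`, so nearer context words are weighted more.
  A fixed radius is available (`dynamic_window=False`).
- **Learning rate.** Linear decay from `learning_rate` (default 0.025) to
  1/10,000th of it over the total planned training words.
- **Subsampling.** Frequent-word subsampling is off by default (`sample=0`)
  because the target corpora are small; set `sample=1e-3` for the classic
  behavior.
- **Determinism.** Training is single-threaded with an explicit
  linear-congruential RNG (the C tool's constants), so a fixed seed gives
  bit-identical matrices across runs. The `threads` field is accepted for
  interface compatibility but lock-free multithreaded SGD is deliberately
  not implemented: it is irreproducible and unnecessary at these corpus
  sizes. The inner loop is a numba kernel; a full default-design training
  run (120k tokens, dim 50, 5 epochs) takes a few seconds.
- **Diagnostics.** Mean per-pair loss is recorded per epoch
  (`model.epoch_losses`). Loss falls steeply within the first epoch and
  then plateaus; small epoch-to-epoch fluctuations are normal SGD noise.

Defaults mirror a published configuration for this kind of corpus
(dim 200, window 12, 5 epochs, hierarchical softmax). The recovery tests
and the acceptance script use dim 50 and window 5 — ample for corpora with
a few hundred vocabulary words, and fast.

## Cosine geometry

Similarity is `S(u,v) = ⟨u,v⟩/(‖u‖‖v‖)`; the semantic distance used
everywhere is `d = 1 − S ∈ [0, 2]`. Vector algebra queries
(`sum(plus) − sum(minus)`) are not renormalized — cosine queries normalize
anyway, so only direction matters. `nearest_terms` ranks the whole
vocabulary by distance, breaking exact ties by vocabulary order
(count-descending, then lexicographic), and excludes an explicit word set;
analogy and concept queries exclude their own query/seed words, since a
query word is trivially near its own expression.

## Semantic categorization test

For each word *i* of category *C* in a norms table: *a(i)* is the mean
distance to the other in-vocabulary words of *C* (self excluded), *b(i)*
the minimum over other categories *C′* of the mean distance to *C′*'s
words, and `s(i) = (b − a)/max(a, b)` (defined as 0 when both vanish, the
standard silhouette convention). Ties in the argmin go to the lowest
category id, deterministically.

**Duplicated norm words are taken at face value**: if word *i* also appears
in a competing category, its own occurrence there contributes distance 0 to
that category's mean. This matches how the norms behave when used directly
(water is both a non-alcoholic beverage and a liquid, and its silhouette as
a liquid is dragged negative by its zero distance to itself in the beverage
category). `dedupe_norms=True` removes such self-occurrences instead — the
"corrected" variant — because faithfulness to the face-value computation
and the correction are both legitimate, and the choice should be explicit.

Out-of-vocabulary norm words are skipped by default with a coverage report
(`oov_policy="error"` raises instead, naming the words). A category left
with fewer than 2 usable words is reported untestable rather than silently
dropped; it still competes as a neighbor when it has at least 1 usable
word.

The packaged norms fixture (`icfvec/data/category_norms_synthetic.tsv`,
65 categories × 5 ranked words) follows the structure of the updated
Battig–Montague category norms but its word lists are reconstructed
exemplars — see `icfvec/data/PROVENANCE.md`. Replace it with a
transcription of the published norms for publication-grade category
results; the file layout is the same 4-column TSV.

## Analogy battery

Items are `a b c expected` lines (the classic questions-words layout, `:`
section headers ignored). The query vector is `v(a) − v(b) + v(c)`; a hit
means `expected` ranks in the top k (default 5) with a, b, c excluded.
Items with any out-of-vocabulary word are reported untestable and excluded
from the aggregate denominator. The reported distance is `d(query,
v(expected))` whether or not the item hit, so near-misses are visible.

## ICF concept mapping

The concept map is data, not code: a YAML tree of chapters → coded
subcategories, each with `plus`/`minus` seed lists and a result count `k`
(default 6). Seed terms are weighted equally; cosine scale-invariance makes
sum normalization irrelevant, and no evidence supports unequal weights.
Running the map evaluates each expression and reports nearest terms;
queries with missing seeds become skip records naming the words, and the
run continues — a report always contains exactly one entry per configured
query. The packaged default covers ICF environmental-factor chapters e1–e5;
the e1 chapter reproduces published seed expressions for this analysis
style, the rest derive from the ICF subcategory definitions (provenance in
the data directory). Editing the YAML retargets the machinery at any other
ICF component.

## Synthetic corpora: what they do and do not show

`generate_category_corpus` writes pushshift-style JSONL so the *entire*
pipeline is exercised, ingestion included. Each document gets a theme
category; token slots alternate between content (a theme word with
probability `category_coherence`, default 0.7, else a Zipf-distributed
background word) and context (one of the theme's 3 dedicated context
words under the same coin). Sharing context words is what makes
same-category words converge after training.

`generate_analogy_corpus` plants relational pairs (x_i, y_i): all x-words
share one 3-word side context, all y-words another, and each pair
additionally draws a 6-word context subset from a pool shared across pairs.
Two choices matter and were made on mechanism grounds:

- pair contexts are *overlapping subsets*, not dedicated words — a word
  uniquely tied to one pair would itself be the best answer to that pair's
  analogy query, which tests nothing;
- targets occupy every 4th slot rather than alternating — denser targets
  waste most skip-gram pairs on target→target self-prediction, which
  carries no relational information.

The default design (10 categories × 5 words, 8 relation pairs, 200
background words, 2,000 documents × 60 tokens, coherence 0.7, Zipf exponent
1.1) is desk-scale: generation plus training takes seconds. Under it,
planted-category mean silhouette is ≈ 0.98 and the top-5 analogy hit rate
≈ 0.94 over 5 seeds.

These corpora have no grammar, no polysemy, no author or temporal
structure. Passing the recovery tests shows the training and evaluation
machinery is correct and sensitive — it says nothing about the semantic
quality a particular real corpus will yield, which is exactly what the
validation tests are for when pointed at real data.

### A note on the permutation control

Under randomly permuted category membership the mean silhouette is not 0
but mildly **negative** (≈ −0.22 with the default design): *b* is a minimum
over 9 competing category means while *a* is a single mean, and the minimum
of several same-distribution means sits below any one of them. The control
therefore checks for *absence of positive cohesion* (mean s < 0.1) and for
the planted/permuted contrast, not for |mean s| ≈ 0.

## Numerical choices and edge cases

- Silhouette with `max(a,b)=0` → s = 0; zero vectors are rejected in
  cosine computations with a clear error.
- `nearest_terms` with k beyond the eligible vocabulary returns all
  eligible words; k = 0 returns an empty list.
- Vector files use the word2vec text format (`|V| dim` header, 8-decimal
  floats: roundtrip perturbs pairwise distances by < 1e-6); the original
  binary format is supported read-only. Header/row-count mismatches in
  either direction are format errors.
- Huffman tie-breaking follows the C tool's two-pointer merge over
  count-sorted leaves, so the tree — and training — is deterministic.

## Known limitations

- Study-corpus numbers from any particular Reddit dump (comment counts,
  specific nearest-term distances, per-category silhouettes) depend on the
  dump and on training nondeterminism upstream of this package; they are
  illustrations, not regression targets.
- The packaged norms are reconstructed, not transcribed (above).
- No CBOW, GloVe or fastText; no subword units. Skip-gram was chosen for
  its stronger performance on semantic tasks at small scale.
- Multithreaded training is not implemented (determinism first).
- `min_length`/tokenization choices are fixed per run; there is no
  per-document language detection or spam filtering.
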