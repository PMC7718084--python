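# icfvec

Word embeddings for disability-related social-media text, with intrinsic
semantic validation and ICF concept discovery.

## The problem

The WHO's International Classification of Functioning, Disability and
Health (ICF) frames disability as a health experience that occurs in a
*context*: the physical, social and attitudinal environment, coded as
environmental-factor subcategories in five chapters (e1 products and
technology … e5 services, systems and policies). Word embeddings rest on
the same idea — words occurring in similar contexts have similar meanings —
so a skip-gram model trained on a disability community's own comments can
surface the concrete terms (products, services, attitudes, sports, apps)
that populate those ICF subcategories for that community.

`icfvec` packages that workflow for researchers in rehabilitation and
health informatics:

1. **Ingest** a pushshift-style JSON-lines dump of subreddit comments,
   clean and tokenize it (`icfvec.corpus`).
2. **Train** skip-gram word2vec vectors — hierarchical softmax when
   `negative_samples=0`, negative sampling otherwise; single-threaded and
   bit-reproducible with a fixed seed (`icfvec.training`).
3. **Validate** the embedding intrinsically (`icfvec.evaluation`):
   - an **analogy battery**: does `v(a) − v(b) + v(c)` rank the expected
     word in the top k?
   - a **semantic categorization test** against category norms
     (Battig–Montague style): for word *i* with mean within-category cosine
     distance *a(i)* and minimum mean distance to another category *b(i)*,
     the silhouette coefficient

     ```
     s(i) = (b(i) − a(i)) / max(a(i), b(i))
     ```

     is positive when the embedding groups the word with its category.
     Cosine distance is `d(u, v) = 1 − ⟨u,v⟩ / (‖u‖‖v‖)` throughout.
4. **Discover** ICF-related terms (`icfvec.concepts`): run a configurable
   map of ICF codes → seed-term expressions (e.g. `e1100: food +
   cholesterol`, `e1401: adapted + sport`) and report the nearest
   vocabulary terms per subcategory.
5. **Test without any download**: `icfvec.synthetic` generates
   pushshift-style corpora with planted semantic categories and planted
   relational pairs, plus manifests of the ground truth, so every stage is
   verifiable end to end.

## Worked example

```python
import icfvec as iv

# a corpus with 10 planted 5-word categories in Zipfian background noise
design = iv.PlantedDesign(seed=3)
manifest = iv.generate_category_corpus(design, "comments.jsonl")

corpus = iv.build_corpus(iv.read_comments("comments.jsonl"), min_count=5)
model = iv.train_skipgram(
    corpus, iv.TrainingConfig(dim=50, window=5, epochs=5, seed=3)
)

norms = iv.generate_norms_from_manifest(manifest)
records, coverage = iv.silhouette_test(model, norms)
summary = iv.silhouette_summary(records)
print(round(summary["global_mean"], 3))
```

prints `0.98`: the mean silhouette over the 50 planted words is close to
1, i.e. the trained embedding groups nearly every planted word with its own
category rather than any competitor. Running the packaged ICF map against a
model (`iv.run_concept_map(model, iv.load_concept_map())`) returns one
report entry per configured subcategory — nearest terms with cosine
distances, or a skip record naming any seed word missing from the
vocabulary. See `examples/` for one narrative script per capability
(corpus statistics, analogy validation, semantic categorization, concept
mapping) and `docs/methods.md` for the model and its assumptions.

A thin CLI mirrors the library:

```sh
icfvec simulate categories --out sim/ --seed 21
icfvec train --comments sim/comments.jsonl --dim 50 --window 5 --out vecs.txt
icfvec evaluate silhouette --vectors vecs.txt --norms sim/norms.tsv --out report.tsv
icfvec map-concepts --vectors vecs.txt --out icf_report.tsv
```

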