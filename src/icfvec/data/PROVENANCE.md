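# Packaged data provenance

## `category_norms_synthetic.tsv`

A category-norms table in the layout of Van Overschelde, Rawson & Dunlosky's
updated and expanded Battig–Montague category norms: the first 5 exemplars
of the first 65 categories (325 word entries), category ids numbered as in
the published norm (1 "A precious stone", 3 "A relative", 20 "An alcoholic
beverage", 38 "A nonalcoholic beverage", 43 "A vegetable", 52 "A fish",
59 "A liquid", ...).

The exemplar word lists themselves are **synthetic**: they are plausible
reconstructions typed in from general knowledge, not a transcription of the
published production-frequency tables, which were not available when this
fixture was assembled. The table preserves the structural properties the
evaluation machinery depends on — 65 categories x 5 ranked words, and words
that legitimately belong to more than one category (water appears both as a
non-alcoholic beverage and as a liquid) — and is suitable for exercising the
pipeline and as a template. For publication-grade results, replace it with
a transcription of the published norms in the same 4-column TSV layout.

## `icf_environmental_factors.yaml`

Seed-term algebraic expressions for subcategories of the WHO ICF
environmental factors (chapters e1–e5). The e1 (products and technology)
entries and the e555 entry reproduce published seed expressions for this
kind of analysis; the remaining e2–e4 entries were derived from the ICF
subcategory definitions by the package authors. The map is user-editable
data: add, remove or retarget queries freely (including at other ICF
components such as body functions and structures).
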