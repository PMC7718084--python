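"""Ingest a pushshift-style comment dump and report corpus statistics.

Builds a small synthetic dump (the same JSONL layout pushshift.io serves
for a subreddit's comments), reads it back, tokenizes, and prints the
descriptive statistics one would report for a study corpus: comment and
author counts, vocabulary size after rare-word filtering, the top words,
and the percentage of each year's comments containing a chosen word.
"""

import tempfile
from pathlib import Path

import icfvec as iv

workdir = Path(tempfile.mkdtemp())
dump = workdir / "comments.jsonl"

design = iv.PlantedDesign(n_documents=500, tokens_per_document=40, seed=11)
iv.generate_category_corpus(design, dump)

comments = iv.read_comments(dump)          # tombstones would be dropped here
corpus = iv.build_corpus(comments, min_count=5)

print(f"comments read:        {len(comments)}")
print(f"distinct authors:     {len({c.author for c in comments})}")
print(f"vocabulary (count>=5): {len(corpus.vocabulary)} words, "
      f"{corpus.total_tokens} tokens kept")

top, per_year = iv.frequency_report(
    corpus, comments, words=["cat0word0"], k=5
)
print("\ntop 5 words by raw count (word, count):")
for word, count in top:
    print(f"  {word:12s} {count}")

print("\npercentage of each year's comments containing 'cat0word0':")
for _, row in per_year.iterrows():
    print(f"  {row.year}: {row.percent:5.1f}%")
print("\nA planted category word appears only in documents themed with its"
      "\ncategory, so the yearly percentages hover near 1/n_categories.")
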