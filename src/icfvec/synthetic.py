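"""Synthetic comment corpora with planted semantic structure.

Real training data for this pipeline is a decade of comments from a
disability-community subreddit; nothing about the pipeline's correctness
can be tested against it, because embeddings from an unseeded run on an
unversioned dump are not reproducible.  The generators here plant the two
kinds of structure the validation suite measures — semantic categories
(words that share sentence contexts) and relational pairs (supporting
a - b + c analogies) — inside a Zipfian background vocabulary, and write
pushshift-style JSONL so the whole pipeline, ingestion included, is
exercised end to end.  Manifests record all planted ground truth.

What these corpora do NOT emulate: grammar, discourse, polysemy, author
effects, or any temporal drift.  Passing recovery tests shows the
training/evaluation machinery works, not that real Reddit text yields
embeddings of any particular quality.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .evaluation import Category, CategoryNorms

#: posting window of the study corpus: Feb 2009 .. Dec 2019
_UTC_START = 1_233_446_400
_UTC_END = 1_577_750_400

#: context words dedicated to each planted category or relation side
CONTEXT_WORDS_PER_GROUP = 3


@dataclass(frozen=True)
class PlantedDesign:
    """Size and strength of the planted structure.

    ``category_coherence`` is the probability that a content slot in a
    category-themed document is filled from that category (the rest comes
    from the Zipfian background).  Defaults are desk-scale: they train in
    seconds at dim 50 while leaving enough signal for category and analogy
    recovery.
    """

    n_categories: int = 10
    words_per_category: int = 5
    n_relation_pairs: int = 8
    background_vocab: int = 200
    n_documents: int = 2000
    tokens_per_document: int = 60
    category_coherence: float = 0.7
    zipf_exponent: float = 1.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_categories",
            "words_per_category",
            "n_relation_pairs",
            "n_documents",
            "tokens_per_document",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.background_vocab < 0:
            raise ValueError("background_vocab must be >= 0")
        if not 0.0 < self.category_coherence <= 1.0:
            raise ValueError("category_coherence must be in (0, 1]")


def _zipf_weights(n: int, exponent: float) -> np.ndarray:
    ranks = np.arange(1, n + 1, dtype=np.float64)
    w = ranks ** (-exponent)
    return w / w.sum()


def _write_jsonl(docs: list[list[str]], path, rng: np.random.Generator) -> None:
    """Write documents as pushshift-style comment JSONL.

    Timestamps are sorted uniform draws over the 2009-2019 window; authors
    and ids are synthetic.
    """
    stamps = np.sort(rng.integers(_UTC_START, _UTC_END, size=len(docs)))
    with open(path, "w", encoding="utf-8") as fh:
        for i, doc in enumerate(docs):
            rec = {
                "body": " ".join(doc),
                "author": f"user{rng.integers(0, max(2, len(docs) // 4)):05d}",
                "created_utc": int(stamps[i]),
                "id": f"c{i:07d}",
            }
            fh.write(json.dumps(rec) + "\n")


def generate_category_corpus(
    design: PlantedDesign, corpus_path, manifest_path=None
) -> dict:
    """Write a JSONL corpus with planted semantic categories.

    Each document gets a theme category.  Token positions alternate between
    a *content* slot — a theme-category word with probability
    ``category_coherence``, else a background word — and a *context* slot —
    one of the theme's 3 dedicated context words under the same coin, else
    background.  Sharing context words is what makes same-category words
    land near each other after training.

    Returns (and optionally writes) a manifest with every word's category,
    every document's theme, and exact token counts.
    """
    rng = np.random.default_rng(design.seed)
    cats = {
        c: [f"cat{c}word{w}" for w in range(design.words_per_category)]
        for c in range(design.n_categories)
    }
    ctx = {
        c: [f"cat{c}ctx{j}" for j in range(CONTEXT_WORDS_PER_GROUP)]
        for c in range(design.n_categories)
    }
    bg = [f"bg{i}" for i in range(design.background_vocab)]
    bg_w = (
        _zipf_weights(design.background_vocab, design.zipf_exponent)
        if design.background_vocab
        else None
    )

    docs: list[list[str]] = []
    themes: list[int] = []
    for _ in range(design.n_documents):
        theme = int(rng.integers(design.n_categories))
        themes.append(theme)
        doc = []
        for t in range(design.tokens_per_document):
            pool = cats[theme] if t % 2 == 0 else ctx[theme]
            if bg is not None and bg_w is not None and (
                rng.random() >= design.category_coherence
            ):
                doc.append(bg[rng.choice(design.background_vocab, p=bg_w)])
            else:
                doc.append(pool[int(rng.integers(len(pool)))])
        docs.append(doc)

    _write_jsonl(docs, corpus_path, rng)

    counts: dict[str, int] = {}
    for doc in docs:
        for tok in doc:
            counts[tok] = counts.get(tok, 0) + 1
    manifest = {
        "kind": "category",
        "design": asdict(design),
        "categories": cats,
        "context_words": ctx,
        "background_words": bg,
        "document_themes": themes,
        "token_counts": counts,
    }
    if manifest_path is not None:
        with open(manifest_path, "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1)
    return manifest


def generate_analogy_corpus(
    design: PlantedDesign, corpus_path, items_path=None, manifest_path=None
) -> dict:
    """Write a JSONL corpus with planted relational pairs (x_i, y_i).

    All x-words share one context set, all y-words another, and each pair
    additionally shares a pair-specific context set, so that
    v(x_i) - v(y_i) is approximately pair-independent — the geometry behind
    a - b + c analogies.  Pair contexts are overlapping subsets of a shared
    pool: no single context word identifies a pair (which would make that
    context word, not the planted pair member, the best answer to the
    analogy query), but the *combination* does — the diffuse way relational
    contexts behave in natural text.  Emits items ``x_i - y_i + y_j -> x_j``
    for every anchor i and j != i (n_relation_pairs * (n_relation_pairs - 1)
    items).
    """
    if design.n_relation_pairs < 2:
        raise ValueError("n_relation_pairs must be >= 2")
    rng = np.random.default_rng(design.seed)
    n = design.n_relation_pairs
    xs = [f"pair{i}x" for i in range(n)]
    ys = [f"pair{i}y" for i in range(n)]
    side_ctx = {
        "x": [f"xside{j}" for j in range(CONTEXT_WORDS_PER_GROUP)],
        "y": [f"yside{j}" for j in range(CONTEXT_WORDS_PER_GROUP)],
    }
    pool = [f"relctx{m}" for m in range(4 * n)]
    pair_ctx = {
        i: sorted(
            rng.choice(pool, size=min(6, len(pool)), replace=False).tolist()
        )
        for i in range(n)
    }
    bg = [f"bg{i}" for i in range(design.background_vocab)]
    bg_w = (
        _zipf_weights(design.background_vocab, design.zipf_exponent)
        if design.background_vocab
        else None
    )

    docs: list[list[str]] = []
    doc_labels: list[dict] = []
    for _ in range(design.n_documents):
        i = int(rng.integers(n))
        side = "x" if rng.random() < 0.5 else "y"
        target = xs[i] if side == "x" else ys[i]
        doc_labels.append({"pair": i, "side": side})
        doc = []
        for t in range(design.tokens_per_document):
            # target every 4th slot, context between: a denser target would
            # spend most skip-gram pairs on target->target self-prediction,
            # which carries no relational information
            if t % 4 == 0:
                tok_pool = [target]
            else:
                tok_pool = side_ctx[side] + pair_ctx[i]
            if bg_w is not None and rng.random() >= design.category_coherence:
                doc.append(bg[rng.choice(design.background_vocab, p=bg_w)])
            else:
                doc.append(tok_pool[int(rng.integers(len(tok_pool)))])
        docs.append(doc)

    _write_jsonl(docs, corpus_path, rng)

    items = [
        (xs[i], ys[i], ys[j], xs[j])
        for i in range(n)
        for j in range(n)
        if j != i
    ]
    if items_path is not None:
        with open(items_path, "w", encoding="utf-8") as fh:
            fh.write(": planted-relations\n")
            for a, b, c, d in items:
                fh.write(f"{a} {b} {c} {d}\n")

    manifest = {
        "kind": "analogy",
        "design": asdict(design),
        "pairs": [[x, y] for x, y in zip(xs, ys)],
        "side_context": side_ctx,
        "pair_context": {str(k): v for k, v in pair_ctx.items()},
        "background_words": bg,
        "document_labels": doc_labels,
        "items": [list(it) for it in items],
    }
    if manifest_path is not None:
        with open(manifest_path, "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1)
    return manifest


def generate_norms_from_manifest(
    manifest: dict, inject_duplicate: bool = False
) -> CategoryNorms:
    """Turn a category manifest into norms for the silhouette test.

    ``inject_duplicate=True`` additionally places the first word of the
    first category at the end of the second category's list, recreating the
    situation where one norm word belongs to two categories and its
    self-distance of 0 drags the competing mean down.
    """
    if manifest.get("kind") != "category":
        raise ValueError("manifest is not from generate_category_corpus")
    cats = manifest["categories"]
    categories = []
    for cid_str in sorted(cats, key=lambda s: int(s)):
        cid = int(cid_str)
        words = list(cats[cid_str])
        if inject_duplicate and cid == 1:
            dup = cats[sorted(cats, key=lambda s: int(s))[0]][0]
            words.append(dup)
        categories.append(
            Category(category_id=cid, label=f"planted category {cid}",
                     words=tuple(words))
        )
    return CategoryNorms(categories=categories)
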