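"""Intrinsic validation of an embedding.

Two complementary checks:

* a **semantic categorization test**: for every word of a category-norms
  table (Battig–Montague style), a silhouette coefficient over cosine
  distances measures whether the word sits closer to its own category's
  words than to the nearest other category;
* an **analogy battery**: a - b + c queries whose expected answer should
  appear among the top-k nearest vocabulary words.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .training import EmbeddingModel, nearest_terms, vector_expression

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Category:
    category_id: int
    label: str
    words: tuple[str, ...]


@dataclass
class CategoryNorms:
    """Ordered semantic categories, each an ordered word list.

    A word may appear in several categories (the norms themselves do this:
    "water" is both a non-alcoholic beverage and a liquid) but not twice
    within one category.
    """

    categories: list[Category]

    def __post_init__(self) -> None:
        for cat in self.categories:
            if not cat.words:
                raise ValueError(f"category {cat.category_id} is empty")
            if len(set(cat.words)) != len(cat.words):
                raise ValueError(
                    f"duplicate word within category {cat.category_id}"
                )

    def __len__(self) -> int:
        return len(self.categories)

    @property
    def n_words(self) -> int:
        return sum(len(c.words) for c in self.categories)


@dataclass(frozen=True)
class SilhouetteRecord:
    """Per-word silhouette: s = (b - a) / max(a, b).

    ``a`` is the mean cosine distance to the other words of the word's own
    category; ``b`` the minimum over other categories of the mean distance
    to that category's words; ``neighbor_category_id`` the argmin category.
    """

    word: str
    category_id: int
    a: float
    b: float
    s: float
    neighbor_category_id: int


@dataclass(frozen=True)
class AnalogyItem:
    """One a - b + c = expected query with a top-k cutoff."""

    a: str
    b: str
    c: str
    expected: str
    k: int = 5


@dataclass(frozen=True)
class AnalogyResult:
    item: AnalogyItem
    testable: bool
    hit: bool
    rank: int | None
    distance: float | None


def parse_norms(path) -> CategoryNorms:
    """Read a norms TSV (category_id, category_label, word, rank).

    A header row is detected and skipped.  Categories come back ordered by
    id, words by rank.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, dtype=str, skip_blank_lines=True
        )
    except pd.errors.EmptyDataError:
        raise ValueError("empty norms file") from None
    if df.empty:
        raise ValueError("empty norms file")
    if df.shape[1] < 4:
        raise ValueError("norms file needs 4 columns: id, label, word, rank")
    if not str(df.iloc[0, 0]).strip().lstrip("-").isdigit():
        df = df.iloc[1:]
    if df.empty:
        raise ValueError("norms file has a header but no rows")
    df = df.iloc[:, :4].copy()
    df.columns = ["category_id", "category_label", "word", "rank"]
    df["category_id"] = df["category_id"].astype(int)
    df["rank"] = df["rank"].astype(int)

    categories = []
    for cid, grp in df.groupby("category_id", sort=True):
        grp = grp.sort_values("rank")
        words = tuple(w.strip() for w in grp["word"])
        categories.append(
            Category(category_id=int(cid), label=grp["category_label"].iloc[0],
                     words=words)
        )
    return CategoryNorms(categories=categories)


def write_norms(norms: CategoryNorms, path) -> None:
    """Write a norms table in the 4-column TSV layout parse_norms reads."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("category_id\tcategory_label\tword\trank\n")
        for cat in norms.categories:
            for rank, word in enumerate(cat.words, start=1):
                fh.write(f"{cat.category_id}\t{cat.label}\t{word}\t{rank}\n")


def silhouette_score(a: float, b: float) -> float:
    """s = (b - a) / max(a, b); defined as 0 when both distances vanish."""
    m = max(a, b)
    if m == 0.0:
        return 0.0
    return (b - a) / m


def silhouette_test(
    model: EmbeddingModel,
    norms: CategoryNorms,
    oov_policy: str = "skip",
    dedupe_norms: bool = False,
) -> tuple[list[SilhouetteRecord], dict]:
    """Silhouette coefficient of every in-vocabulary norm word.

    For word i of category C, ``a`` averages d(i, j) over the other
    in-vocabulary words j of C, and ``b`` is the minimum over other
    categories C' of the mean d(i, j) over C' members.  When word i itself
    also occurs in C', that occurrence contributes distance 0 to the C'
    mean — the norms are taken at face value.  ``dedupe_norms=True``
    removes such self occurrences from the competing means instead.

    Returns the records plus a coverage report: out-of-vocabulary words
    skipped (``oov_policy="skip"``, the default) and categories left with
    fewer than 2 usable words, whose members are reported as untestable
    rather than silently dropped.
    """
    if oov_policy not in ("skip", "error"):
        raise ValueError("oov_policy must be 'skip' or 'error'")

    oov = [
        (cat.category_id, w)
        for cat in norms.categories
        for w in cat.words
        if w not in model
    ]
    if oov and oov_policy == "error":
        missing = ", ".join(w for _, w in oov)
        raise ValueError(f"norm words missing from vocabulary: {missing}")

    usable = {
        cat.category_id: [w for w in cat.words if w in model]
        for cat in norms.categories
    }
    untestable = [cid for cid, ws in usable.items() if len(ws) < 2]
    evaluable = [c for c in norms.categories if len(usable[c.category_id]) >= 2]
    if len(evaluable) < 2:
        raise ValueError("need at least 2 categories with >= 2 usable words")

    # one distance matrix over the distinct in-vocabulary norm words
    vocab_words = sorted({w for ws in usable.values() for w in ws})
    widx = {w: i for i, w in enumerate(vocab_words)}
    unit = np.stack(
        [model.vector(w) / np.linalg.norm(model.vector(w)) for w in vocab_words]
    )
    dmat = 1.0 - unit @ unit.T

    records: list[SilhouetteRecord] = []
    for cat in evaluable:
        own = usable[cat.category_id]
        for w in own:
            wi = widx[w]
            others = [widx[o] for o in own if o != w]
            a = float(np.mean(dmat[wi, others]))

            b = np.inf
            neighbor = -1
            for other in norms.categories:
                if other.category_id == cat.category_id:
                    continue
                members = usable[other.category_id]
                if dedupe_norms:
                    members = [m for m in members if m != w]
                if not members:
                    continue
                mean_d = float(np.mean(dmat[wi, [widx[m] for m in members]]))
                if mean_d < b:  # ties: first (lowest) category id wins
                    b = mean_d
                    neighbor = other.category_id
            if not np.isfinite(b):
                continue
            records.append(
                SilhouetteRecord(
                    word=w,
                    category_id=cat.category_id,
                    a=a,
                    b=b,
                    s=silhouette_score(a, b),
                    neighbor_category_id=neighbor,
                )
            )

    coverage = {
        "oov_words": oov,
        "untestable_categories": untestable,
        "n_evaluated": len(records),
        "n_norm_words": norms.n_words,
    }
    if oov:
        logger.info("silhouette test skipped %d out-of-vocabulary words", len(oov))
    return records, coverage


def silhouette_summary(
    records: list[SilhouetteRecord], worst_n: int = 10
) -> dict:
    """Per-category mean silhouette, global mean, and worst-word table.

    The worst-word table carries the neighbor-category attribution that
    explains each miscategorization (the diamond-vs-vegetable style
    diagnostic).
    """
    if not records:
        raise ValueError("no silhouette records to summarize")
    df = pd.DataFrame(
        {
            "word": [r.word for r in records],
            "category_id": [r.category_id for r in records],
            "a": [r.a for r in records],
            "b": [r.b for r in records],
            "s": [r.s for r in records],
            "neighbor_category_id": [r.neighbor_category_id for r in records],
        }
    )
    per_category = (
        df.groupby("category_id")["s"].mean().rename("mean_s").reset_index()
    )
    worst = df.nsmallest(worst_n, "s").reset_index(drop=True)
    return {
        "per_category": per_category,
        "global_mean": float(df["s"].mean()),
        "worst_words": worst,
    }


def write_silhouette_report(
    records: list[SilhouetteRecord], coverage: dict, path
) -> None:
    """One record per row as TSV, with a summary footer block."""
    summary = silhouette_summary(records)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("word\tcategory_id\ta\tb\ts\tneighbor_category_id\n")
        for r in records:
            fh.write(
                f"{r.word}\t{r.category_id}\t{r.a:.6f}\t{r.b:.6f}"
                f"\t{r.s:.6f}\t{r.neighbor_category_id}\n"
            )
        fh.write(f"# global_mean_s\t{summary['global_mean']:.6f}\n")
        fh.write(f"# evaluated\t{coverage['n_evaluated']}\n")
        fh.write(f"# oov_skipped\t{len(coverage['oov_words'])}\n")


def parse_analogy_items(path, k: int = 5) -> list[AnalogyItem]:
    """Read 4-column whitespace-separated analogy items (a b c expected).

    Lines starting with ``:`` (section headers in the classic
    questions-words layout) or ``#`` are skipped.
    """
    items = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith((":", "#")):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"analogy line needs 4 words: {line!r}")
            items.append(AnalogyItem(*parts, k=k))
    return items


def analogy_test(
    model: EmbeddingModel, items: list[AnalogyItem]
) -> tuple[list[AnalogyResult], float]:
    """Run v(a) - v(b) + v(c) queries and score top-k hits.

    The three query words are excluded from the candidate set.  Items with
    any out-of-vocabulary word are reported untestable and excluded from
    the aggregate denominator.  The reported distance is d(query,
    v(expected)) whether or not the item hit.
    """
    results = []
    n_hit = 0
    n_testable = 0
    for item in items:
        if any(w not in model for w in (item.a, item.b, item.c, item.expected)):
            results.append(
                AnalogyResult(item=item, testable=False, hit=False, rank=None,
                              distance=None)
            )
            continue
        query = vector_expression(model, plus=[item.a, item.c], minus=[item.b])
        exclude = {item.a, item.b, item.c}
        top = nearest_terms(model, query, k=item.k, exclude=exclude)
        rank = None
        for i, (w, _) in enumerate(top, start=1):
            if w == item.expected:
                rank = i
                break
        qn = np.linalg.norm(query)
        expected_v = model.vector(item.expected)
        dist = 1.0 - float(
            np.dot(query, expected_v) / (qn * np.linalg.norm(expected_v))
        )
        hit = rank is not None
        n_testable += 1
        n_hit += int(hit)
        results.append(
            AnalogyResult(item=item, testable=True, hit=hit, rank=rank,
                          distance=dist)
        )
    hit_rate = n_hit / n_testable if n_testable else float("nan")
    return results, hit_rate
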