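"""Independent brute-force oracles, deliberately naive.

These reimplement the quantities under test with plain double loops and
``math`` so that agreement with the vectorized implementations is
meaningful.  Keep them free of any import from the package's computational
paths (only data containers are shared).
"""

from __future__ import annotations

import math


def cosine_distance_naive(u, v) -> float:
    dot = sum(a * b for a, b in zip(u, v))
    nu = math.sqrt(sum(a * a for a in u))
    nv = math.sqrt(sum(b * b for b in v))
    return 1.0 - dot / (nu * nv)


def silhouette_naive(
    vectors: dict[str, list[float]],
    categories: list[tuple[int, list[str]]],
    dedupe: bool = False,
) -> list[dict]:
    """Per-word a, b, s and neighbor category by exhaustive double loop.

    ``categories`` is a list of (category_id, word list); words missing
    from ``vectors`` are skipped; categories with < 2 usable words yield no
    records.  When a word also occurs in a competing category its own
    occurrence contributes distance 0 there (unless ``dedupe``).
    """
    usable = [
        (cid, [w for w in words if w in vectors]) for cid, words in categories
    ]
    records = []
    for cid, words in usable:
        if len(words) < 2:
            continue
        for w in words:
            a_dists = [
                cosine_distance_naive(vectors[w], vectors[o])
                for o in words
                if o != w
            ]
            a = sum(a_dists) / len(a_dists)
            b = None
            neighbor = None
            for cid2, words2 in usable:
                if cid2 == cid:
                    continue
                members = [m for m in words2 if not (dedupe and m == w)]
                if not members:
                    continue
                ds = [cosine_distance_naive(vectors[w], vectors[m]) for m in members]
                mean_d = sum(ds) / len(ds)
                if b is None or mean_d < b:
                    b = mean_d
                    neighbor = cid2
            if b is None:
                continue
            m = max(a, b)
            s = 0.0 if m == 0.0 else (b - a) / m
            records.append(
                {"word": w, "category_id": cid, "a": a, "b": b, "s": s,
                 "neighbor": neighbor}
            )
    return records


def nearest_naive(
    words: list[str], vectors, query, k: int, exclude=frozenset()
) -> list[tuple[str, float]]:
    """Exhaustive nearest-neighbor sort with vocabulary-order tie-break."""
    scored = [
        (cosine_distance_naive(query, vectors[i]), i)
        for i, w in enumerate(words)
        if w not in exclude
    ]
    scored.sort(key=lambda t: (t[0], t[1]))
    return [(words[i], d) for d, i in scored[:k]]
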