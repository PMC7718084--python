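"""Nearest-term discovery over a configured tree of ICF subcategories.

The WHO ICF's environmental factors (chapters e1-e5: products/technology,
natural environment, support/relationships, attitudes, services/systems/
policies) are coded subcategories such as ``e1100 food``.  Each configured
subcategory carries a seed-term algebraic expression (e.g. food +
cholesterol); running the map evaluates every expression against a trained
embedding and reports the nearest vocabulary terms with their cosine
distances.  The map is data, not code — editing the YAML retargets the same
machinery at any other ICF component.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import yaml

from .training import EmbeddingModel, nearest_terms, vector_expression

_CODE_RE = re.compile(r"^[a-z]\d+$")


@dataclass(frozen=True)
class ConceptQuery:
    """One ICF subcategory with its seed-term expression."""

    code: str
    label: str
    plus: tuple[str, ...]
    minus: tuple[str, ...] = ()
    k: int = 6

    def __post_init__(self) -> None:
        if not self.plus:
            raise ValueError(f"query {self.code}: empty plus list")
        if not _CODE_RE.match(self.code):
            raise ValueError(f"invalid ICF code: {self.code!r}")


@dataclass(frozen=True)
class Chapter:
    code: str
    label: str
    queries: tuple[ConceptQuery, ...]


@dataclass
class ConceptMap:
    chapters: list[Chapter]

    def __post_init__(self) -> None:
        codes = [q.code for ch in self.chapters for q in ch.queries]
        dupes = {c for c in codes if codes.count(c) > 1}
        if dupes:
            raise ValueError(f"duplicate ICF codes in map: {sorted(dupes)}")

    @property
    def queries(self) -> list[ConceptQuery]:
        return [q for ch in self.chapters for q in ch.queries]


@dataclass(frozen=True)
class ConceptEntry:
    """Report row for one query: results, or a skip record naming OOV seeds."""

    query: ConceptQuery
    results: tuple[tuple[str, float], ...]
    skipped: bool = False
    missing: tuple[str, ...] = ()


@dataclass
class ConceptReport:
    entries: list[ConceptEntry] = field(default_factory=list)


def _parse_query(code: str, spec: dict) -> ConceptQuery:
    return ConceptQuery(
        code=code,
        label=str(spec.get("label", "")),
        plus=tuple(spec.get("plus", [])),
        minus=tuple(spec.get("minus", []) or []),
        k=int(spec.get("k", 6)),
    )


def load_concept_map(path=None) -> ConceptMap:
    """Load a concept map; with no path, the packaged e1-e5 default.

    Config layout::

        chapters:
          - code: e1
            label: products and technology
            queries:
              - {code: e1100, label: food, plus: [food, cholesterol], k: 6}
    """
    if path is None:
        ref = resources.files("icfvec.data").joinpath(
            "icf_environmental_factors.yaml"
        )
        raw = yaml.safe_load(ref.read_text(encoding="utf-8"))
    else:
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    if not raw or "chapters" not in raw:
        raise ValueError("concept map config needs a top-level 'chapters' list")
    chapters = []
    for ch in raw["chapters"]:
        queries = tuple(
            _parse_query(str(q["code"]), q) for q in ch.get("queries", [])
        )
        chapters.append(
            Chapter(code=str(ch["code"]), label=str(ch.get("label", "")),
                    queries=queries)
        )
    return ConceptMap(chapters=chapters)


def save_concept_map(cmap: ConceptMap, path) -> None:
    raw = {
        "chapters": [
            {
                "code": ch.code,
                "label": ch.label,
                "queries": [
                    {
                        "code": q.code,
                        "label": q.label,
                        "plus": list(q.plus),
                        "minus": list(q.minus),
                        "k": q.k,
                    }
                    for q in ch.queries
                ],
            }
            for ch in cmap.chapters
        ]
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False, allow_unicode=True)


def run_concept_map(model: EmbeddingModel, cmap: ConceptMap) -> ConceptReport:
    """Evaluate every configured seed expression against the model.

    A query with any out-of-vocabulary seed word becomes a skip entry
    naming the missing words; the run continues.  Seed words are excluded
    from each query's own results.
    """
    report = ConceptReport()
    for query in cmap.queries:
        missing = tuple(
            w for w in (*query.plus, *query.minus) if w not in model
        )
        if missing:
            report.entries.append(
                ConceptEntry(query=query, results=(), skipped=True,
                             missing=missing)
            )
            continue
        vec = vector_expression(model, list(query.plus), list(query.minus))
        hits = nearest_terms(
            model, vec, k=query.k, exclude=set(query.plus) | set(query.minus)
        )
        report.entries.append(ConceptEntry(query=query, results=tuple(hits)))
    return report


def neighborhood(
    model: EmbeddingModel, word: str, k: int = 10
) -> list[tuple[str, float]]:
    """Nearest terms around a single word, the word itself excluded.

    This is the use-case query: e.g. the terms a model trained on a
    disability community's comments places around "resilience".
    """
    vec = model.vector(word)  # raises KeyError naming the word if OOV
    return nearest_terms(model, vec, k=k, exclude={word})


def report_to_tsv(report: ConceptReport, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("code\tlabel\texpression\tstatus\tresults\n")
        for e in report.entries:
            expr = "+".join(e.query.plus)
            if e.query.minus:
                expr += "-" + "-".join(e.query.minus)
            if e.skipped:
                fh.write(
                    f"{e.query.code}\t{e.query.label}\t{expr}\tskipped"
                    f"\tmissing: {', '.join(e.missing)}\n"
                )
            else:
                cells = ", ".join(f"{w} ({d:.3f})" for w, d in e.results)
                fh.write(f"{e.query.code}\t{e.query.label}\t{expr}\tok\t{cells}\n")


def report_to_markdown(report: ConceptReport) -> str:
    """Markdown table mirroring the code / expression / closest-terms layout."""
    lines = [
        "| Code | Label | Expression | Closest terms (cosine distance) |",
        "| --- | --- | --- | --- |",
    ]
    for e in report.entries:
        expr = "+".join(e.query.plus)
        if e.query.minus:
            expr += "-" + "-".join(e.query.minus)
        if e.skipped:
            cells = f"*skipped — missing: {', '.join(e.missing)}*"
        else:
            cells = ", ".join(f"{w} ({d:.3f})" for w, d in e.results)
        lines.append(f"| {e.query.code} | {e.query.label} | {expr} | {cells} |")
    return "\n".join(lines) + "\n"
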