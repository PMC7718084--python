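"""Reading, cleaning and tokenizing pushshift-style comment dumps.

The input format is JSON-lines as distributed by pushshift.io: one JSON
object per line with at least a ``body`` field (``author``, ``created_utc``
and ``id`` are used when present, unknown fields are ignored).  Deleted and
removed comment bodies are dropped before anything downstream sees them.
"""

from __future__ import annotations

import json
import logging
import re
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

_URL_RE = re.compile(r"(?:https?://|www\.)\S+", re.IGNORECASE)
_TOKEN_RE = re.compile(r"[a-z0-9']+")

#: bodies that pushshift stores for comments scrubbed on Reddit's side
_TOMBSTONES = frozenset({"", "[deleted]", "[removed]"})


@dataclass(frozen=True)
class Comment:
    """One Reddit comment as stored in a pushshift dump."""

    body: str
    author: str = "[unknown]"
    created_utc: int = 0
    id: str = ""

    def __post_init__(self) -> None:
        if self.body is None:
            raise ValueError("Comment body must not be None")
        if self.created_utc < 0:
            raise ValueError("created_utc must be >= 0")


@dataclass
class TokenizedCorpus:
    """An ordered collection of token sequences plus vocabulary counts."""

    documents: list[list[str]]
    vocabulary: dict[str, int] = field(default_factory=dict)

    @property
    def total_tokens(self) -> int:
        return sum(self.vocabulary.values())

    def __len__(self) -> int:
        return len(self.documents)


def tokenize(text: str) -> list[str]:
    """Split raw comment text into lowercase tokens.

    URLs are removed first; anything outside ``[a-z0-9']`` then acts as a
    separator.  Alphanumeric blends such as ``8am`` survive as single
    tokens, which matters for time-of-day vocabulary ("breakfast at 8am").
    """
    text = _URL_RE.sub(" ", text.lower())
    return _TOKEN_RE.findall(text)


def read_comments(path, min_length: int = 1, strict: bool = True) -> list[Comment]:
    """Read a pushshift-style JSONL dump into a list of :class:`Comment`.

    Lines whose body is empty, ``[deleted]`` or ``[removed]`` are dropped,
    as are comments whose body tokenizes to fewer than ``min_length``
    tokens.  In strict mode (the default) a malformed JSON line raises a
    :class:`ValueError` naming the line number; in lenient mode it is
    skipped with a warning.
    """
    comments: list[Comment] = []
    n_dropped = 0
    n_bad = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                if strict:
                    raise ValueError(f"malformed JSON on line {lineno}: {exc}") from exc
                logger.warning("skipping malformed JSON on line %d", lineno)
                n_bad += 1
                continue
            body = obj.get("body")
            if body is None or body.strip() in _TOMBSTONES:
                n_dropped += 1
                continue
            if len(tokenize(body)) < min_length:
                n_dropped += 1
                continue
            comments.append(
                Comment(
                    body=body,
                    author=obj.get("author", "[unknown]"),
                    created_utc=int(obj.get("created_utc", 0)),
                    id=obj.get("id", ""),
                )
            )
    if n_dropped or n_bad:
        logger.info("dropped %d tombstone/short lines, %d malformed", n_dropped, n_bad)
    if not comments:
        logger.warning("no usable comments read from %s", path)
    return comments


def build_corpus(comments: list[Comment], min_count: int = 5) -> TokenizedCorpus:
    """Tokenize comments and remove words rarer than ``min_count``.

    Document order is preserved; words below the count threshold are
    removed both from documents and from the vocabulary (the standard
    word2vec preprocessing step).
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    raw_docs = [tokenize(c.body) for c in comments]
    counts = Counter(tok for doc in raw_docs for tok in doc)
    vocab = {w: n for w, n in counts.items() if n >= min_count}
    documents = [[tok for tok in doc if tok in vocab] for doc in raw_docs]
    if not any(documents):
        raise ValueError("empty corpus: no document survives min_count filtering")
    return TokenizedCorpus(documents=documents, vocabulary=vocab)


def frequency_report(
    corpus: TokenizedCorpus,
    comments: list[Comment],
    words: list[str] | None = None,
    k: int = 10,
) -> tuple[list[tuple[str, int]], pd.DataFrame]:
    """Descriptive corpus statistics.

    Returns the top-``k`` words by raw count and, for each requested word,
    the percentage of each calendar year's comments that contain it.
    Words absent from the vocabulary get zero rows rather than an error.
    """
    top = sorted(corpus.vocabulary.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
    if not words:
        return top, pd.DataFrame(columns=["word", "year", "percent"])

    years = pd.to_datetime(
        [c.created_utc for c in comments], unit="s", utc=True
    ).year.to_numpy()
    doc_sets = [set(tokenize(c.body)) for c in comments]
    rows = []
    for word in words:
        for year in sorted(set(years)):
            mask = years == year
            n_year = int(mask.sum())
            n_hit = sum(1 for ds, m in zip(doc_sets, mask) if m and word in ds)
            rows.append(
                {"word": word, "year": int(year), "percent": 100.0 * n_hit / n_year}
            )
    return top, pd.DataFrame(rows)


def write_corpus(corpus: TokenizedCorpus, path) -> None:
    """Write a plain-text one-document-per-line corpus file (UTF-8)."""
    with open(path, "w", encoding="utf-8") as fh:
        for doc in corpus.documents:
            fh.write(" ".join(doc) + "\n")


def read_corpus_file(path) -> TokenizedCorpus:
    """Read a one-document-per-line space-separated corpus file."""
    documents = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            documents.append(line.split())
    counts = Counter(tok for doc in documents for tok in doc)
    return TokenizedCorpus(documents=documents, vocabulary=dict(counts))


def pushshift_query_url(
    subreddit: str, after: int, before: int, size: int = 500
) -> str:
    """Shape of a pushshift.io comment query for a subreddit time slice.

    Documented stub only: this package never performs network requests.
    Users who want to refresh a corpus can page through
    ``created_utc`` windows with this URL and save the ``data`` arrays as
    JSON-lines, which :func:`read_comments` then ingests.
    """
    return (
        "https://api.pushshift.io/reddit/search/comment/"
        f"?subreddit={subreddit}&after={after}&before={before}"
        f"&size={size}&sort=asc&sort_type=created_utc"
    )
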