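"""Skip-gram word2vec training and cosine-geometry queries.

The trainer follows the original C implementation of word2vec: stochastic
gradient descent over (center, context) pairs from a sliding window, with
hierarchical softmax over a Huffman-coded vocabulary when
``negative_samples=0`` (the original tool's behavior when negative sampling
is off) and negative sampling otherwise.  The dynamic window, the linear
learning-rate decay and the linear-congruential RNG all mirror the C tool,
so single-threaded runs with a fixed seed are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .corpus import TokenizedCorpus

MAX_CODE_LENGTH = 64


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of a skip-gram training run.

    ``negative_samples=0`` selects hierarchical softmax.  ``window`` is the
    maximum context radius; by default the effective radius of each center
    word is drawn uniformly from ``[1, window]`` as in the original
    implementation (set ``dynamic_window=False`` for a fixed radius).
    ``sample`` is the frequent-word subsampling threshold (0 disables it;
    the original tool's default is 1e-3).  ``threads`` is accepted for
    interface completeness but training is single-threaded: lock-free
    multithreaded SGD is not reproducible, and the corpora this package
    targets are small.
    """

    dim: int = 200
    window: int = 12
    epochs: int = 5
    negative_samples: int = 0
    learning_rate: float = 0.025
    threads: int = 1
    seed: int = 1
    min_count: int = 5
    sample: float = 0.0
    dynamic_window: bool = True

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.negative_samples < 0:
            raise ValueError("negative_samples must be >= 0")


@dataclass
class EmbeddingModel:
    """A trained embedding: ordered vocabulary and a |V| x dim matrix."""

    words: list[str]
    vectors: np.ndarray
    config: TrainingConfig | None = None
    epoch_losses: list[float] = field(default_factory=list)
    _index: dict[str, int] = field(default_factory=dict, repr=False)
    _unit: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if len(self.words) != len(set(self.words)):
            raise ValueError("duplicate words in vocabulary")
        if self.vectors.shape[0] != len(self.words):
            raise ValueError("vocabulary/matrix row count mismatch")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("non-finite vector entries")
        self._index = {w: i for i, w in enumerate(self.words)}

    def __contains__(self, word: str) -> bool:
        return word in self._index

    def __len__(self) -> int:
        return len(self.words)

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def vector(self, word: str) -> np.ndarray:
        try:
            return self.vectors[self._index[word]]
        except KeyError:
            raise KeyError(f"word not in vocabulary: {word!r}") from None

    def unit_vectors(self) -> np.ndarray:
        """Row-normalized copy of the matrix, cached for neighbor queries."""
        if self._unit is None:
            norms = np.linalg.norm(self.vectors, axis=1, keepdims=True)
            norms[norms == 0] = 1.0
            self._unit = self.vectors / norms
        return self._unit


# ---------------------------------------------------------------------------
# cosine geometry


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """S(u, v) = <u, v> / (|u| |v|), in [-1, 1]."""
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(u, v) / (nu * nv))


def cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    """The semantic distance d(u, v) = 1 - S(u, v), in [0, 2]."""
    return 1.0 - cosine_similarity(u, v)


def vector_expression(
    model: EmbeddingModel,
    plus: list[str],
    minus: list[str] | None = None,
) -> np.ndarray:
    """Evaluate sum(v(plus)) - sum(v(minus)).

    The sum is not renormalized; cosine queries normalize anyway.  A word
    missing from the vocabulary raises a :class:`KeyError` naming it.
    """
    minus = minus or []
    out = np.zeros(model.dim, dtype=np.float64)
    for w in plus:
        out += model.vector(w)
    for w in minus:
        out -= model.vector(w)
    return out


def nearest_terms(
    model: EmbeddingModel,
    query: np.ndarray,
    k: int,
    exclude: frozenset[str] | set[str] = frozenset(),
) -> list[tuple[str, float]]:
    """The k vocabulary words nearest to ``query`` by cosine distance.

    Results come back ascending by distance; exact ties break by
    vocabulary order.  Words in ``exclude`` are never returned.  A ``k``
    larger than the eligible vocabulary returns all eligible words.
    """
    if k <= 0:
        return []
    qn = np.linalg.norm(query)
    if qn == 0.0:
        raise ValueError("cosine distance undefined for a zero query vector")
    dist = 1.0 - model.unit_vectors() @ (np.asarray(query, dtype=np.float64) / qn)
    order = np.argsort(dist, kind="stable")
    out: list[tuple[str, float]] = []
    for idx in order:
        w = model.words[idx]
        if w in exclude:
            continue
        out.append((w, float(dist[idx])))
        if len(out) == k:
            break
    return out


# ---------------------------------------------------------------------------
# Huffman coding for hierarchical softmax


def _build_huffman(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Huffman codes and inner-node paths for each vocabulary word.

    Returns (codes, points, code_lengths); codes/points are |V| x
    MAX_CODE_LENGTH int32 arrays padded with -1.  Tie-breaking follows the
    original implementation's two-pointer merge over count-sorted leaves,
    so the tree (and hence training) is deterministic.
    """
    vocab_size = len(counts)
    order = np.argsort(-counts, kind="stable")
    sorted_counts = counts[order]

    count = np.empty(2 * vocab_size, dtype=np.int64)
    count[:vocab_size] = sorted_counts
    count[vocab_size:] = np.iinfo(np.int64).max
    binary = np.zeros(2 * vocab_size, dtype=np.int32)
    parent = np.zeros(2 * vocab_size, dtype=np.int32)

    pos1 = vocab_size - 1
    pos2 = vocab_size
    for a in range(vocab_size - 1):
        mins = []
        for _ in range(2):
            if pos1 >= 0 and count[pos1] < count[pos2]:
                mins.append(pos1)
                pos1 -= 1
            else:
                mins.append(pos2)
                pos2 += 1
        m1, m2 = mins
        count[vocab_size + a] = count[m1] + count[m2]
        parent[m1] = vocab_size + a
        parent[m2] = vocab_size + a
        binary[m2] = 1

    codes = np.full((vocab_size, MAX_CODE_LENGTH), -1, dtype=np.int32)
    points = np.full((vocab_size, MAX_CODE_LENGTH), -1, dtype=np.int32)
    lengths = np.zeros(vocab_size, dtype=np.int32)
    root = 2 * vocab_size - 2
    for a in range(vocab_size):
        code: list[int] = []
        point: list[int] = []
        b = a
        while b != root:
            code.append(int(binary[b]))
            b = int(parent[b])
            point.append(b - vocab_size)
        n = len(code)
        if n > MAX_CODE_LENGTH:
            raise ValueError("Huffman code longer than MAX_CODE_LENGTH")
        w = int(order[a])
        lengths[w] = n
        # root-to-leaf order, as consumed by the SGD kernel
        for i in range(n):
            codes[w, i] = code[n - 1 - i]
            points[w, i] = point[n - 1 - i]
    return codes, points, lengths


def _build_unigram_table(counts: np.ndarray, size: int = 1_000_000) -> np.ndarray:
    """Negative-sampling table: word frequency raised to the 3/4 power."""
    probs = counts.astype(np.float64) ** 0.75
    probs /= probs.sum()
    table = np.zeros(size, dtype=np.int32)
    cum = 0.0
    w = 0
    p = probs[0]
    for i in range(size):
        table[i] = w
        if (i + 1) / size > cum + p:
            cum += p
            if w < len(counts) - 1:
                w += 1
                p = probs[w]
    return table


# ---------------------------------------------------------------------------
# SGD kernel (single-threaded, bit-reproducible)


@njit(cache=True)
def _lcg(state: np.uint64) -> np.uint64:
    return state * np.uint64(25214903917) + np.uint64(11)


@njit(cache=True)
def _sgd_epoch(
    tokens: np.ndarray,
    offsets: np.ndarray,
    syn0: np.ndarray,
    syn1: np.ndarray,
    codes: np.ndarray,
    points: np.ndarray,
    code_lengths: np.ndarray,
    neg_table: np.ndarray,
    negative: int,
    window: int,
    dynamic_window: bool,
    alpha_start: float,
    alpha_min: float,
    words_done_start: int,
    total_words: int,
    keep_prob: np.ndarray,
    rng_state: np.uint64,
) -> tuple[float, int, np.uint64]:
    """One pass over the corpus; returns (mean pair loss, pairs, rng state)."""
    dim = syn0.shape[1]
    neu1e = np.zeros(dim, dtype=np.float32)
    loss = 0.0
    n_pairs = 0
    words_done = words_done_start

    for d in range(len(offsets) - 1):
        start, end = offsets[d], offsets[d + 1]
        # frequent-word subsampling (keep_prob is all ones when disabled)
        sent = np.empty(end - start, dtype=np.int32)
        slen = 0
        for t in range(start, end):
            w = tokens[t]
            if keep_prob[w] >= 1.0:
                sent[slen] = w
                slen += 1
            else:
                rng_state = _lcg(rng_state)
                r = ((rng_state >> np.uint64(16)) & np.uint64(0xFFFF)) / 65536.0
                if r < keep_prob[w]:
                    sent[slen] = w
                    slen += 1

        for pos in range(slen):
            center = sent[pos]
            words_done += 1
            alpha = alpha_start * (1.0 - words_done / (total_words + 1.0))
            if alpha < alpha_min:
                alpha = alpha_min

            if dynamic_window:
                rng_state = _lcg(rng_state)
                shrink = int(rng_state % np.uint64(window))
            else:
                shrink = 0
            b = window - shrink  # effective radius in [1, window]

            for off in range(-b, b + 1):
                if off == 0:
                    continue
                cpos = pos + off
                if cpos < 0 or cpos >= slen:
                    continue
                context = sent[cpos]
                # skip-gram: predict context from center; the input vector
                # updated is the center word's, per the C implementation
                v = syn0[center]
                for i in range(dim):
                    neu1e[i] = 0.0

                if negative == 0:
                    # hierarchical softmax along context's Huffman path
                    for s in range(code_lengths[context]):
                        node = points[context, s]
                        code = codes[context, s]
                        f = 0.0
                        for i in range(dim):
                            f += v[i] * syn1[node, i]
                        if f > 30.0:
                            p = 1.0
                        elif f < -30.0:
                            p = 0.0
                        else:
                            p = 1.0 / (1.0 + np.exp(-f))
                        # label: 1 - code (code 0 -> positive branch)
                        g = (1.0 - code - p) * alpha
                        target_p = p if code == 0 else 1.0 - p
                        if target_p < 1e-10:
                            target_p = 1e-10
                        loss -= np.log(target_p)
                        for i in range(dim):
                            neu1e[i] += g * syn1[node, i]
                        for i in range(dim):
                            syn1[node, i] += g * v[i]
                else:
                    # negative sampling: 1 positive + `negative` draws
                    for s in range(negative + 1):
                        if s == 0:
                            target = context
                            label = 1.0
                        else:
                            rng_state = _lcg(rng_state)
                            target = neg_table[
                                int(
                                    (rng_state >> np.uint64(16))
                                    % np.uint64(len(neg_table))
                                )
                            ]
                            if target == context:
                                continue
                            label = 0.0
                        f = 0.0
                        for i in range(dim):
                            f += v[i] * syn1[target, i]
                        if f > 30.0:
                            p = 1.0
                        elif f < -30.0:
                            p = 0.0
                        else:
                            p = 1.0 / (1.0 + np.exp(-f))
                        g = (label - p) * alpha
                        target_p = p if label == 1.0 else 1.0 - p
                        if target_p < 1e-10:
                            target_p = 1e-10
                        loss -= np.log(target_p)
                        for i in range(dim):
                            neu1e[i] += g * syn1[target, i]
                        for i in range(dim):
                            syn1[target, i] += g * v[i]

                n_pairs += 1
                for i in range(dim):
                    v[i] += neu1e[i]

    mean_loss = loss / n_pairs if n_pairs > 0 else 0.0
    return mean_loss, words_done, rng_state


def train_skipgram(
    corpus: TokenizedCorpus, config: TrainingConfig | None = None
) -> EmbeddingModel:
    """Fit skip-gram embeddings on a tokenized corpus.

    With ``threads=1`` (the only mode implemented) and a fixed seed the
    returned matrix is bit-identical across runs.  Per-epoch mean pair
    losses are recorded on the model for convergence diagnostics.
    """
    config = config or TrainingConfig()
    if not corpus.documents or not any(corpus.documents):
        raise ValueError("empty corpus")

    words = sorted(corpus.vocabulary, key=lambda w: (-corpus.vocabulary[w], w))
    if len(words) < 2:
        raise ValueError("vocabulary must contain at least 2 words")
    index = {w: i for i, w in enumerate(words)}
    counts = np.array([corpus.vocabulary[w] for w in words], dtype=np.int64)

    flat: list[int] = []
    offsets = [0]
    for doc in corpus.documents:
        flat.extend(index[t] for t in doc)
        offsets.append(len(flat))
    tokens = np.array(flat, dtype=np.int32)
    offsets_arr = np.array(offsets, dtype=np.int64)

    rng = np.random.RandomState(config.seed)
    syn0 = (
        (rng.random_sample((len(words), config.dim)) - 0.5) / config.dim
    ).astype(np.float32)

    if config.negative_samples == 0:
        codes, points, lengths = _build_huffman(counts)
        syn1 = np.zeros((len(words), config.dim), dtype=np.float32)
        neg_table = np.zeros(1, dtype=np.int32)
    else:
        codes = np.zeros((1, 1), dtype=np.int32)
        points = np.zeros((1, 1), dtype=np.int32)
        lengths = np.zeros(1, dtype=np.int32)
        syn1 = np.zeros((len(words), config.dim), dtype=np.float32)
        neg_table = _build_unigram_table(counts)

    n_tokens = len(tokens)
    if config.sample > 0:
        freq = counts / n_tokens
        keep = np.minimum(
            1.0, np.sqrt(config.sample / freq) + config.sample / freq
        ).astype(np.float64)
    else:
        keep = np.ones(len(words), dtype=np.float64)

    total_words = n_tokens * config.epochs
    alpha_min = config.learning_rate / 10_000.0
    rng_state = np.uint64(config.seed if config.seed > 0 else 1)

    losses: list[float] = []
    words_done = 0
    for _ in range(config.epochs):
        mean_loss, words_done, rng_state = _sgd_epoch(
            tokens,
            offsets_arr,
            syn0,
            syn1,
            codes,
            points,
            lengths,
            neg_table,
            config.negative_samples,
            config.window,
            config.dynamic_window,
            config.learning_rate,
            alpha_min,
            words_done,
            total_words,
            keep,
            rng_state,
        )
        rng_state = np.uint64(rng_state)  # numba hands back a Python int
        losses.append(float(mean_loss))

    return EmbeddingModel(
        words=words, vectors=syn0.astype(np.float64), config=config,
        epoch_losses=losses,
    )


# ---------------------------------------------------------------------------
# word2vec vector-file formats


def save_vectors(model: EmbeddingModel, path) -> None:
    """Write the model in word2vec text format ("|V| dim" header)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(model.words)} {model.dim}\n")
        for w, row in zip(model.words, model.vectors):
            fh.write(w + " " + " ".join(f"{x:.8f}" for x in row) + "\n")


def load_vectors(path) -> EmbeddingModel:
    """Load a word2vec text-format vector file."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError("malformed word2vec text header")
        n_words, dim = int(header[0]), int(header[1])
        words: list[str] = []
        rows = np.empty((n_words, dim), dtype=np.float64)
        for i in range(n_words):
            line = fh.readline()
            if not line:
                raise ValueError(
                    f"header declares {n_words} words but file has {i} rows"
                )
            parts = line.rstrip("\n").split(" ")
            if len(parts) != dim + 1:
                raise ValueError(f"row {i + 1}: expected {dim} values")
            words.append(parts[0])
            rows[i] = [float(x) for x in parts[1:]]
        if fh.readline().strip():
            raise ValueError("file has more rows than the header declares")
    return EmbeddingModel(words=words, vectors=rows)


def load_vectors_binary(path) -> EmbeddingModel:
    """Read the original word2vec binary format (little-endian float32)."""
    with open(path, "rb") as fh:
        header = fh.readline().split()
        n_words, dim = int(header[0]), int(header[1])
        words = []
        rows = np.empty((n_words, dim), dtype=np.float64)
        for i in range(n_words):
            chars = []
            while True:
                ch = fh.read(1)
                if ch == b" ":
                    break
                if ch == b"":
                    raise ValueError("unexpected end of binary vector file")
                if ch != b"\n":
                    chars.append(ch)
            words.append(b"".join(chars).decode("utf-8"))
            rows[i] = np.frombuffer(fh.read(4 * dim), dtype="<f4")
    return EmbeddingModel(words=words, vectors=rows)
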