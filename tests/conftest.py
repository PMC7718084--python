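"""Shared fixtures.

The expensive objects — skip-gram models trained on the default planted
designs over 5 seeds — are session-scoped and shared between the recovery
property tests and the acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import icfvec as iv

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")

RECOVERY_SEEDS = (0, 1, 2, 3, 4)

#: the training configuration used for all planted-structure recovery runs
RECOVERY_CONFIG = dict(dim=50, window=5, epochs=5)


def small_random_model(
    n_words: int, dim: int, seed: int, prefix: str = "w"
) -> iv.EmbeddingModel:
    """A toy model with Gaussian vectors — geometry only, no training."""
    rng = np.random.default_rng(seed)
    words = [f"{prefix}{i}" for i in range(n_words)]
    return iv.EmbeddingModel(words=words, vectors=rng.normal(size=(n_words, dim)))


@pytest.fixture(scope="session")
def category_runs(tmp_path_factory):
    """Default planted-category corpora trained over 5 seeds.

    Yields a list of (manifest, corpus, model) triples.
    """
    root = tmp_path_factory.mktemp("category_runs")
    runs = []
    for seed in RECOVERY_SEEDS:
        design = iv.PlantedDesign(seed=seed)
        path = root / f"cat{seed}.jsonl"
        manifest = iv.generate_category_corpus(design, path)
        corpus = iv.build_corpus(iv.read_comments(path), min_count=5)
        model = iv.train_skipgram(
            corpus, iv.TrainingConfig(seed=seed, **RECOVERY_CONFIG)
        )
        runs.append((manifest, corpus, model))
    return runs


@pytest.fixture(scope="session")
def analogy_runs(tmp_path_factory):
    """Default planted-relation corpora trained over 5 seeds.

    Yields a list of (manifest, items, model) triples.
    """
    root = tmp_path_factory.mktemp("analogy_runs")
    runs = []
    for seed in RECOVERY_SEEDS:
        design = iv.PlantedDesign(seed=seed)
        cpath = root / f"an{seed}.jsonl"
        ipath = root / f"an{seed}_items.txt"
        manifest = iv.generate_analogy_corpus(design, cpath, ipath)
        corpus = iv.build_corpus(iv.read_comments(cpath), min_count=5)
        model = iv.train_skipgram(
            corpus, iv.TrainingConfig(seed=seed, **RECOVERY_CONFIG)
        )
        items = iv.parse_analogy_items(ipath)
        runs.append((manifest, items, model))
    return runs


@pytest.fixture(scope="session")
def small_trained_model(tmp_path_factory):
    """One small trained model for tests that need real (non-toy) vectors."""
    root = tmp_path_factory.mktemp("small_model")
    design = iv.PlantedDesign(
        n_categories=5, n_documents=400, tokens_per_document=40,
        background_vocab=50, seed=123,
    )
    path = root / "small.jsonl"
    manifest = iv.generate_category_corpus(design, path)
    corpus = iv.build_corpus(iv.read_comments(path), min_count=5)
    model = iv.train_skipgram(
        corpus, iv.TrainingConfig(dim=30, window=5, epochs=3, seed=123)
    )
    return manifest, corpus, model


def permuted_norms(norms: iv.CategoryNorms, seed: int) -> iv.CategoryNorms:
    """Shuffle word membership across categories, preserving sizes."""
    from icfvec.evaluation import Category

    rng = np.random.default_rng(seed)
    words = [w for c in norms.categories for w in c.words]
    perm = list(rng.permutation(words))
    out = []
    k = 0
    for c in norms.categories:
        out.append(Category(c.category_id, c.label, tuple(perm[k:k + len(c.words)])))
        k += len(c.words)
    return iv.CategoryNorms(categories=out)
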