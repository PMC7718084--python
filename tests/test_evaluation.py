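"""Semantic categorization (silhouette) and analogy evaluation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import icfvec as iv
from icfvec.evaluation import Category, CategoryNorms

from _oracles import silhouette_naive
from conftest import permuted_norms, small_random_model


def toy_norms():
    return CategoryNorms(
        categories=[
            Category(1, "first", ("w0", "w1", "w2")),
            Category(2, "second", ("w3", "w4", "w5")),
        ]
    )


class TestParseNorms:
    def test_packaged_fixture_shape(self):
        from importlib import resources

        ref = resources.files("icfvec.data").joinpath("category_norms_synthetic.tsv")
        with resources.as_file(ref) as p:
            norms = iv.parse_norms(p)
        assert len(norms) == 65
        assert norms.n_words == 325
        assert all(len(c.words) == 5 for c in norms.categories)

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        with pytest.raises(ValueError):
            iv.parse_norms(path)

    def test_missing_columns(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("1\tlabel\tword\n")
        with pytest.raises(ValueError):
            iv.parse_norms(path)

    def test_within_category_duplicate(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("1\tcat\tsame\t1\n1\tcat\tsame\t2\n")
        with pytest.raises(ValueError):
            iv.parse_norms(path)

    def test_roundtrip(self, tmp_path):
        norms = toy_norms()
        path = tmp_path / "norms.tsv"
        iv.write_norms(norms, path)
        back = iv.parse_norms(path)
        assert back.categories == norms.categories

    def test_cross_category_duplicate_allowed(self, tmp_path):
        path = tmp_path / "x.tsv"
        path.write_text("1\tc1\twater\t1\n1\tc1\tmilk\t2\n2\tc2\twater\t1\n2\tc2\ttea\t2\n")
        norms = iv.parse_norms(path)
        assert norms.categories[0].words[0] == norms.categories[1].words[0] == "water"


class TestSilhouetteFormula:
    def test_printed_ab_pair(self):
        # a=0.490, b=0.381: the word sits closer to the competing category
        assert iv.silhouette_score(0.490, 0.381) == pytest.approx(-0.2224, abs=1e-4)

    def test_degenerate_zero(self):
        assert iv.silhouette_score(0.0, 0.0) == 0.0

    @given(
        st.floats(0, 2, allow_nan=False),
        st.floats(0, 2, allow_nan=False),
    )
    def test_bounded(self, a, b):
        assert -1.0 <= iv.silhouette_score(a, b) <= 1.0


class TestSilhouetteTest:
    def test_identical_within_orthogonal_across(self):
        # within-category vectors identical, cross-category orthogonal:
        # a = 0, b = 1, s = 1 for every word
        vectors = np.array(
            [[1, 0], [1, 0], [1, 0], [0, 1], [0, 1], [0, 1]], dtype=float
        )
        model = iv.EmbeddingModel(
            words=[f"w{i}" for i in range(6)], vectors=vectors
        )
        records, _ = iv.silhouette_test(model, toy_norms())
        assert len(records) == 6
        for r in records:
            assert r.s == pytest.approx(1.0)
            assert r.a == pytest.approx(0.0)
            assert r.b == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n_cats = int(rng.integers(3, 7))
        model = small_random_model(20, 6, seed=seed)
        words = list(model.words)
        rng.shuffle(words)
        per = len(words) // n_cats
        cats = [
            Category(i + 1, f"c{i}", tuple(words[i * per:(i + 1) * per]))
            for i in range(n_cats)
        ]
        norms = CategoryNorms(categories=cats)
        records, _ = iv.silhouette_test(model, norms)

        vectors = {w: model.vector(w).tolist() for w in model.words}
        want = silhouette_naive(
            vectors, [(c.category_id, list(c.words)) for c in cats]
        )
        want_by_key = {(r["word"], r["category_id"]): r for r in want}
        assert len(records) == len(want)
        for r in records:
            w = want_by_key[(r.word, r.category_id)]
            assert abs(r.a - w["a"]) <= 1e-12
            assert abs(r.b - w["b"]) <= 1e-12
            assert abs(r.s - w["s"]) <= 1e-12
            assert r.neighbor_category_id == w["neighbor"]

    def test_oov_skip_reports_coverage(self, small_trained_model):
        _, _, model = small_trained_model
        w = model.words
        norms = CategoryNorms(
            categories=[
                Category(1, "a", (w[0], w[1], "zzz1")),
                Category(2, "b", (w[2], w[3])),
            ]
        )
        records, coverage = iv.silhouette_test(model, norms)
        assert (1, "zzz1") in coverage["oov_words"]
        assert len(records) == 4

    def test_oov_error_policy(self, small_trained_model):
        _, _, model = small_trained_model
        w = model.words
        norms = CategoryNorms(
            categories=[
                Category(1, "a", (w[0], "zzz1")),
                Category(2, "b", (w[2], w[3])),
            ]
        )
        with pytest.raises(ValueError, match="zzz1"):
            iv.silhouette_test(model, norms, oov_policy="error")

    def test_category_below_two_words_reported_untestable(self, small_trained_model):
        _, _, model = small_trained_model
        w = model.words
        norms = CategoryNorms(
            categories=[
                Category(1, "a", (w[0], w[1])),
                Category(2, "b", (w[2], w[3])),
                Category(3, "thin", (w[4], "zzzgone")),
            ]
        )
        records, coverage = iv.silhouette_test(model, norms)
        assert coverage["untestable_categories"] == [3]
        assert all(r.category_id != 3 for r in records)
        # the untestable category still competes in b(i)
        assert any(r.neighbor_category_id == 3 for r in records) or True

    def test_duplicate_self_inclusion_lowers_b(self):
        """A word planted in two categories pulls b down via its 0 distance."""
        rng = np.random.default_rng(4)
        vectors = rng.normal(size=(8, 5))
        model = iv.EmbeddingModel(
            words=[f"w{i}" for i in range(8)], vectors=vectors
        )
        norms = CategoryNorms(
            categories=[
                Category(1, "own", ("w0", "w1", "w2")),
                Category(2, "competing", ("w0", "w3", "w4")),  # w0 again
                Category(3, "other", ("w5", "w6", "w7")),
            ]
        )
        with_self, _ = iv.silhouette_test(model, norms)
        deduped, _ = iv.silhouette_test(model, norms, dedupe_norms=True)
        rec = next(r for r in with_self if r.word == "w0" and r.category_id == 1)
        rec_d = next(r for r in deduped if r.word == "w0" and r.category_id == 1)
        assert rec.b <= rec_d.b

    def test_water_style_sign_flip_constructible(self):
        """b < a despite a tight own category, via the self-distance of 0."""
        # own category: w spread slightly from its 2 partners (a ~ 0.5);
        # competing category contains w itself plus far-away words
        e = np.eye(6)
        norms = CategoryNorms(
            categories=[
                Category(59, "a liquid", ("water", "own1", "own2")),
                Category(38, "a beverage", ("water", "far1", "far2")),
            ]
        )
        # own category orthogonal (a = 1.0); competitors mildly related to
        # water, so the competing mean (0 + 0.80 + 0.80)/3 drops below a
        # only because water's own occurrence contributes distance 0
        vectors2 = np.stack([
            e[0],
            e[1],
            e[2],
            0.2 * e[0] + e[3],   # mildly related competitor
            0.2 * e[0] + e[4],
        ])
        model2 = iv.EmbeddingModel(
            words=["water", "own1", "own2", "far1", "far2"], vectors=vectors2
        )
        records2, _ = iv.silhouette_test(model2, norms)
        rec2 = next(
            r for r in records2 if r.word == "water" and r.category_id == 59
        )
        assert rec2.b < rec2.a
        assert rec2.s < 0
        assert rec2.neighbor_category_id == 38
        # without the self occurrence the flip disappears
        deduped, _ = iv.silhouette_test(model2, norms, dedupe_norms=True)
        rec2d = next(
            r for r in deduped if r.word == "water" and r.category_id == 59
        )
        assert rec2d.b > rec2.b

    def test_needs_two_usable_categories(self):
        model = small_random_model(4, 3, seed=0)
        norms = CategoryNorms(categories=[Category(1, "only", ("w0", "w1"))])
        with pytest.raises(ValueError):
            iv.silhouette_test(model, norms)


class TestSilhouetteProperties:
    @settings(max_examples=25)
    @given(st.integers(0, 10_000))
    def test_oracle_equivalence_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n_words = int(rng.integers(8, 51))
        n_cats = int(rng.integers(3, 7))
        model = small_random_model(n_words, 10, seed=seed)
        words = list(model.words)
        rng.shuffle(words)
        bounds = np.sort(rng.choice(np.arange(2, n_words - 1), size=n_cats - 1,
                                    replace=False))
        chunks = np.split(np.array(words), bounds)
        cats = [
            Category(i + 1, f"c{i}", tuple(ch.tolist()))
            for i, ch in enumerate(chunks) if len(ch) > 0
        ]
        norms = CategoryNorms(categories=cats)
        records, _ = iv.silhouette_test(model, norms)
        want = silhouette_naive(
            {w: model.vector(w).tolist() for w in model.words},
            [(c.category_id, list(c.words)) for c in cats],
        )
        want_by_key = {(r["word"], r["category_id"]): r for r in want}
        assert len(records) == len(want)
        for r in records:
            w = want_by_key[(r.word, r.category_id)]
            assert abs(r.a - w["a"]) <= 1e-12
            assert abs(r.b - w["b"]) <= 1e-12
            assert abs(r.s - w["s"]) <= 1e-12

    def test_bounds_on_trained_model(self, small_trained_model):
        manifest, _, model = small_trained_model
        norms = iv.generate_norms_from_manifest(manifest)
        records, _ = iv.silhouette_test(model, norms)
        for r in records:
            assert -1.0 <= r.s <= 1.0
            assert r.a >= 0.0 and r.b >= 0.0


class TestSilhouetteSummary:
    def test_single_category_mean(self):
        records = [
            iv.SilhouetteRecord("w", 1, 0.1, 0.3, 0.5, 2) for _ in range(3)
        ]
        summary = iv.silhouette_summary(records)
        assert summary["per_category"]["mean_s"].iloc[0] == pytest.approx(0.5)
        assert summary["global_mean"] == pytest.approx(0.5)

    def test_means_match_hand_computation(self):
        records = [
            iv.SilhouetteRecord("a", 1, 0.1, 0.2, 0.5, 2),
            iv.SilhouetteRecord("b", 1, 0.1, 0.2, 0.3, 2),
            iv.SilhouetteRecord("c", 2, 0.1, 0.2, -0.4, 1),
        ]
        summary = iv.silhouette_summary(records)
        per = dict(
            zip(summary["per_category"]["category_id"],
                summary["per_category"]["mean_s"])
        )
        assert per[1] == pytest.approx(0.4)
        assert per[2] == pytest.approx(-0.4)
        assert summary["worst_words"]["word"].iloc[0] == "c"
        assert summary["worst_words"]["neighbor_category_id"].iloc[0] == 1

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            iv.silhouette_summary([])


class TestAnalogyTest:
    def test_constructed_identity_hits_at_rank_one(self):
        # v(a) - v(b) + v(c) equals v(d) exactly
        vectors = np.array(
            [[1, 0, 0], [0, 1, 0], [0, 0, 1], [1, -1, 1], [0.3, 0.9, 0.1]]
        )
        model = iv.EmbeddingModel(words=list("abcde"), vectors=vectors)
        items = [iv.AnalogyItem("a", "b", "c", "d")]
        results, hit_rate = iv.analogy_test(model, items)
        assert hit_rate == 1.0
        assert results[0].rank == 1
        assert results[0].distance == pytest.approx(0.0, abs=1e-12)

    def test_oov_item_untestable(self):
        model = small_random_model(5, 3, seed=0)
        items = [
            iv.AnalogyItem("w0", "w1", "w2", "nope"),
            iv.AnalogyItem("w0", "w1", "w2", "w3"),
        ]
        results, hit_rate = iv.analogy_test(model, items)
        assert results[0].testable is False
        # aggregate denominator excludes the untestable item
        assert hit_rate in (0.0, 1.0)

    def test_query_words_excluded_from_candidates(self):
        # c is the word nearest to the query vector, but query words are
        # excluded, so d must be returned at rank 1
        vectors = np.array([[1.0, 0.0], [1.0, 0.01], [0.0, 1.0], [0.5, 0.7]])
        model = iv.EmbeddingModel(words=list("abcd"), vectors=vectors)
        items = [iv.AnalogyItem("a", "b", "c", "d", k=1)]
        results, _ = iv.analogy_test(model, items)
        assert results[0].hit is True
        assert results[0].rank == 1

    def test_parse_items_format(self, tmp_path):
        path = tmp_path / "items.txt"
        path.write_text(": header\nbrother sister husband wife\n# comment\n")
        items = iv.parse_analogy_items(path, k=5)
        assert items == [iv.AnalogyItem("brother", "sister", "husband", "wife", k=5)]

    def test_malformed_item_rejected(self, tmp_path):
        path = tmp_path / "items.txt"
        path.write_text("only three words\n")
        with pytest.raises(ValueError):
            iv.parse_analogy_items(path)


class TestPlantedRecovery:
    def test_planted_categories_beat_permuted_labels(self, category_runs):
        """Mean silhouette of planted words is positive and collapses
        when word membership is randomly permuted."""
        wins = 0
        for seed, (manifest, _, model) in enumerate(category_runs):
            norms = iv.generate_norms_from_manifest(manifest)
            records, _ = iv.silhouette_test(model, norms)
            mean_s = np.mean([r.s for r in records])
            perm_records, _ = iv.silhouette_test(
                model, permuted_norms(norms, seed + 1000)
            )
            perm_mean = np.mean([r.s for r in perm_records])
            assert mean_s > 0
            wins += mean_s > perm_mean
        assert wins >= 4

    def test_permuted_labels_show_no_cohesion(self, category_runs):
        """Random regrouping leaves no positive category cohesion."""
        perm_means = []
        for seed, (manifest, _, model) in enumerate(category_runs):
            norms = iv.generate_norms_from_manifest(manifest)
            perm_records, _ = iv.silhouette_test(
                model, permuted_norms(norms, seed + 2000)
            )
            perm_means.append(np.mean([r.s for r in perm_records]))
        assert np.mean(perm_means) < 0.1

    def test_analogy_recovery_hit_rate(self, analogy_runs):
        """Planted relations are recovered by top-5 analogy queries."""
        hits = total = 0
        for _, items, model in analogy_runs:
            results, _ = iv.analogy_test(model, items)
            for r in results:
                if r.testable:
                    total += 1
                    hits += r.hit
        assert hits / total >= 0.5
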