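"""Calinski–Harabasz correctness, invariances and permutation baselines."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_toy_space
from semdiv.diagnostics import (
    calinski_harabasz,
    corpus_label_diagnostic,
    embed_2d,
    load_context_labels,
    random_label_baseline,
    word_context_diagnostic,
)


def ch_oracle(X, labels):
    """Independent trace-ratio computation with explicit loops."""
    X = np.asarray(X, float)
    cats = sorted(set(labels))
    g, n = len(cats), len(X)
    grand = X.mean(axis=0)
    between = within = 0.0
    for c in cats:
        pts = X[[i for i, l in enumerate(labels) if l == c]]
        mu = pts.mean(axis=0)
        between += len(pts) * float(np.sum((mu - grand) ** 2))
        within += float(np.sum((pts - mu) ** 2))
    return (between / (g - 1)) / (within / (n - g))


class TestCalinskiHarabasz:
    def test_six_point_two_label_hand_case(self):
        X = np.array([[0.0, 0], [1, 0], [0, 1], [10, 10], [11, 10], [10, 11]])
        labels = ["a", "a", "a", "b", "b", "b"]
        assert calinski_harabasz(X, labels) == pytest.approx(ch_oracle(X, labels), abs=1e-12)

    def test_score_grows_with_separation(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal((40, 3))
        labels = ["a"] * 20 + ["b"] * 20
        prev = 0.0
        for sep in (1.0, 3.0, 9.0):
            X = base.copy()
            X[20:] += sep
            score = calinski_harabasz(X, labels)
            assert score > prev
            prev = score
        assert prev > 50  # tight well-separated clusters score ≫ 1

    def test_single_label_errors(self):
        with pytest.raises(ValueError):
            calinski_harabasz(np.eye(4), ["a"] * 4)

    def test_degenerate_perfect_clustering_errors(self):
        X = np.array([[0.0, 0], [0, 0], [5, 5], [5, 5]])
        with pytest.raises(ValueError, match="within"):
            calinski_harabasz(X, ["a", "a", "b", "b"])

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_oracle_and_sklearn(self, seed):
        rng = np.random.default_rng(seed)
        n, k, g = int(rng.integers(6, 30)), int(rng.integers(2, 6)), int(rng.integers(2, 4))
        X = rng.standard_normal((n, k))
        labels = list(rng.integers(0, g, size=n))
        labels[:g] = range(g)  # every label present
        ours = calinski_harabasz(X, labels)
        assert ours == pytest.approx(ch_oracle(X, labels), abs=1e-9)
        from sklearn.metrics import calinski_harabasz_score
        assert ours == pytest.approx(calinski_harabasz_score(X, labels), rel=1e-9)

    def test_invariance_translation_rotation_scale(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((25, 4))
        labels = list(rng.integers(0, 3, size=25))
        labels[:3] = [0, 1, 2]
        base = calinski_harabasz(X, labels)
        Q = np.linalg.qr(rng.standard_normal((4, 4)))[0]
        for Y in (X + 7.5, X @ Q, 0.003 * X):
            assert calinski_harabasz(Y, labels) == pytest.approx(base, rel=1e-9)


class TestRandomLabelBaseline:
    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((50, 3))
        labels = ["a"] * 25 + ["b"] * 25
        assert random_label_baseline(X, labels, 50, seed=9) == \
            random_label_baseline(X, labels, 50, seed=9)

    def test_single_iteration_sd_zero_with_warning(self, caplog):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((20, 3))
        with caplog.at_level("WARNING"):
            mean, sd = random_label_baseline(X, ["a"] * 10 + ["b"] * 10, n_iterations=1, seed=0)
        assert sd == 0.0 and "single iteration" in caplog.text

    def test_mean_near_one_even_for_clustered_data(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((2000, 20))
        X[:1000] += 3.0  # strong real structure; permuting must erase it
        labels = ["a"] * 1000 + ["b"] * 1000
        mean, sd = random_label_baseline(X, labels, n_iterations=200, seed=4)
        assert mean == pytest.approx(1.0, abs=0.1)


class TestContextDiagnostics:
    def _labelled_space(self, orthogonal=True, n_per=12, seed=0):
        rng = np.random.default_rng(seed)
        A = np.hstack([rng.standard_normal((n_per, 3)) * 0.2 + [5, 0, 0]])
        shift = [0, 5, 0] if orthogonal else [5, 0, 0]
        B = rng.standard_normal((n_per, 3)) * 0.2 + shift
        V = np.vstack([A, B])
        space = make_toy_space(V, {"ww": list(range(2 * n_per))})
        labels = {i: ("m1" if i < n_per else "m2") for i in range(2 * n_per)}
        return space, labels

    def test_planted_meanings_recovered(self):
        space, labels = self._labelled_space(orthogonal=True)
        d = word_context_diagnostic(space, "ww", labels, fraction=1.0, seed=0, n_iterations=200)
        assert d.ch_score > d.baseline_mean + 3 * d.baseline_sd
        assert d.exceeds_baseline

    def test_random_labels_sit_at_baseline(self):
        space, _ = self._labelled_space(orthogonal=True, n_per=30)
        rng = np.random.default_rng(8)
        rand_labels = {i: ("m1" if b else "m2") for i, b in enumerate(rng.integers(0, 2, 60))}
        d = word_context_diagnostic(space, "ww", rand_labels, fraction=1.0, seed=1,
                                    n_iterations=300)
        assert abs(d.ch_score - d.baseline_mean) <= 3 * d.baseline_sd

    def test_fraction_sampling(self):
        space, labels = self._labelled_space()
        d_half = word_context_diagnostic(space, "ww", labels, fraction=0.5, seed=0,
                                         n_iterations=20)
        assert d_half.n_points == 12  # ceil(0.5 * 24)
        d_all = word_context_diagnostic(space, "ww", labels, fraction=1.0, seed=0,
                                        n_iterations=20)
        assert d_all.n_points == 24

    def test_missing_label_errors(self):
        space, labels = self._labelled_space()
        del labels[0]
        with pytest.raises(KeyError):
            word_context_diagnostic(space, "ww", labels, fraction=1.0, seed=0, n_iterations=10)

    def test_labels_file_loader(self, tmp_path):
        p = tmp_path / "labels.tsv"
        p.write_text("context_id\tcategory\n0\tm1\n1\tm2\n")
        assert load_context_labels(p) == {0: "m1", 1: "m2"}


class TestCorpusLabelDiagnostic:
    def test_topic_labels_cluster_in_synthetic_corpus(self, small_run):
        space = small_run["result"].space
        d = corpus_label_diagnostic(space, "domain", seed=0, n_iterations=100)
        assert d.ch_score > d.baseline_mean + 3 * d.baseline_sd
        assert 0.5 < d.baseline_mean < 1.5

    def test_permuted_labels_fall_to_baseline(self, small_run):
        space = small_run["result"].space
        rng = np.random.default_rng(0)
        perm_labels = rng.permutation([space.row_labels[i]["domain"]
                                       for i in range(space.n_contexts)])
        ch = calinski_harabasz(space.context_vectors, perm_labels)
        mean, sd = random_label_baseline(space.context_vectors, perm_labels,
                                         n_iterations=100, seed=1)
        assert abs(ch - mean) <= 4 * sd

    def test_missing_dimension_errors(self, small_run):
        with pytest.raises(ValueError):
            corpus_label_diagnostic(small_run["result"].space, "nonexistent")


class TestEmbed2D:
    def test_shape_and_determinism(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((30, 5))
        labels = ["a"] * 15 + ["b"] * 15
        e1 = embed_2d(X, labels, perplexity=5, seed=3)
        e2 = embed_2d(X, labels, perplexity=5, seed=3)
        assert list(e1.columns) == ["x", "y", "label"]
        assert len(e1) == 30
        np.testing.assert_array_equal(e1[["x", "y"]].to_numpy(), e2[["x", "y"]].to_numpy())

    def test_perplexity_bound(self):
        with pytest.raises(ValueError):
            embed_2d(np.eye(6), ["a"] * 6, perplexity=6, seed=0)

    def test_planted_clusters_silhouette_positive(self):
        rng = np.random.default_rng(7)
        A = rng.standard_normal((20, 4)) * 0.1
        B = rng.standard_normal((20, 4)) * 0.1 + 4.0
        labels = ["a"] * 20 + ["b"] * 20
        emb = embed_2d(np.vstack([A, B]), labels, perplexity=10, seed=0)
        from sklearn.metrics import silhouette_score
        assert silhouette_score(emb[["x", "y"]].to_numpy(), labels) > 0
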