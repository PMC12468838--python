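"""Feature engineering: TF-IDF, Word2Vec embeddings, z-scoring, CLAHE
image preprocessing, Savitzky-Golay smoothing, and SMOTE + Tomek-link
rebalancing, each against hand-computed or brute-force oracles."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qavfl import features as ft
from qavfl.textproc import EmbeddingModel, TextCorpusStats


# ---------------------------------------------------------------------------
# TF-IDF

class TestTfidf:
    def _stats(self, docs):
        return ft.build_corpus_stats(docs)

    def test_hand_computed_weight(self):
        # tf=2, N=10, df=4 -> 2 * ln(10/5)
        docs = [["x", "x"]] + [["x"] for _ in range(3)] + [["y"] for _ in range(6)]
        stats = self._stats(docs)
        w = ft.tfidf_weights(stats, 0)
        assert w["x"] == pytest.approx(2 * math.log(10 / 5), abs=1e-4)

    def test_zero_when_df_plus_one_equals_n(self):
        # tf=3, N=10, df=9 -> 3 * ln(10/10) = 0
        docs = [["z", "z", "z"]] + [["z"] for _ in range(8)] + [["q"]]
        stats = self._stats(docs)
        assert ft.tfidf_weights(stats, 0)["z"] == pytest.approx(0.0, abs=1e-12)

    def test_absent_token_gets_no_weight(self):
        stats = self._stats([["a"], ["b"]])
        assert "b" not in ft.tfidf_weights(stats, 0)

    def test_nonnegative_when_df_small(self):
        stats = self._stats([["a", "b"], ["a"], ["c"]])
        for doc in range(3):
            for w, v in ft.tfidf_weights(stats, doc).items():
                if stats.df[w] + 1 <= stats.N:
                    assert v >= 0

    def test_errors(self):
        with pytest.raises(ValueError):
            ft.build_corpus_stats([])
        stats = self._stats([["a"]])
        with pytest.raises(IndexError):
            ft.tfidf_weights(stats, 5)


# ---------------------------------------------------------------------------
# Word2Vec

class TestWord2Vec:
    def test_min_count_filters_rare_tokens(self):
        docs = [["alpha", "beta"]] * 10 + [["gamma", "alpha"]]
        model = ft.train_word2vec(docs, dim=8, min_count=2, epochs=2, seed=0)
        assert "gamma" not in model.vectors
        assert "alpha" in model.vectors

    def test_vector_dimension(self):
        docs = [["a", "b", "c"]] * 12
        model = ft.train_word2vec(docs, dim=5, min_count=1, epochs=2, seed=0)
        assert all(v.shape == (5,) for v in model.vectors.values())

    def test_cooccurrence_drives_similarity(self):
        # 'sun'/'moon' always share contexts with 'sky'; 'rock' never does
        rng = np.random.default_rng(0)
        docs = []
        for _ in range(150):
            docs.append(["sun", "sky", "moon"])
            docs.append(["rock", "dust", "sand"])
        model = ft.train_word2vec(docs, dim=12, min_count=1, window=2,
                                  epochs=10, seed=1)

        def cos(a, b):
            va, vb = model.vectors[a], model.vectors[b]
            return va @ vb / (np.linalg.norm(va) * np.linalg.norm(vb))

        assert cos("sun", "moon") > cos("sun", "rock")

    def test_errors(self):
        with pytest.raises(ValueError):
            ft.train_word2vec([["a"]] * 5, dim=4)     # too few documents
        with pytest.raises(ValueError):
            ft.train_word2vec([["a"], ["b"], ["c"], ["d"], ["e"], ["f"],
                               ["g"], ["h"], ["i"], ["j"]],
                              dim=4, min_count=3)     # empty vocabulary


class TestEmbedText:
    def _fixture(self):
        vecs = {"cupping": np.array([1.0, 0.0]), "halos": np.array([0.0, 1.0])}
        model = EmbeddingModel(dim=2, vectors=vecs)
        stats = TextCorpusStats(N=10, df={"cupping": 4, "halos": 1},
                                tf=[Counter()], vocabulary=["cupping", "halos"])
        return stats, model

    def test_single_token_is_its_vector(self):
        stats, model = self._fixture()
        np.testing.assert_allclose(ft.embed_text("cupping", stats, model),
                                   [1.0, 0.0])

    def test_empty_note_is_zero_vector(self):
        stats, model = self._fixture()
        np.testing.assert_allclose(ft.embed_text("", stats, model), [0.0, 0.0])
        np.testing.assert_allclose(ft.embed_text("the of and", stats, model),
                                   [0.0, 0.0])

    def test_weighted_mean_hand_computed(self):
        stats, model = self._fixture()
        # weights: cupping = ln(10/5) = 0.6931, halos = ln(10/2) = 1.6094
        w1, w2 = math.log(2.0), math.log(5.0)
        expected = (w1 * np.array([1.0, 0.0]) + w2 * np.array([0.0, 1.0])) / (w1 + w2)
        got = ft.embed_text("cupping halos", stats, model)
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_token_limit_truncates(self):
        stats, model = self._fixture()
        model.token_limit = 1
        got = ft.embed_text("cupping halos", stats, model)
        np.testing.assert_allclose(got, [1.0, 0.0])


# ---------------------------------------------------------------------------
# z-score

class TestZscore:
    def test_fit_transform_standardizes(self):
        X = np.array([[2.0], [4.0], [6.0]])
        params = ft.fit_zscore(X)
        z = ft.zscore(X, params)
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std() == pytest.approx(1.0, abs=1e-12)

    def test_constant_column_maps_to_zero(self):
        X = np.full((5, 3), 7.0)
        z = ft.zscore(X, ft.fit_zscore(X))
        np.testing.assert_allclose(z, 0.0)

    def test_hand_arithmetic(self):
        params = ft.NormalizationParams(mu=np.array([2.0]), sigma=np.array([1.5]))
        np.testing.assert_allclose(ft.zscore(np.array([5.0]), params), [2.0])

    def test_dimension_mismatch(self):
        params = ft.fit_zscore(np.ones((4, 3)))
        with pytest.raises(ValueError):
            ft.zscore(np.ones(2), params)


# ---------------------------------------------------------------------------
# image preprocessing

class TestPreprocessImage:
    def test_resize_shape(self):
        img = np.random.default_rng(0).random((64, 64, 3))
        out = ft.preprocess_image(img, target_size=224)
        assert out.shape == (224, 224, 3)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_flat_field_stays_flat(self):
        img = np.full((64, 64, 3), 0.5)
        out = ft.preprocess_image(img, target_size=64)
        assert out.min() >= 0.0 and out.max() <= 1.0
        # CLAHE of a constant field maps to a (possibly different) constant
        assert out.std() < 0.02

    def test_contrast_not_reduced_on_gradient(self):
        ramp = np.linspace(0.45, 0.55, 64)
        img = np.repeat(ramp[None, :, None], 64, axis=0)
        img = np.repeat(img, 3, axis=2)
        out = ft.preprocess_image(img, target_size=64)
        lum_in = img.mean(axis=2)
        lum_out = out.mean(axis=2)
        assert lum_out.max() - lum_out.min() >= lum_in.max() - lum_in.min()

    def test_rejects_non_rgb(self):
        with pytest.raises(ValueError):
            ft.preprocess_image(np.zeros((32, 32)))


# ---------------------------------------------------------------------------
# Savitzky-Golay

class TestSgFilter:
    def test_k3_p2_is_identity(self):
        rng = np.random.default_rng(0)
        s = rng.normal(0, 1, 50)
        out = ft.sg_filter(s, ft.SGConfig(window=3, polyorder=2))
        np.testing.assert_allclose(out, s, atol=1e-9)

    def test_constant_signal_unchanged(self):
        s = np.full(40, 3.25)
        np.testing.assert_allclose(ft.sg_filter(s, ft.SGConfig(7, 2)), s,
                                   atol=1e-12)

    def test_quadratic_reproduced_exactly(self):
        t = np.arange(60, dtype=float)
        s = 0.3 * t**2 - 2 * t + 5
        out = ft.sg_filter(s, ft.SGConfig(7, 2))
        np.testing.assert_allclose(out, s, atol=1e-8)

    def test_linearity(self):
        rng = np.random.default_rng(3)
        s1, s2 = rng.normal(0, 1, 64), rng.normal(0, 1, 64)
        cfg = ft.SGConfig(9, 3)
        lhs = ft.sg_filter(2.0 * s1 - 0.5 * s2, cfg)
        rhs = 2.0 * ft.sg_filter(s1, cfg) - 0.5 * ft.sg_filter(s2, cfg)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_matches_dense_window_least_squares(self, seed):
        # interior points equal the center value of a per-window polyfit
        rng = np.random.default_rng(seed)
        s = rng.normal(0, 1, 40)
        k, p = 7, 2
        out = ft.sg_filter(s, ft.SGConfig(k, p))
        half = k // 2
        t = np.arange(k) - half
        for i in range(half, len(s) - half):
            coef = np.polynomial.polynomial.polyfit(t, s[i - half:i + half + 1], p)
            assert abs(out[i] - coef[0]) < 1e-8

    def test_config_errors(self):
        with pytest.raises(ValueError):
            ft.sg_filter(np.ones(20), ft.SGConfig(4, 2))
        with pytest.raises(ValueError):
            ft.sg_filter(np.ones(20), ft.SGConfig(5, 5))
        with pytest.raises(ValueError):
            ft.sg_filter(np.ones(3), ft.SGConfig(7, 2))


# ---------------------------------------------------------------------------
# SMOTE + Tomek

class TestSmoteTomek:
    def test_balanced_separated_input_unchanged(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.1, (10, 2)), rng.normal(5, 0.1, (10, 2))])
        y = np.array([0] * 10 + [1] * 10)
        X2, y2 = ft.smote_tomek(X, y, seed=1)
        assert np.array_equal(X2, X) and np.array_equal(y2, y)

    def test_two_point_minority_interpolates_on_segment(self):
        a, b = np.array([0.0, 0.0]), np.array([1.0, 1.0])
        X = np.vstack([[a], [b], np.random.default_rng(2).normal(10, 0.1, (8, 2))])
        y = np.array([1, 1] + [0] * 8)
        with pytest.warns(UserWarning):
            X2, y2 = ft.smote_tomek(X, y, k_neighbors=5, seed=3)
        synthetic = X2[10:][y2[10:] == 1]
        assert len(synthetic) > 0
        for p in synthetic:
            # on segment [a, b]: both coordinates equal and within [0, 1]
            assert p[0] == pytest.approx(p[1], abs=1e-12)
            assert -1e-12 <= p[0] <= 1 + 1e-12

    def test_counts_equalized_before_tomek(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(0, 0.2, (20, 3)), rng.normal(8, 0.2, (7, 3))])
        y = np.array([0] * 20 + [1] * 7)
        X2, y2 = ft.smote_tomek(X, y, seed=5)
        # classes well separated -> no Tomek removals, so counts are equal
        assert (y2 == 0).sum() == (y2 == 1).sum() == 20

    def test_tomek_link_majority_member_removed(self):
        # one interleaved majority point whose mutual NN is a minority point
        X = np.array([
            [0.0, 0.0], [0.2, 0.0],          # minority pair
            [0.25, 0.0],                      # majority intruder (Tomek link)
            [5.0, 5.0], [5.2, 5.0], [5.4, 5.0],  # majority cluster
        ])
        y = np.array([1, 1, 0, 0, 0, 0])
        # brute-force oracle: mutual nearest neighbors of opposite label
        d = np.linalg.norm(X[:, None] - X[None], axis=2) + np.eye(6) * 1e9
        nn = d.argmin(axis=1)
        links = [(i, j) for i, j in enumerate(nn)
                 if nn[j] == i and y[i] != y[j]]
        assert any(2 in pair for pair in links)
        with pytest.warns(UserWarning):
            X2, y2 = ft.smote_tomek(X, y, seed=6)
        assert not any(np.allclose(row, [0.25, 0.0]) for row in X2)

    def test_never_removes_minority_or_fabricates_majority(self):
        rng = np.random.default_rng(7)
        X = np.vstack([rng.normal(0, 1.0, (15, 2)), rng.normal(1, 1.0, (6, 2))])
        y = np.array([0] * 15 + [1] * 6)
        X2, y2 = ft.smote_tomek(X, y, seed=8)
        # all original minority rows survive
        for row in X[y == 1]:
            assert any(np.allclose(row, r) for r in X2[y2 == 1])
        # majority count never grows
        assert (y2 == 0).sum() <= 15

    def test_errors(self):
        X = np.ones((4, 2))
        with pytest.raises(ValueError):
            ft.smote_tomek(X, np.array([0, 0, 0, 0]))
        with pytest.raises(ValueError):
            ft.smote_tomek(X, np.array([0, 0, 0, 1]))
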