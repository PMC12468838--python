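"""Fusion Attention Module: quality indicators, softmax attention with
masking/renormalization, weighted-sum fusion, the multi-objective loss,
gradient correctness, and suppression of a pure-noise modality."""

import numpy as np
import pytest

from qavfl.fusion import (AttentionState, FusionConfig, FusionHead,
                          LossConfig, ModalityFeature, attention_weights,
                          fuse, quality_indicators, total_loss)


# ---------------------------------------------------------------------------
# quality indicators

class TestQualityIndicators:
    def test_constant_vector_degenerate(self):
        q = quality_indicators(np.full(32, 1.7))
        assert q.variance == 0.0
        assert q.entropy == 0.0

    def test_uniform_bins_max_entropy(self):
        # 16 distinct values repeated equally fill all 16 bins evenly
        h = np.repeat(np.arange(16, dtype=float), 4)
        q = quality_indicators(h)
        assert q.entropy == pytest.approx(np.log(16), abs=1e-9)

    def test_hand_unbiased_variance(self):
        q = quality_indicators(np.array([0.0, 0.0, 1.0, 1.0]))
        assert q.variance == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_entropy_bounds(self, rng):
        for _ in range(10):
            q = quality_indicators(rng.normal(0, 1, 64))
            assert 0.0 <= q.entropy <= np.log(16) + 1e-12
            assert q.variance >= 0.0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            quality_indicators(np.array([1.0]))


# ---------------------------------------------------------------------------
# attention weights (functional op)

def _features(hs, available=(True, True, True)):
    names = ["text", "image", "signal"]
    return [ModalityFeature(m, np.asarray(h, dtype=float), av)
            for m, h, av in zip(names, hs, available)]


class TestAttentionWeights:
    def test_equal_logits_uniform(self):
        params = {m: np.zeros(6) for m in ("text", "image", "signal")}
        feats = _features([np.ones(4), np.ones(4) * 2, np.ones(4) * 3])
        state = attention_weights(feats, params, temperature=0.5)
        for m in ("text", "image", "signal"):
            assert state.alpha[m] == pytest.approx(1 / 3, abs=1e-9)

    def test_masked_modality_renormalizes(self):
        params = {m: np.zeros(6) for m in ("text", "image", "signal")}
        feats = _features([np.ones(4)] * 3, available=(True, True, False))
        state = attention_weights(feats, params)
        assert state.alpha["signal"] == 0.0
        assert state.alpha["text"] == pytest.approx(0.5, abs=1e-9)
        assert state.alpha["image"] == pytest.approx(0.5, abs=1e-9)

    def test_hand_softmax(self):
        # logits (ln 2, 0, 0) at temperature 1 -> alpha = (0.5, 0.25, 0.25)
        w = np.zeros(4)
        w[0] = 1.0
        params = {m: w for m in ("text", "image", "signal")}
        h1 = np.array([np.log(2.0), 0.0])     # quality entries are 0 via w
        h0 = np.array([0.0, 0.0])
        feats = _features([h1, h0, h0])
        state = attention_weights(feats, params, temperature=1.0)
        assert state.alpha["text"] == pytest.approx(0.5, abs=1e-9)
        assert state.alpha["image"] == pytest.approx(0.25, abs=1e-9)
        assert state.alpha["signal"] == pytest.approx(0.25, abs=1e-9)

    def test_all_masked_rejected(self):
        params = {m: np.zeros(6) for m in ("text", "image", "signal")}
        feats = _features([np.ones(4)] * 3, available=(False, False, False))
        with pytest.raises(ValueError):
            attention_weights(feats, params)

    @pytest.mark.parametrize("mask", [
        (True, True, True), (True, True, False), (True, False, True),
        (False, True, True), (True, False, False), (False, True, False),
        (False, False, True),
    ])
    def test_simplex_under_every_mask(self, mask, rng):
        params = {m: rng.normal(0, 1, 10) for m in ("text", "image", "signal")}
        feats = _features([rng.normal(0, 1, 8) for _ in range(3)], mask)
        state = attention_weights(feats, params)
        total = sum(state.alpha.values())
        assert total == pytest.approx(1.0, abs=1e-9)
        for m, av in zip(("text", "image", "signal"), mask):
            assert state.alpha[m] >= 0.0
            if not av:
                assert state.alpha[m] == 0.0

    def test_masking_equals_two_modality_oracle(self, rng):
        # masking the third modality must equal a direct two-way softmax
        params = {m: rng.normal(0, 1, 10) for m in ("text", "image", "signal")}
        hs = [rng.normal(0, 1, 8) for _ in range(3)]
        masked = attention_weights(_features(hs, (True, True, False)), params)
        z = [masked.logits["text"], masked.logits["image"]]
        e = np.exp(np.array(z) - max(z))
        oracle = e / e.sum()
        assert masked.alpha["text"] == pytest.approx(oracle[0], abs=1e-12)
        assert masked.alpha["image"] == pytest.approx(oracle[1], abs=1e-12)


class TestFuse:
    def test_degenerate_weight_returns_input(self):
        feats = _features([[2.0, 0.0], [0.0, 2.0], [1.0, 1.0]])
        state = AttentionState(["text", "image", "signal"], {},
                               {"text": 1.0, "image": 0.0, "signal": 0.0},
                               0.5, {m: True for m in ("text", "image", "signal")})
        np.testing.assert_allclose(fuse(feats, state), [2.0, 0.0])

    def test_convexity_fixed_point(self, rng):
        h = rng.normal(0, 1, 6)
        feats = _features([h, h, h])
        state = AttentionState(["text", "image", "signal"], {},
                               {"text": 0.2, "image": 0.5, "signal": 0.3},
                               0.5, {m: True for m in ("text", "image", "signal")})
        np.testing.assert_allclose(fuse(feats, state), h, atol=1e-12)

    def test_hand_weighted_sum(self):
        feats = _features([[2.0, 0.0], [0.0, 2.0]], (True, True))[:2]
        state = AttentionState(["text", "image"], {},
                               {"text": 0.75, "image": 0.25}, 0.5,
                               {"text": True, "image": True})
        np.testing.assert_allclose(fuse(feats, state), [1.5, 0.5])

    def test_dim_mismatch_rejected(self):
        feats = [ModalityFeature("text", np.zeros(4), True),
                 ModalityFeature("image", np.zeros(5), True)]
        state = AttentionState(["text", "image"], {},
                               {"text": 0.5, "image": 0.5}, 0.5,
                               {"text": True, "image": True})
        with pytest.raises(ValueError):
            fuse(feats, state)


# ---------------------------------------------------------------------------
# multi-objective loss

class TestTotalLoss:
    def test_degenerate_minimum(self):
        logits = np.array([[30.0, 0.0]])
        out = total_loss(logits, {"text": logits, "image": logits},
                         np.array([0]), np.zeros((1, 2)), LossConfig(0.1, 0.1))
        assert out.L_CE == pytest.approx(0.0, abs=1e-10)
        assert out.L_fuse == pytest.approx(0.0, abs=1e-10)
        assert out.L_sparsity == 0.0

    def test_reduces_to_cross_entropy(self, rng):
        logits = rng.normal(0, 1, (4, 2))
        heads = {"text": rng.normal(0, 1, (4, 2))}
        z = rng.normal(0, 1, (4, 3))
        y = np.array([0, 1, 1, 0])
        out = total_loss(logits, heads, y, z, LossConfig(0.0, 0.0))
        assert out.L_total == pytest.approx(out.L_CE, abs=1e-12)

    def test_hand_cross_entropy(self):
        out = total_loss(np.array([[0.0, 0.0]]), {}, np.array([1]),
                         np.zeros((1, 3)), LossConfig())
        assert out.L_CE == pytest.approx(np.log(2.0), abs=1e-9)
        # probabilities on the simplex
        assert out.probabilities.sum() == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(out.probabilities, [[0.5, 0.5]], atol=1e-12)

    def test_hand_softmax_probability(self):
        out = total_loss(np.array([[np.log(3.0), 0.0]]), {}, np.array([0]),
                         np.zeros((1, 1)), LossConfig())
        np.testing.assert_allclose(out.probabilities, [[0.75, 0.25]], atol=1e-9)

    def test_kl_nonnegative_and_zero_iff_equal(self, rng):
        fused = rng.normal(0, 1, (5, 2))
        same = total_loss(fused, {"a": fused.copy(), "b": fused.copy()},
                          np.zeros(5, dtype=int), np.zeros((5, 2)), LossConfig())
        assert same.L_fuse == pytest.approx(0.0, abs=1e-12)
        for _ in range(5):
            other = total_loss(fused, {"a": rng.normal(0, 1, (5, 2))},
                               np.zeros(5, dtype=int), np.zeros((5, 2)),
                               LossConfig())
            assert other.L_fuse >= 0.0

    def test_total_is_exact_linear_combination(self, rng):
        logits = rng.normal(0, 1, (3, 2))
        heads = {"text": rng.normal(0, 1, (3, 2))}
        z = rng.normal(0, 1, (3, 3))
        y = np.array([1, 0, 1])
        cfg = LossConfig(lambda_fuse=0.01, lambda_att=0.001)
        out = total_loss(logits, heads, y, z, cfg)
        assert out.L_total == pytest.approx(
            out.L_CE + cfg.lambda_fuse * out.L_fuse
            + cfg.lambda_att * out.L_sparsity, abs=1e-14)


# ---------------------------------------------------------------------------
# trainable head

class TestFusionHead:
    IN_DIMS = {"text": 5, "image": 6, "signal": 4}

    def _head(self, **kw):
        cfg = FusionConfig(d_f=8, heads=kw.pop("heads", 1), dropout=0.0, seed=0)
        return FusionHead(cfg, self.IN_DIMS)

    def _latents(self, rng, B=6):
        return {m: rng.normal(0, 1, (B, d)) for m, d in self.IN_DIMS.items()}

    def test_batch_alpha_simplex_every_mask(self, rng):
        head = self._head()
        lat = self._latents(rng)
        from itertools import combinations
        mods = ("text", "image", "signal")
        for size in (1, 2, 3):
            for subset in combinations(mods, size):
                mask = {m: m in subset for m in mods}
                _, _, alpha, _, _ = head.forward(lat, mask=mask, train=False)
                np.testing.assert_allclose(alpha.sum(axis=1), 1.0, atol=1e-9)
                for mi, m in enumerate(mods):
                    if m not in subset:
                        assert np.all(alpha[:, mi] == 0.0)

    def test_gradients_match_numerical(self, rng):
        # quality entries zeroed: the variance/entropy inputs to the score
        # are stop-gradient by design, all other paths must be exact
        head = self._head()
        for m in head.scores:
            head.scores[m].value[:, -2:] = 0.0
        lat = self._latents(rng)
        y = np.array([0, 1, 1, 0, 1, 0])
        lcfg = LossConfig(lambda_fuse=0.05, lambda_att=0.01)
        theta = head.get_theta()
        for p in head.params():
            p.zero_grad()
        head.loss_and_grad(lat, y, lcfg, train=True)
        grad = np.concatenate([p.grad.ravel() for p in head.params()])

        def loss_at(vec):
            head.set_theta(vec)
            return head.loss_and_grad(lat, y, lcfg, train=True,
                                      backward=False).L_total

        eps = 1e-6
        idx = np.random.default_rng(5).choice(theta.size, 50, replace=False)
        for i in idx:
            v = theta.copy(); v[i] += eps; lp = loss_at(v)
            v = theta.copy(); v[i] -= eps; lm = loss_at(v)
            num = (lp - lm) / (2 * eps)
            assert abs(num - grad[i]) <= 1e-5 * max(1.0, abs(num))

    def test_multi_head_variant_partitions(self, rng):
        head = self._head(heads=4)
        lat = self._latents(rng)
        logits, _, alpha, z, _ = head.forward(lat, train=False)
        assert alpha.shape == (6, 3, 4)
        np.testing.assert_allclose(alpha.sum(axis=1), 1.0, atol=1e-9)
        assert logits.shape == (6, 2)

    def test_predict_proba_simplex(self, rng):
        head = self._head()
        proba = head.predict_proba(self._latents(rng))
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(proba >= 0)

    def test_no_available_modality_rejected(self, rng):
        head = self._head()
        with pytest.raises(ValueError):
            head.forward(self._latents(rng),
                         mask={"text": False, "image": False, "signal": False})

    def test_noise_modality_gets_lowest_attention(self):
        # informative latents carry severity; 'signal' is pure noise.
        # After training, the noise modality's mean attention is below each
        # informative modality's (repeated over 3 seeds).
        for seed in (0, 1, 2):
            rng = np.random.default_rng(100 + seed)
            n, d = 300, 8
            sev = rng.uniform(0, 1, n)
            y = (sev >= 0.5).astype(int)
            lat = {
                "text": sev[:, None] * rng.normal(1, 0.2, (1, d))
                + rng.normal(0, 0.3, (n, d)),
                "image": sev[:, None] * rng.normal(-1, 0.2, (1, d))
                + rng.normal(0, 0.3, (n, d)),
                "signal": rng.normal(0, 1.0, (n, d)),
            }
            cfg = FusionConfig(d_f=24, dropout=0.0, seed=seed)
            head = FusionHead(cfg, {m: d for m in lat})
            head.fit(lat, y, LossConfig(), epochs=25, lr=3e-3, seed=seed)
            _, _, alpha, _, _ = head.forward(lat, train=False)
            mean_alpha = alpha.mean(axis=0).ravel()   # text, image, signal
            assert mean_alpha[2] < mean_alpha[0]
            assert mean_alpha[2] < mean_alpha[1]
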