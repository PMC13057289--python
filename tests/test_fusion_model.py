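"""Fusion, classification head, loss, and whole-model contracts."""

import numpy as np
import pytest

from leaffusionnet import nn
from leaffusionnet.branches import CnnConfig, VitConfig
from leaffusionnet.fusion_model import (ClassificationHead, GaborConfig,
                                        HeadConfig, LeafFusionNet, ModelConfig,
                                        count_parameters, fuse, head_forward,
                                        model_forward, sparse_ce_loss,
                                        tiny_profile)
from leaffusionnet.nn import tensor as T


def small_config(n_classes=3, dropout=0.0):
    return ModelConfig(
        image_side=16, n_classes=n_classes,
        gabor=GaborConfig(n_orientations=2, ksize=5),
        cnn=CnnConfig(widths=(4, 4)),
        vit=VitConfig(input_side=16, patch_size=8, d_model=8, depth=1, n_heads=2),
        head=HeadConfig(hidden=(6, 5), dropout_rate=dropout, n_classes=n_classes),
        reduction_ratio=2)


class TestFuse:
    def test_additive_lengths(self, rng):
        fv = fuse(rng.random(128), rng.random(192), rng.random(128))
        assert fv.values.shape == (448,)
        assert fv.lengths == (128, 192, 128)

    def test_layout_preserves_first_stream_exactly(self, rng):
        a, b, c = rng.random(5), rng.random(3), rng.random(4)
        fv = fuse(a, b, c)
        np.testing.assert_array_equal(fv.values[:5], a)
        np.testing.assert_array_equal(fv.values[5:8], b)
        np.testing.assert_array_equal(fv.values[8:], c)

    def test_one_hot_streams_land_at_predictable_offsets(self):
        a = np.eye(4)[1]
        b = np.eye(3)[0]
        c = np.eye(5)[4]
        fv = fuse(a, b, c)
        assert np.flatnonzero(fv.values).tolist() == [1, 4, 11]

    def test_empty_stream_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            fuse(np.array([]), rng.random(3), rng.random(3))


class TestHead:
    def test_probabilities_normalised_and_positive(self, rng):
        head = ClassificationHead(10, HeadConfig(hidden=(8, 6), n_classes=5), rng)
        probs = head_forward(rng.normal(size=(7, 10)), head)
        np.testing.assert_allclose(probs.sum(1), 1.0, atol=1e-6)
        assert probs.min() > 0

    def test_zeroed_output_layer_gives_uniform_distribution(self, rng):
        head = ClassificationHead(4, HeadConfig(hidden=(5, 4), n_classes=6), rng)
        head.out.W.data[:] = 0.0
        head.out.b.data[:] = 0.0
        probs = head_forward(rng.normal(size=4), head)
        np.testing.assert_allclose(probs, 1 / 6, atol=1e-12)

    def test_tiny_integer_head_matches_scalar_forward_oracle(self):
        rng = np.random.default_rng(0)
        cfg = HeadConfig(hidden=(4, 3), dropout_rate=0.0, n_classes=2)
        head = ClassificationHead(5, cfg, rng)
        w1 = np.arange(20).reshape(5, 4) % 3 - 1.0
        w2 = np.arange(12).reshape(4, 3) % 2 * 1.0
        w3 = np.array([[1.0, -1], [0, 2], [1, 1]])
        for p in head.parameters():
            p.data = p.data.astype(np.float64)
        for lay in head.modules():
            if isinstance(lay, nn.BatchNorm1d):
                lay.register_buffer("running_mean",
                                    lay.running_mean.astype(np.float64))
                lay.register_buffer("running_var",
                                    lay.running_var.astype(np.float64))
        head.layers[0].W.data, head.layers[0].b.data[:] = w1, 0.0
        head.layers[3].W.data, head.layers[3].b.data[:] = w2, 0.0
        head.out.W.data, head.out.b.data[:] = w3, 0.0
        z = np.array([0.5, -1.0, 2.0, 0.0, 1.0])
        # scalar oracle; BatchNorm in inference mode with fresh buffers is
        # x/sqrt(1+eps), included below
        h1 = np.maximum(z @ w1, 0) / np.sqrt(1 + 1e-5)
        h2 = np.maximum(h1 @ w2, 0) / np.sqrt(1 + 1e-5)
        logits = h2 @ w3
        expected = np.exp(logits - logits.max())
        expected /= expected.sum()
        probs = head_forward(z, head)
        assert np.abs(probs - expected).max() <= 1e-10

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            HeadConfig(n_classes=1)
        with pytest.raises(ValueError):
            HeadConfig(dropout_rate=1.0)


class TestSparseCeLoss:
    def test_perfect_prediction_is_zero(self):
        assert sparse_ce_loss(np.array([0.0, 1.0, 0.0]), 1) == pytest.approx(0.0)

    def test_half_probability_gives_ln_two(self):
        probs = np.array([0.5, 0.25, 0.25])
        assert sparse_ce_loss(probs, 0) == pytest.approx(np.log(2), abs=1e-9)

    def test_uniform_over_38_classes_gives_ln_38(self):
        probs = np.full(38, 1 / 38)
        for y in (0, 17, 37):
            assert sparse_ce_loss(probs, y) == pytest.approx(np.log(38), abs=1e-9)

    def test_batched_mean(self):
        probs = np.array([[0.5, 0.5], [0.25, 0.75]])
        expected = (np.log(2) - np.log(0.75)) / 2
        assert sparse_ce_loss(probs, [0, 1]) == pytest.approx(expected, abs=1e-12)

    def test_out_of_range_label_rejected(self):
        with pytest.raises(ValueError):
            sparse_ce_loss(np.array([0.5, 0.5]), 2)


class TestModelForward:
    def test_output_contract_and_determinism(self, rng):
        model = LeafFusionNet(small_config(), seed=1)
        img = rng.random((16, 16, 3)).astype(np.float32)
        p1, cache = model_forward(model, img)
        p2, _ = model_forward(model, img)
        assert p1.shape == (3,)
        assert p1.sum() == pytest.approx(1.0, abs=1e-6)
        np.testing.assert_array_equal(p1, p2)
        assert "F3" in cache and "Fpp" in cache

    def test_parameter_count_matches_analytic_sum(self):
        cfg = tiny_profile()
        model = LeafFusionNet(cfg, seed=0)
        counts = count_parameters(model)

        def dense(i, o, bias=True):
            return i * o + (o if bias else 0)

        c_in = 3 + 3 * 16  # passthrough + 8 orientations x 2 wavelengths
        cnn = dense(9 * c_in, 8) + dense(9 * 8, 16) + dense(9 * 16, 32)
        d, heads, hidden = 64, 2, 4 * 64
        block = (2 * d                      # ln1
                 + dense(d, 3 * d)          # qkv
                 + dense(d, d)              # proj
                 + 2 * d                    # ln2
                 + dense(d, hidden) + dense(hidden, d))
        n_tokens = (64 // 16) ** 2 + 1
        vit = dense(16 * 16 * 3, d) + d + n_tokens * d + 2 * block + 2 * d
        tam = 32 * 2 + 2 * 32 + dense(49, 1)  # bottleneck mlp + 7x7 conv
        fused = 32 + 64 + 32
        head = (dense(fused, 512) + 2 * 512 + dense(512, 256) + 2 * 256
                + dense(256, 4))
        assert counts["gabor"] == 0
        assert counts["cnn"] == cnn
        assert counts["vit"] == vit
        assert counts["tam"] == tam
        assert counts["head"] == head
        assert counts["total"] == cnn + vit + tam + head

    def test_softmax_normalisation_under_weight_fuzzing(self, rng):
        model = LeafFusionNet(small_config(), seed=0)
        img = rng.random((1, 16, 16, 3)).astype(np.float32)
        for draw in range(200):
            for p in model.parameters():
                p.data = rng.normal(scale=0.5, size=p.data.shape).astype(np.float32)
            with T.no_grad():
                probs = model(img, training=False).probs.data
            np.testing.assert_allclose(probs.sum(1), 1.0, atol=1e-6)

    def test_gabor_kernels_bit_identical_after_training_steps(self, rng):
        model = LeafFusionNet(small_config(dropout=0.1), seed=0)
        before = [k.copy() for k in model.bank.kernels]
        X = rng.random((8, 16, 16, 3)).astype(np.float32)
        y = rng.integers(0, 3, size=8)
        optim = nn.Adam(model.parameters(), lr=1e-3)
        for _ in range(3):
            out = model(X, training=True)
            loss = T.cross_entropy_with_logits(out.logits, y)
            optim.zero_grad()
            loss.backward()
            optim.step()
        for b, a in zip(before, model.bank.kernels):
            np.testing.assert_array_equal(b, a)
        assert count_parameters(model)["gabor"] == 0

    def test_loss_decreases_over_full_batch_steps(self, rng):
        model = LeafFusionNet(small_config(dropout=0.0), seed=3)
        X = rng.random((16, 16, 16, 3)).astype(np.float32)
        y = rng.integers(0, 3, size=16)
        optim = nn.Adam(model.parameters(), lr=1e-3)
        losses = []
        for _ in range(20):
            out = model(X, training=True)
            loss = T.cross_entropy_with_logits(out.logits, y)
            optim.zero_grad()
            loss.backward()
            optim.step()
            losses.append(loss.item())
        increases = sum(b > a + 1e-6 for a, b in zip(losses, losses[1:]))
        assert increases <= 2
        assert losses[-1] < losses[0]
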