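"""ConvMixer building blocks against naive oracles, plus training behaviour."""

import numpy as np
import pytest

from pouremg.convmixer import (
    BatchNormParams,
    ConvMixerNet,
    FeatureDenseNet,
    ModelConfig,
    _DepthwiseConv1d,
    _MixerBlock,
    _PatchEmbed,
    _PointwiseConv,
    batch_normalize,
    load_model,
    predict,
    save_model,
    softmax,
    train_model,
)


def small_config(**kw):
    defaults = dict(
        n_classes=2,
        hidden_dim=8,
        depth=1,
        kernel_size=3,
        patch_size=10,
        fusion_mode="none",
        epochs=5,
        batch_size=16,
        seed=0,
    )
    defaults.update(kw)
    return ModelConfig(**defaults)


def separable_dataset(rng, n_per_class=40, n=100):
    """Two amplitude classes of 4-channel noise windows, trivially separable."""
    lo = rng.standard_normal((n_per_class, 4, n)) * 0.2
    hi = rng.standard_normal((n_per_class, 4, n)) * 2.0
    x = np.concatenate([lo, hi])
    y = np.array([0] * n_per_class + [1] * n_per_class)
    order = rng.permutation(len(y))
    return x[order], y[order]


class TestBatchNormalize:
    def test_matches_naive_elementwise_formula(self, rng):
        x = rng.standard_normal((6, 5, 7))
        params = BatchNormParams(
            mu=rng.standard_normal(5),
            var=rng.uniform(0.1, 2.0, 5),
            gamma=rng.standard_normal(5),
            beta=rng.standard_normal(5),
        )
        eps = 1e-5
        got = batch_normalize(x, params, eps)
        naive = np.empty_like(x)
        for b in range(6):
            for c in range(5):
                for t in range(7):
                    naive[b, c, t] = (
                        (x[b, c, t] - params.mu[c]) / np.sqrt(params.var[c] + eps)
                    ) * params.gamma[c] + params.beta[c]
        np.testing.assert_allclose(got, naive, atol=1e-6)

    def test_identity_parameters_pass_input_through(self, rng):
        x = rng.standard_normal((3, 4, 5))
        params = BatchNormParams(np.zeros(4), np.ones(4), np.ones(4), np.zeros(4))
        np.testing.assert_allclose(batch_normalize(x, params, 1e-5), x, rtol=1e-4)

    def test_zero_gamma_gives_constant_beta(self, rng):
        x = rng.standard_normal((3, 4, 5))
        beta = rng.standard_normal(4)
        params = BatchNormParams(np.zeros(4), np.ones(4), np.zeros(4), beta)
        out = batch_normalize(x, params, 1e-5)
        np.testing.assert_allclose(out, np.broadcast_to(beta[None, :, None], out.shape))

    def test_non_positive_eps_rejected(self, rng):
        params = BatchNormParams(np.zeros(2), np.ones(2), np.ones(2), np.zeros(2))
        with pytest.raises(ValueError):
            batch_normalize(rng.standard_normal((1, 2)), params, 0.0)

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            BatchNormParams(np.zeros(2), -np.ones(2), np.ones(2), np.zeros(2))


class TestPatchEmbed:
    def test_481_samples_with_patch_13_gives_37_positions(self, rng):
        pe = _PatchEmbed(4, 13, 16, rng)
        out = pe.forward(rng.standard_normal((2, 4, 481)), training=False)
        assert out.shape == (2, 16, 481 // 13) == (2, 16, 37)

    def test_constant_input_gives_constant_embedding(self, rng):
        pe = _PatchEmbed(4, 7, 6, rng)
        out = pe.forward(np.ones((1, 4, 70)), training=False)
        np.testing.assert_allclose(out - out[:, :, :1], 0.0, atol=1e-12)

    @pytest.mark.parametrize("n,p,h", [(100, 10, 4), (481, 13, 64), (96, 4, 8), (55, 11, 3)])
    def test_shape_contract(self, rng, n, p, h):
        pe = _PatchEmbed(4, p, h, rng)
        out = pe.forward(rng.standard_normal((3, 4, n)), training=False)
        assert out.shape == (3, h, n // p)

    def test_patch_longer_than_window_rejected(self, rng):
        cfg = small_config(patch_size=10)
        net = ConvMixerNet(cfg)
        with pytest.raises(ValueError):
            net.forward(rng.standard_normal((1, 4, 5)))


class TestDepthwiseConv:
    def test_matches_naive_per_channel_convolution(self, rng):
        c, k, t = 5, 7, 12
        dw = _DepthwiseConv1d(c, k, rng)
        x = rng.standard_normal((2, c, t))
        got = dw.forward(x, training=False)
        pad = (k - 1) // 2
        naive = np.zeros_like(got)
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        for b in range(2):
            for ch in range(c):
                for i in range(t):
                    naive[b, ch, i] = (
                        np.dot(xp[b, ch, i : i + k], dw.params["W"][ch]) + dw.params["b"][ch]
                    )
        np.testing.assert_allclose(got, naive, atol=1e-5)

    def test_channelwise_locality(self, rng):
        """groups=C: perturbing channel j changes only channel j of output."""
        c, k, t = 6, 5, 20
        dw = _DepthwiseConv1d(c, k, rng)
        x = rng.standard_normal((1, c, t))
        base = dw.forward(x, training=False)
        for j in range(c):
            xp = x.copy()
            xp[0, j] += rng.standard_normal(t)
            out = dw.forward(xp, training=False)
            changed = np.any(np.abs(out - base) > 1e-12, axis=2)[0]
            assert changed[j]
            assert not changed[np.arange(c) != j].any()

    def test_pointwise_matches_matrix_product(self, rng):
        pw = _PointwiseConv(4, 3, rng)
        x = rng.standard_normal((2, 4, 9))
        got = pw.forward(x, training=False)
        for t in range(9):
            np.testing.assert_allclose(
                got[:, :, t], x[:, :, t] @ pw.params["W"].T + pw.params["b"], atol=1e-6
            )


class TestMixerBlock:
    def test_shape_preserved(self, rng):
        for h, k, t in [(8, 3, 10), (16, 9, 37), (4, 5, 6)]:
            blk = _MixerBlock(h, k, 1e-5, residual=True, rng=rng)
            x = rng.standard_normal((3, h, t))
            assert blk.forward(x, training=True).shape == x.shape

    def test_zero_depthwise_weights_make_stage_identity(self, rng):
        """With the depthwise kernel and bias zeroed and batch statistics,
        BN(GELU(0)) = 0, so the residual path passes the input unchanged."""
        blk = _MixerBlock(6, 3, 1e-5, residual=True, rng=rng)
        blk.dw.params["W"][:] = 0.0
        blk.dw.params["b"][:] = 0.0
        x = rng.standard_normal((4, 6, 11))
        np.testing.assert_allclose(blk.depthwise_stage(x, training=True), x, atol=1e-9)

    def test_empty_input_rejected(self, rng):
        blk = _MixerBlock(4, 3, 1e-5, residual=True, rng=rng)
        with pytest.raises(ValueError):
            blk.forward(np.zeros((0, 4, 5)), training=False)


class TestForward:
    def test_softmax_rows_sum_to_one(self, rng):
        net = ConvMixerNet(small_config())
        p = net.predict_proba(rng.standard_normal((5, 4, 100)))
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_fusion_none_ignores_features(self, rng):
        net = ConvMixerNet(small_config(fusion_mode="none"))
        x = rng.standard_normal((3, 4, 100))
        a = net.forward(x)
        b = net.forward(x, rng.standard_normal((3, 16)))
        np.testing.assert_array_equal(a, b)

    def test_zeroed_fusion_head_equals_unfused(self, rng):
        x = rng.standard_normal((3, 4, 100))
        f = rng.standard_normal((3, 16))
        fused = ConvMixerNet(small_config(fusion_mode="late_concat"))
        unfused = ConvMixerNet(small_config(fusion_mode="none"))
        h = fused.config.hidden_dim
        # identical trunk weights; zero the classifier rows for feature dims
        for (_, la, na), (_, lb, nb) in zip(unfused.parameters(), fused.parameters()):
            if la is unfused.classifier:
                lb.params[nb][:] = 0.0
                lb.params["W"][:h] = la.params["W"]
                lb.params["b"][:] = la.params["b"]
            else:
                lb.params[nb] = la.params[na].copy()
        np.testing.assert_allclose(fused.forward(x, f), unfused.forward(x), atol=1e-10)

    def test_missing_features_in_fusion_mode_rejected(self, rng):
        net = ConvMixerNet(small_config(fusion_mode="late_concat"))
        with pytest.raises(ValueError, match="requires feature"):
            net.forward(rng.standard_normal((2, 4, 100)))


class TestTraining:
    def test_separable_two_class_task_reaches_95_percent(self, rng):
        x, y = separable_dataset(rng)
        xv, yv = separable_dataset(np.random.default_rng(99), n_per_class=15)
        cfg = small_config(epochs=20)
        report = train_model(x, y, cfg, val_windows=xv, val_labels=yv)
        assert max(report.val_accuracy) >= 0.95

    def test_same_seed_gives_identical_first_epoch_loss(self, rng):
        x, y = separable_dataset(rng)
        losses = [
            train_model(x, y, small_config(epochs=1)).epoch_loss[0] for _ in range(2)
        ]
        assert losses[0] == losses[1]

    def test_loss_trends_downward_early(self, rng):
        x, y = separable_dataset(rng)
        report = train_model(x, y, small_config(epochs=5))
        assert report.epoch_loss[-1] < report.epoch_loss[0]
        assert max(report.epoch_loss[1:]) <= report.epoch_loss[0] + 1e-3

    def test_tiny_model_overfits_training_set(self, rng):
        x, y = separable_dataset(rng, n_per_class=10)
        cfg = small_config(epochs=30, hidden_dim=16)
        report = train_model(x, y, cfg)
        pred, _ = predict(report.model, x)
        assert np.mean(pred == y) == 1.0

    def test_absent_class_rejected(self, rng):
        x, y = separable_dataset(rng)  # classes {0, 1} only
        with pytest.raises(ValueError, match="absent"):
            train_model(x, y, small_config(n_classes=3))
        with pytest.raises(ValueError, match="2 classes"):
            train_model(x, np.zeros(len(x), dtype=int), small_config())

    def test_predict_is_deterministic(self, rng):
        x, y = separable_dataset(rng)
        report = train_model(x, y, small_config(epochs=2))
        p1 = predict(report.model, x)[1]
        p2 = predict(report.model, x)[1]
        np.testing.assert_array_equal(p1, p2)

    def test_feature_count_mismatch_rejected(self, rng):
        x, y = separable_dataset(rng)
        f = rng.standard_normal((len(x), 16))
        report = train_model(x, y, small_config(fusion_mode="late_concat"), features=f)
        with pytest.raises(ValueError):
            predict(report.model, x, f[:-1])

    def test_feature_dense_head_trains_on_features_alone(self, rng):
        f = np.concatenate([rng.standard_normal((30, 16)), rng.standard_normal((30, 16)) + 4.0])
        y = np.array([0] * 30 + [1] * 30)
        cfg = small_config(epochs=30)
        report = train_model(None, y, cfg, features=f, model_class=FeatureDenseNet)
        pred, _ = predict(report.model, None, f)
        assert np.mean(pred == y) >= 0.95


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, tmp_path, rng):
        x, y = separable_dataset(rng, n_per_class=10)
        f = np.abs(rng.standard_normal((len(x), 16)))
        report = train_model(
            x, y, small_config(epochs=2, fusion_mode="late_concat"), features=f
        )
        save_model(report.model, tmp_path / "ckpt.npz")
        back = load_model(tmp_path / "ckpt.npz")
        np.testing.assert_array_equal(
            predict(report.model, x, f)[1], predict(back, x, f)[1]
        )


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        small_config(kernel_size=4)  # even kernel
    with pytest.raises(ValueError):
        small_config(n_classes=1)
    with pytest.raises(ValueError):
        small_config(fusion_mode="early")
    with pytest.raises(ValueError):
        small_config(bn_epsilon=0.0)


def test_softmax_is_shift_invariant(rng):
    z = rng.standard_normal((4, 6))
    np.testing.assert_allclose(softmax(z), softmax(z + 100.0), atol=1e-12)
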