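"""UNet construction, training behaviour, inference and persistence."""

from dataclasses import replace

import numpy as np
import pytest

from triseg import nn
from triseg.datasets import Patch
from triseg.segnet import (
    TrainConfig,
    UNetConfig,
    build_model,
    load_model,
    predict_probmaps,
    save_model,
    train_model,
)

TINY = UNetConfig(depth=2, base_features=4, in_channels=1, dropout_bottom=0.0)


def random_patches(n, size=16, channels=1, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        out.append(
            Patch(
                image=rng.uniform(0, 1, (size, size, channels)),
                classes=rng.integers(0, 3, (size, size)),
                weights=np.ones((size, size)),
            )
        )
    return out


def blob_patches(n, size=16, seed=0):
    """Learnable toy task: a bright disk labeled center/contour."""
    from triseg.labels import instance_to_annotation

    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        inst = np.zeros((size, size), np.int32)
        r = int(rng.integers(3, 5))
        cy, cx = rng.integers(r + 1, size - r - 1, 2)
        yy, xx = np.mgrid[:size, :size]
        inst[(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] = 1
        pack = instance_to_annotation(inst, contour_width_px=1)
        img = 0.1 + 0.8 * (inst > 0) + rng.normal(0, 0.05, (size, size))
        out.append(
            Patch(
                image=np.clip(img, 0, 1)[:, :, None],
                classes=pack.classmap.astype(np.int64),
                weights=pack.gapweight,
            )
        )
    return out


class TestBuild:
    def test_same_seed_identical_parameters(self):
        m1 = build_model(TINY, seed=3)
        m2 = build_model(TINY, seed=3)
        for a, b in zip(m1.state_arrays(), m2.state_arrays()):
            np.testing.assert_array_equal(a, b)

    def test_channel_count_only_affects_first_layer(self):
        m1 = build_model(TINY, seed=0)
        m2 = build_model(replace(TINY, in_channels=2), seed=0)
        s1 = [s.value.shape for s in m1.param_slots()]
        s2 = [s.value.shape for s in m2.param_slots()]
        assert s1[0] != s2[0]  # first conv weight widens
        assert s1[1:] == s2[1:]

    def test_minimal_model_forward_shape(self):
        m = build_model(UNetConfig(depth=1, base_features=2, in_channels=1), seed=0)
        x = np.zeros((1, 16, 16, 1), np.float32)
        assert m.forward(x).shape == (1, 16, 16, 3)

    def test_incompatible_size_reported(self):
        m = build_model(TINY, seed=0)
        with pytest.raises(ValueError, match="divisible"):
            m.forward(np.zeros((1, 10, 10, 1), np.float32))


class TestGradients:
    def test_analytic_matches_numeric_directional_derivative(self):
        """Backprop oracle: float64 finite differences on a no-batchnorm
        model agree with the analytic directional derivative."""
        cfg = UNetConfig(
            depth=2, base_features=3, in_channels=2,
            dropout_bottom=0.0, batch_norm=False,
        )
        m = build_model(cfg, seed=1)
        for blk in m._modules():
            layers = blk.layers if isinstance(blk, nn.Block) else [blk]
            for l in layers:
                for a in ("w", "b", "gw", "gb"):
                    if hasattr(l, a):
                        setattr(l, a, getattr(l, a).astype(np.float64))
        rng = np.random.default_rng(0)
        x = rng.standard_normal((2, 8, 8, 2))
        y = rng.integers(0, 3, (2, 8, 8))
        w = rng.uniform(1, 2, (2, 8, 8))

        def loss():
            return nn.weighted_cross_entropy(m.forward(x, training=True), y, w)

        _, d = loss()
        m.backward(d)
        slots = list(m.param_slots())
        vs = [rng.standard_normal(s.value.shape) for s in slots]
        ana = sum(float((s.grad * v).sum()) for s, v in zip(slots, vs))
        eps = 1e-6
        for s, v in zip(slots, vs):
            s.value += eps * v
        lp, _ = loss()
        for s, v in zip(slots, vs):
            s.value -= 2 * eps * v
        lm, _ = loss()
        num = (lp - lm) / (2 * eps)
        assert num == pytest.approx(ana, rel=1e-5)

    def test_conv_forward_matches_scipy(self):
        from scipy import ndimage as ndi

        rng = np.random.default_rng(2)
        conv = nn.Conv2d(2, 3, 3, rng)
        x = rng.standard_normal((1, 10, 10, 2)).astype(np.float32)
        y = conv.forward(x, training=False)
        w4 = conv.w.reshape(3, 3, 2, 3)
        for co in range(3):
            expect = conv.b[co]
            for ci in range(2):
                expect = expect + ndi.correlate(
                    x[0, :, :, ci], w4[:, :, ci, co], mode="constant"
                )
            np.testing.assert_allclose(y[0, :, :, co], expect, atol=1e-5)


class TestTraining:
    def test_overfits_single_batch(self):
        patches = blob_patches(4, seed=1)
        model = build_model(TINY, seed=0)
        cfg = TrainConfig(
            batch_size=4, learning_rate=3e-3, max_epochs=200, max_steps=200,
            early_stopping_patience=200, l1_weight=0.0, seed=0,
        )
        train_model(model, patches, patches, cfg)
        first = model.history[0]["train_loss"]
        last = model.history[-1]["train_loss"]
        assert last < 0.25 * first

    def test_validation_loss_improves(self):
        train_p = blob_patches(12, seed=2)
        val_p = blob_patches(4, seed=3)
        model = build_model(TINY, seed=0)
        cfg = TrainConfig(
            batch_size=4, learning_rate=3e-3, max_epochs=50, max_steps=120,
            early_stopping_patience=50, seed=0,
        )
        train_model(model, train_p, val_p, cfg)
        assert model.history[-1]["val_loss"] < model.history[0]["val_loss"]

    def test_neutral_weights_equal_unweighted_loss(self):
        rng = np.random.default_rng(0)
        logits = rng.standard_normal((2, 8, 8, 3)).astype(np.float32)
        y = rng.integers(0, 3, (2, 8, 8))
        loss_w, _ = nn.weighted_cross_entropy(logits, y, np.ones((2, 8, 8)))
        p = nn.softmax(logits)
        py = np.take_along_axis(p, y[..., None], axis=-1)
        loss_ref = float(-np.log(py).mean())
        assert loss_w == pytest.approx(loss_ref, rel=1e-6)

    def test_reproducible_history(self):
        patches = blob_patches(6, seed=4)
        cfg = TrainConfig(
            batch_size=3, learning_rate=1e-3, max_epochs=5, max_steps=10,
            early_stopping_patience=5, seed=7,
        )
        h = []
        for _ in range(2):
            model = build_model(TINY, seed=9)
            train_model(model, patches, patches, cfg)
            h.append([e["train_loss"] for e in model.history])
        assert h[0] == h[1]

    def test_empty_train_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train_model(build_model(TINY, seed=0), [], [], TrainConfig(seed=0))


@pytest.fixture(scope="module")
def model():
    return build_model(TINY, seed=2)


class TestInference:

    def test_probabilities_normalized(self, model):
        rng = np.random.default_rng(0)
        probs = predict_probmaps(model, rng.uniform(0, 1, (40, 52)))
        assert probs.probs.shape == (40, 52, 3)
        np.testing.assert_allclose(probs.probs.sum(axis=2), 1.0, atol=1e-9)

    def test_tiled_matches_untiled(self, model):
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 1, (128, 128))
        whole = predict_probmaps(model, img, tile_px=128)
        tiled = predict_probmaps(model, img, tile_px=96, overlap_px=64)
        assert np.abs(whole.probs - tiled.probs).max() < 1e-4

    def test_argmax_classmap_shape(self, model):
        rng = np.random.default_rng(2)
        probs = predict_probmaps(model, rng.uniform(0, 1, (30, 30)))
        assert probs.argmax_classmap().shape == (30, 30)

    def test_channel_mismatch_named(self, model):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError, match="channels"):
            predict_probmaps(model, rng.uniform(0, 1, (32, 32, 2)))

    def test_save_load_round_trip(self, model, tmp_path):
        rng = np.random.default_rng(4)
        img = rng.uniform(0, 1, (32, 32))
        before = predict_probmaps(model, img).probs
        save_model(model, tmp_path / "ckpt")
        back = load_model(tmp_path / "ckpt")
        after = predict_probmaps(back, img).probs
        np.testing.assert_array_equal(before, after)
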