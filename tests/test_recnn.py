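import numpy as np
import pytest

from adstage import (
    GrayImage,
    RECNNConfig,
    build_recnn,
    forward_features,
    forward_features_batch,
    train_extractor,
)
from adstage.recnn import (
    _backward_graph,
    _forward_graph,
    load_checkpoint,
    save_checkpoint,
)


def tiny_cfg(**kw):
    base = dict(scale=1 / 64, input_size=32, seed=0)
    base.update(kw)
    return RECNNConfig(**base)


class TestArchitecture:
    def test_full_scale_structural_audit(self):
        cfg = RECNNConfig()
        model = build_recnn(cfg)
        assert cfg.n_conv_layers == 3
        assert cfg.n_pool_layers == 4
        assert model.conv_layer_shapes == [(512, 5), (1024, 7), (512, 7)]
        assert cfg.feature_length == 1024 + 1024 + 512 == 2560

    def test_scaled_filter_counts(self):
        cfg = tiny_cfg()
        assert (cfg.c1, cfg.c2, cfg.c3) == (8, 16, 8)
        assert cfg.feature_length == 16 + 16 + 8 == 40

    @pytest.mark.parametrize("size", [64, 128, 256])
    def test_spatial_bookkeeping(self, size):
        # two stride-2 pools along each path: tapped maps at size/4,
        # except Pool2 which sits one pool deep at size/2
        cfg = RECNNConfig(scale=1 / 128, input_size=size, seed=0)
        model = build_recnn(cfg)
        x = np.zeros((1, 1, size, size))
        feat, cache = _forward_graph(model, x, need_cache=True)
        assert cache["shapes"]["p2"][2:] == (size // 2, size // 2)
        assert cache["shapes"]["p3"][2:] == (size // 4, size // 4)
        assert cache["shapes"]["p4"][2:] == (size // 4, size // 4)

    def test_input_size_must_be_divisible_by_four(self):
        with pytest.raises(ValueError):
            RECNNConfig(input_size=30)

    def test_scale_bounds(self):
        with pytest.raises(ValueError):
            RECNNConfig(scale=0.0)
        assert RECNNConfig(scale=1 / 10000).c1 == 1  # floor at one filter


class TestForward:
    def test_feature_length_and_determinism(self, rng):
        cfg = tiny_cfg()
        model = build_recnn(cfg)
        img = GrayImage(rng.random((32, 32)))
        f1 = forward_features(model, img)
        f2 = forward_features(model, img)
        assert f1.shape == (40,)
        assert np.all(np.isfinite(f1))
        assert f1.tobytes() == f2.tobytes()

    def test_batch_permutation_equivariance(self, rng):
        cfg = tiny_cfg()
        model = build_recnn(cfg)
        imgs = [GrayImage(rng.random((32, 32))) for _ in range(4)]
        F = forward_features_batch(model, imgs)
        Fr = forward_features_batch(model, imgs[::-1])
        np.testing.assert_array_equal(F[::-1], Fr)

    def test_shape_mismatch_rejected(self, rng):
        model = build_recnn(tiny_cfg())
        with pytest.raises(ValueError):
            forward_features(model, GrayImage(rng.random((16, 16))))

    def test_gradient_matches_numerical(self):
        # analytic backward vs central differences on a tiny graph
        cfg = RECNNConfig(scale=1 / 256, input_size=8, conv1_kernel=3,
                          conv2_kernel=3, conv3_kernel=3, seed=1)
        model = build_recnn(cfg)
        rng = np.random.default_rng(0)
        x = rng.random((2, 1, 8, 8))
        v = rng.random((2, cfg.feature_length))
        _, cache = _forward_graph(model, x, True)
        grads = _backward_graph(model, v, cache)
        eps = 1e-6
        for key in ("W1", "W2", "W3", "b1", "b2", "b3"):
            w = model.weights[key]
            idx = tuple(0 for _ in w.shape)
            w[idx] += eps
            f1, _ = _forward_graph(model, x, False)
            w[idx] -= 2 * eps
            f0, _ = _forward_graph(model, x, False)
            w[idx] += eps
            num = ((f1 - f0) / (2 * eps) * v).sum()
            assert grads[key][idx] == pytest.approx(num, rel=1e-5, abs=1e-8)


class TestTraining:
    def _separable_set(self, n_per_class=8, seed=0):
        rng = np.random.default_rng(seed)
        imgs, labels = [], []
        for _ in range(n_per_class):
            bright = np.clip(0.8 + 0.05 * rng.standard_normal((32, 32)), 0, 1)
            dark = np.clip(0.2 + 0.05 * rng.standard_normal((32, 32)), 0, 1)
            imgs += [GrayImage(bright), GrayImage(dark)]
            labels += ["A", "B"]
        return imgs, labels

    def test_epochs_zero_keeps_weights(self):
        model = build_recnn(tiny_cfg())
        imgs, labels = self._separable_set(2)
        out = train_extractor(model, imgs, labels, epochs=0)
        for k in model.weights:
            np.testing.assert_array_equal(out.weights[k], model.weights[k])

    def test_single_class_rejected(self):
        model = build_recnn(tiny_cfg())
        imgs, _ = self._separable_set(2)
        with pytest.raises(ValueError):
            train_extractor(model, imgs, ["A"] * len(imgs), epochs=1)

    def test_seeded_training_reproducible(self):
        imgs, labels = self._separable_set(4)
        outs = []
        for _ in range(2):
            model = build_recnn(tiny_cfg(seed=3))
            out = train_extractor(model, imgs, labels, epochs=2, seed=9)
            outs.append(out)
        for k in outs[0].weights:
            assert outs[0].weights[k].tobytes() == outs[1].weights[k].tobytes()

    def test_loss_decreases_and_probe_separates(self):
        imgs, labels = self._separable_set(8, seed=5)
        model = build_recnn(tiny_cfg(seed=5))
        out = train_extractor(model, imgs, labels, epochs=5, seed=5)
        lc = out.meta["loss_curve"]
        assert lc[-1] < lc[0]
        # nearest-class-mean probe on held-out images
        test_imgs, test_labels = self._separable_set(4, seed=99)
        F = forward_features_batch(out, imgs)
        Ft = forward_features_batch(out, test_imgs)
        mu = {c: F[np.asarray(labels) == c].mean(axis=0) for c in ("A", "B")}
        pred = [
            min(mu, key=lambda c: np.linalg.norm(f - mu[c])) for f in Ft
        ]
        acc = np.mean([p == t for p, t in zip(pred, test_labels)])
        assert acc >= 0.95


class TestCheckpoint:
    def test_round_trip(self, tmp_path, rng):
        model = build_recnn(tiny_cfg(seed=2))
        path = tmp_path / "m.npz"
        save_checkpoint(model, path)
        back = load_checkpoint(path)
        assert back.cfg == model.cfg
        img = GrayImage(rng.random((32, 32)))
        np.testing.assert_array_equal(
            forward_features(back, img), forward_features(model, img)
        )
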