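import numpy as np
import pytest

from petfusion._nn import softmax_ce
from petfusion.localnet import (LocalEncoder, LocalNetConfig, TrainConfig, extract_local_latents,
                                layer_cam, local_latent_names, prepare_input, train_network)
from petfusion.volume import Volume3D

TINY = LocalNetConfig(input_shape=(13, 13, 13),
                      layers=((2, 3, 1), (3, 3, 2), (4, 3, 3)), n_classes=2)


class TestConfig:
    def test_receptive_field_formula(self):
        assert LocalNetConfig().receptive_field == 13
        assert LocalNetConfig.desk_scale().receptive_field == 13

    def test_dilations_must_increase(self):
        with pytest.raises(ValueError):
            LocalNetConfig(layers=((4, 3, 2), (8, 3, 2), (16, 3, 3)))

    def test_input_smaller_than_receptive_field_rejected(self):
        with pytest.raises(ValueError):
            LocalNetConfig(input_shape=(12, 13, 13),
                           layers=((2, 3, 1), (3, 3, 2), (4, 3, 3)))

    def test_latent_dim_is_last_layer_width(self):
        assert LocalNetConfig().latent_dim == 128
        assert local_latent_names(3) == ["Local_latent_0", "Local_latent_1", "Local_latent_2"]


class TestForwardBackward:
    def test_forward_shapes(self):
        net = LocalEncoder(TINY, seed=0)
        cache = net.forward(np.random.default_rng(0).standard_normal((13, 13, 13)).astype(np.float32))
        assert cache["latent"].shape == (4,)
        assert cache["logits"].shape == (2,)
        assert cache["last"].shape == (4, 13, 13, 13)

    def test_wrong_input_shape_rejected(self):
        net = LocalEncoder(TINY, seed=0)
        with pytest.raises(ValueError):
            net.forward(np.zeros((13, 13, 12), np.float32))

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(1)
        net = LocalEncoder(TINY, seed=1)
        x = rng.standard_normal((13, 13, 13)).astype(np.float32)
        cache = net.forward(x, keep=True)
        loss, dlogits = softmax_ce(cache["logits"], 1)
        for p in net.params.values():
            p.grad[...] = 0.0
        net.backward(cache, dlogits)
        eps = 1e-3
        for name in ("conv1_w", "conv3_w", "head_w", "conv2_b"):
            p = net.params[name]
            flat = p.value.ravel()
            for j in rng.choice(flat.size, size=3, replace=False):
                orig = flat[j]
                flat[j] = orig + eps
                lp, _ = softmax_ce(net.forward(x)["logits"], 1)
                flat[j] = orig - eps
                lm, _ = softmax_ce(net.forward(x)["logits"], 1)
                flat[j] = orig
                fd = (lp - lm) / (2 * eps)
                an = p.grad.ravel()[j]
                assert an == pytest.approx(fd, abs=2e-3 + 5e-2 * abs(fd)), name

    def test_unknown_layer_and_class_rejected(self):
        net = LocalEncoder(TINY, seed=0)
        x = np.zeros((13, 13, 13), np.float32)
        with pytest.raises(KeyError):
            net.activation_and_gradient(x, 0, "conv9")
        with pytest.raises(IndexError):
            net.activation_and_gradient(x, 5, "conv1")


class TestTraining:
    @staticmethod
    def _separable_data(n_per_class=12, seed=0):
        rng = np.random.default_rng(seed)
        xs, labels = [], []
        for cls, mu in (("A", -1.0), ("B", 1.0)):
            for _ in range(n_per_class):
                xs.append((mu + 0.3 * rng.standard_normal((13, 13, 13))).astype(np.float32))
                labels.append(cls)
        return xs, labels

    def test_training_separates_classes(self):
        xs, labels = self._separable_data()
        net = LocalEncoder(TINY, seed=0)
        train_network(net, xs, labels, TrainConfig(lr=3e-3, epochs=6, batch_size=8,
                                                   val_fraction=0.0, seed=0,
                                                   head_warmup_epochs=20))
        pred = [int(np.argmax(net.predict_logits(x))) for x in xs]
        y = [0 if l == "A" else 1 for l in labels]
        acc = np.mean(np.asarray(pred) == np.asarray(y))
        assert acc >= 0.9
        # warmup already separates the blobs, so training loss sits far below
        # the chance level ln(2)
        assert net.train_log[-1]["train_loss"] < 0.5

    def test_training_deterministic(self):
        xs, labels = self._separable_data(n_per_class=6)
        cfg = TrainConfig(lr=3e-3, epochs=2, batch_size=4, val_fraction=0.0, seed=7,
                          head_warmup_epochs=4)
        a = train_network(LocalEncoder(TINY, seed=3), xs, labels, cfg)
        b = train_network(LocalEncoder(TINY, seed=3), xs, labels, cfg)
        for k in a.params:
            assert np.array_equal(a.params[k].value, b.params[k].value), k

    def test_class_count_mismatch_rejected(self):
        xs, labels = self._separable_data(n_per_class=2)
        net = LocalEncoder(LocalNetConfig(input_shape=(13, 13, 13),
                                          layers=TINY.layers, n_classes=3), seed=0)
        with pytest.raises(ValueError):
            train_network(net, xs, labels, TrainConfig(epochs=1))

    def test_calibrated_latents_standardized(self):
        xs, labels = self._separable_data(n_per_class=8)
        net = LocalEncoder(TINY, seed=0)
        net.calibrate_latent(xs)
        lat = np.stack([net.latent(x) for x in xs])
        assert np.allclose(lat.mean(axis=0), 0, atol=1e-5)
        assert np.allclose(lat.std(axis=0), 1, atol=1e-4)


class TestLayerCam:
    def test_map_range_shape_and_upsampling(self):
        net = LocalEncoder(TINY, seed=0)
        x = np.random.default_rng(0).standard_normal((13, 13, 13)).astype(np.float32)
        amap = layer_cam(net, x, 0, layer="conv2", target_shape=(26, 26, 26), spacing=(2, 2, 2))
        assert amap.data.shape == (26, 26, 26)
        assert amap.data.min() >= 0.0 and amap.data.max() <= 1.0
        assert amap.source == "layer_cam"

    def test_positive_channel_gradients_are_head_weights(self):
        # with a frozen 1-hidden-stack GAP head, dy_c/dA_k = w_ck / (sigma_k * nvox)
        net = LocalEncoder(TINY, seed=2)
        x = np.random.default_rng(2).standard_normal((13, 13, 13)).astype(np.float32)
        acts, grads = net.activation_and_gradient(x, 1, "conv3")
        nvox = acts[0].size
        expected = net.params["head_w"].value[1] / (net.latent_sigma * nvox)
        got = grads.reshape(grads.shape[0], -1)
        assert np.allclose(got, expected[:, None], atol=1e-7)

    def test_prepare_input_resamples(self):
        v = Volume3D(np.random.default_rng(0).random((40, 48, 35)), (4, 4, 4))
        x = prepare_input(v, (20, 24, 18))
        assert x.shape == (20, 24, 18)
        assert x.dtype == np.float32
        lat = extract_local_latents(LocalEncoder(LocalNetConfig.desk_scale(), seed=0), v)
        assert lat.shape == (16,)
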