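import numpy as np
import pytest

from petfusion._nn import softmax_ce
from petfusion.globalnet import (AttentionStack, GlobalEncoder, GlobalNetConfig,
                                 attention_rollout, extract_global_latents,
                                 global_latent_names, patchify, prepare_global_input,
                                 rollout_map, train_global_network)
from petfusion.localnet import TrainConfig

TINY = GlobalNetConfig(input_shape=(12, 12, 6), patch_kernel=6, patch_stride=6,
                       embed_dim=8, depth=2, heads=2, n_classes=2)


class TestConfig:
    def test_grid_and_token_counts(self):
        cfg = GlobalNetConfig()
        assert cfg.grid_dims == (25, 31, 21)
        assert cfg.n_tokens == cfg.n_patches + 1
        desk = GlobalNetConfig.desk_scale()
        assert desk.grid_dims == (4, 5, 3)
        assert desk.n_patches == 60

    def test_validation(self):
        with pytest.raises(ValueError):
            GlobalNetConfig(patch_kernel=4, patch_stride=6)
        with pytest.raises(ValueError):
            GlobalNetConfig(embed_dim=30, heads=4)
        with pytest.raises(ValueError):
            GlobalNetConfig(input_shape=(4, 30, 18), patch_kernel=6)


class TestPatchify:
    def test_patches_match_direct_slicing(self):
        rng = np.random.default_rng(0)
        data = rng.random((12, 18, 6))
        patches, grid, origins = patchify(data, 6, 6)
        assert grid == (2, 3, 1)
        assert patches.shape == (6, 216)
        for p, (i, j, k) in zip(patches, origins):
            want = data[i:i + 6, j:j + 6, k:k + 6].ravel()
            assert np.allclose(p, want, atol=1e-6)

    def test_overlapping_stride(self):
        data = np.zeros((12, 12, 12))
        patches, grid, origins = patchify(data, 6, 3)
        assert grid == (3, 3, 3)
        assert len(origins) == 27


class TestRollout:
    def test_matches_matrix_chain_oracle(self):
        rng = np.random.default_rng(0)
        stack = []
        for _ in range(3):
            a = rng.random((2, 5, 5))
            a /= a.sum(axis=-1, keepdims=True)
            stack.append(a)
        got = attention_rollout(AttentionStack(stack))
        roll = np.eye(5)
        for a in stack:
            aug = a.mean(axis=0) + np.eye(5)
            aug /= aug.sum(axis=1, keepdims=True)
            roll = aug @ roll
        assert np.allclose(got, roll, atol=1e-10)
        assert np.allclose(got.sum(axis=1), 1.0, atol=1e-10)

    def test_identity_attention_rolls_to_identity(self):
        eye = np.repeat(np.eye(4)[None], 2, axis=0)
        got = attention_rollout(AttentionStack([eye, eye]))
        assert np.allclose(got, np.eye(4), atol=1e-12)

    def test_non_stochastic_rows_rejected(self):
        with pytest.raises(ValueError):
            AttentionStack([np.ones((2, 3, 3))])


class TestEncoder:
    def test_context_token_permutation_invariance(self):
        rng = np.random.default_rng(1)
        net = GlobalEncoder(TINY, seed=1)
        patches, _, _ = patchify(rng.random(TINY.input_shape), 6, 6)
        base = net.forward(patches)
        # perm reorders token/positional-row pairs jointly; the pooled context
        # token must not depend on the token order
        perm = rng.permutation(TINY.n_patches)
        permuted = net.forward(patches, perm=perm)
        assert np.allclose(base["latent"], permuted["latent"], atol=1e-10)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(2)
        net = GlobalEncoder(TINY, seed=2)
        patches, _, _ = patchify(rng.random(TINY.input_shape), 6, 6)
        cache = net.forward(patches, keep=True)
        _, dlogits = softmax_ce(cache["logits"], 0)
        for p in net.params.values():
            p.grad[...] = 0.0
        net.backward(cache, dlogits.astype(np.float64))
        eps = 1e-3
        for name in ("embed_w", "l0_wq", "l1_w1", "pos", "head_w", "lnf_g"):
            p = net.params[name]
            flat = p.value.ravel()
            for j in rng.choice(flat.size, size=3, replace=False):
                orig = flat[j]
                flat[j] = orig + eps
                lp, _ = softmax_ce(net.logits(patches), 0)
                flat[j] = orig - eps
                lm, _ = softmax_ce(net.logits(patches), 0)
                flat[j] = orig
                fd = (lp - lm) / (2 * eps)
                an = p.grad.ravel()[j]
                assert an == pytest.approx(fd, abs=2e-3 + 5e-2 * abs(fd)), name

    def test_attention_stack_is_row_stochastic(self):
        net = GlobalEncoder(TINY, seed=0)
        patches, _, _ = patchify(np.random.default_rng(0).random(TINY.input_shape), 6, 6)
        stack = net.attention_stack(patches)   # validates in __post_init__
        assert len(stack.attentions) == TINY.depth


class TestTrainingAndMaps:
    @staticmethod
    def _separable(n=10, seed=0):
        rng = np.random.default_rng(seed)
        vols, labels = [], []
        for cls, mu in (("A", -1.0), ("B", 1.0)):
            for _ in range(n):
                vols.append(mu + 0.3 * rng.standard_normal(TINY.input_shape))
                labels.append(cls)
        return vols, labels

    def test_training_separates_classes_and_is_deterministic(self):
        vols, labels = self._separable()
        cfg = TrainConfig(lr=1e-3, epochs=6, batch_size=8, val_fraction=0.0, seed=0)
        net = train_global_network(GlobalEncoder(TINY, seed=0), vols, labels, cfg)
        pred = []
        for v in vols:
            patches, _, _ = patchify(prepare_global_input(v, TINY.input_shape), 6, 6)
            pred.append(int(np.argmax(net.logits(patches))))
        y = [0 if l == "A" else 1 for l in labels]
        assert np.mean(np.asarray(pred) == np.asarray(y)) >= 0.9
        net2 = train_global_network(GlobalEncoder(TINY, seed=0), vols, labels, cfg)
        for k in net.params:
            assert np.array_equal(net.params[k].value, net2.params[k].value), k

    def test_latents_and_rollout_map_contract(self):
        net = GlobalEncoder(TINY, seed=0)
        vol = np.random.default_rng(3).random((24, 24, 12))
        lat = extract_global_latents(net, vol)
        assert lat.shape == (TINY.embed_dim,)
        assert global_latent_names(2) == ["Global_latent_0", "Global_latent_1"]
        amap = rollout_map(net, vol, target_shape=(24, 24, 12), spacing=(2, 2, 2))
        assert amap.data.shape == (24, 24, 12)
        assert amap.data.min() >= 0.0 and amap.data.max() <= 1.0
        assert amap.source == "rollout"
        again = rollout_map(net, vol, target_shape=(24, 24, 12), spacing=(2, 2, 2))
        assert np.array_equal(amap.data, again.data)
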