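"""The global channel: 3-D patch-embedding Transformer with rollout maps.

Volumes are resampled to the configured input grid and cut into
(overlapping, when stride < kernel) 6x6x6 patches by a convolutional
patch embedding.  A pooled context token — the global average of the patch
embeddings — is prepended to the patch sequence (it plays the class-token
role for both latent extraction and rollout attribution), learned
positional encodings are added, and the sequence passes through a pre-LN
Transformer encoder whose per-layer attention matrices are exposed.

Rollout attribution: per layer, heads are averaged, the identity is added
(residual path) and rows re-normalized; the rollout matrix is the ordered
product over layers.  The context-token row over patch tokens is painted
uniformly onto each token's voxel footprint (overlaps averaged) and
min-max normalized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ._nn import Adam, Param, he_normal, relu, relu_grad, softmax, softmax_ce
from .localnet import TrainConfig, _class_codes
from .volume import AttributionVolume, Volume3D

__all__ = ["GlobalNetConfig", "AttentionStack", "GlobalEncoder", "patchify",
           "build_global_encoder", "train_global_network", "extract_global_latents",
           "attention_rollout", "rollout_map", "global_latent_names", "prepare_global_input"]


@dataclass(frozen=True)
class GlobalNetConfig:
    input_shape: tuple[int, int, int] = (78, 96, 66)
    patch_kernel: int = 6
    patch_stride: int = 3
    embed_dim: int = 64
    depth: int = 4
    heads: int = 4
    mlp_ratio: int = 2
    n_classes: int = 3

    def __post_init__(self) -> None:
        if self.patch_stride > self.patch_kernel:
            raise ValueError("stride must not exceed kernel (patches must tile the grid)")
        if any(self.patch_kernel > s for s in self.input_shape):
            raise ValueError("patch kernel exceeds input shape")
        if self.embed_dim % self.heads:
            raise ValueError("embed dim must be divisible by the number of heads")

    @property
    def grid_dims(self) -> tuple[int, int, int]:
        return tuple((s - self.patch_kernel) // self.patch_stride + 1 for s in self.input_shape)

    @property
    def n_patches(self) -> int:
        return int(np.prod(self.grid_dims))

    @property
    def n_tokens(self) -> int:
        return self.n_patches + 1  # + context token

    @property
    def latent_dim(self) -> int:
        return self.embed_dim

    @staticmethod
    def desk_scale(n_classes: int = 3) -> "GlobalNetConfig":
        return GlobalNetConfig(input_shape=(24, 30, 18), patch_kernel=6, patch_stride=6,
                               embed_dim=32, depth=2, heads=4, n_classes=n_classes)


def global_latent_names(dim: int) -> list[str]:
    return [f"Global_latent_{i}" for i in range(dim)]


def prepare_global_input(volume: Volume3D | np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    data = volume.data if isinstance(volume, Volume3D) else volume
    data = np.asarray(data, dtype=np.float64)
    if tuple(data.shape) == tuple(shape):
        return data.astype(np.float32)
    zoom = [t / s for t, s in zip(shape, data.shape)]
    return ndimage.zoom(data, zoom, order=1).astype(np.float32)


def patchify(data: np.ndarray, kernel: int, stride: int):
    """Sliding-window patches plus each token's voxel footprint.

    Returns ``(patches, grid_dims, origins)`` where patches is
    (P, kernel^3) and origins holds each patch's start voxel.
    """
    data = np.asarray(data)
    if any(kernel > s for s in data.shape):
        raise ValueError("kernel exceeds volume shape")
    win = np.lib.stride_tricks.sliding_window_view(data, (kernel,) * 3)
    win = win[::stride, ::stride, ::stride]
    grid_dims = win.shape[:3]
    patches = win.reshape(-1, kernel ** 3)
    origins = np.stack(np.meshgrid(*[np.arange(g) * stride for g in grid_dims],
                                   indexing="ij"), axis=-1).reshape(-1, 3)
    return patches.astype(np.float32), grid_dims, origins


@dataclass
class AttentionStack:
    """Per-layer, per-head row-stochastic attention matrices."""

    attentions: list[np.ndarray]  # each (heads, T, T)

    def __post_init__(self) -> None:
        sizes = set()
        for a in self.attentions:
            a = np.asarray(a)
            if a.ndim != 3 or a.shape[1] != a.shape[2]:
                raise ValueError("attention matrices must be (heads, T, T)")
            if not np.allclose(a.sum(axis=-1), 1.0, atol=1e-5):
                raise ValueError("attention rows must sum to 1")
            sizes.add(a.shape[1])
        if len(sizes) > 1:
            raise ValueError("inconsistent token count across layers")


def attention_rollout(stack: AttentionStack) -> np.ndarray:
    """R = A_hat_L ... A_hat_1 with A_hat = row-normalized (mean_heads(A) + I)."""
    rollout = None
    for a in stack.attentions:
        mean = np.asarray(a, dtype=np.float64).mean(axis=0)
        aug = mean + np.eye(mean.shape[0])
        aug /= aug.sum(axis=1, keepdims=True)
        rollout = aug if rollout is None else aug @ rollout
    if rollout is None:
        raise ValueError("empty attention stack")
    return rollout


class GlobalEncoder:
    """Pre-LN Transformer encoder over [context ‖ patch] tokens."""

    def __init__(self, config: GlobalNetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        E, T = config.embed_dim, config.n_tokens
        k3 = config.patch_kernel ** 3
        P = self.params = {}
        P["embed_w"] = Param(he_normal(rng, (k3, E), k3))
        P["embed_b"] = Param(np.zeros(E, dtype=np.float32))
        P["pos"] = Param(0.02 * rng.standard_normal((T, E)).astype(np.float32))
        H = config.mlp_ratio * E
        for l in range(config.depth):
            for nm, shape, fan in (("wq", (E, E), E), ("wk", (E, E), E), ("wv", (E, E), E),
                                   ("wo", (E, E), E), ("w1", (E, H), E), ("w2", (H, E), H)):
                P[f"l{l}_{nm}"] = Param(he_normal(rng, shape, fan))
            for nm, dim in (("bq", E), ("bk", E), ("bv", E), ("bo", E), ("b1", H), ("b2", E)):
                P[f"l{l}_{nm}"] = Param(np.zeros(dim, dtype=np.float32))
            for nm in ("ln1_g", "ln2_g"):
                P[f"l{l}_{nm}"] = Param(np.ones(E, dtype=np.float32))
            for nm in ("ln1_b", "ln2_b"):
                P[f"l{l}_{nm}"] = Param(np.zeros(E, dtype=np.float32))
        P["lnf_g"] = Param(np.ones(E, dtype=np.float32))
        P["lnf_b"] = Param(np.zeros(E, dtype=np.float32))
        P["head_w"] = Param(he_normal(rng, (config.n_classes, E), E))
        P["head_b"] = Param(np.zeros(config.n_classes, dtype=np.float32))
        self.train_log: list[dict] = []

    def param_list(self):
        return list(self.params.values())

    def parameter_count(self) -> int:
        return int(sum(p.value.size for p in self.params.values()))

    # ------------------------------------------------------------ layernorm
    @staticmethod
    def _ln_forward(x, g, b, eps=1e-5):
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc ** 2).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = xc * inv
        return xhat * g + b, (xhat, inv, g)

    @staticmethod
    def _ln_backward(dy, cache):
        xhat, inv, g = cache
        dg = (dy * xhat).sum(axis=0)
        db = dy.sum(axis=0)
        dxhat = dy * g
        n = xhat.shape[-1]
        dx = inv * (dxhat - dxhat.mean(axis=-1, keepdims=True)
                    - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True))
        return dx, dg, db

    # -------------------------------------------------------------- forward
    def forward(self, patches: np.ndarray, keep: bool = False, perm: np.ndarray | None = None) -> dict:
        cfg = self.config
        P = self.params
        tok = patches.astype(np.float32) @ P["embed_w"].value + P["embed_b"].value
        ctx = tok.mean(axis=0)
        seq = np.vstack([ctx[None], tok])
        pos = P["pos"].value
        if perm is not None:
            order = np.concatenate([[0], 1 + np.asarray(perm)])
            seq = seq[order]
            pos = pos[order]
        h = (seq + pos).astype(np.float64)
        E, nh = cfg.embed_dim, cfg.heads
        dh = E // nh
        cache = {"patches": patches, "tok": tok, "layers": [], "attn": []}
        for l in range(cfg.depth):
            pre = h
            x1, ln1c = self._ln_forward(h, P[f"l{l}_ln1_g"].value, P[f"l{l}_ln1_b"].value)
            q = x1 @ P[f"l{l}_wq"].value + P[f"l{l}_bq"].value
            k = x1 @ P[f"l{l}_wk"].value + P[f"l{l}_bk"].value
            v = x1 @ P[f"l{l}_wv"].value + P[f"l{l}_bv"].value
            T = h.shape[0]
            qh = q.reshape(T, nh, dh).transpose(1, 0, 2)
            kh = k.reshape(T, nh, dh).transpose(1, 0, 2)
            vh = v.reshape(T, nh, dh).transpose(1, 0, 2)
            scores = qh @ kh.transpose(0, 2, 1) / np.sqrt(dh)
            attn = softmax(scores, axis=-1)                  # (nh, T, T)
            ctxh = attn @ vh                                 # (nh, T, dh)
            concat = ctxh.transpose(1, 0, 2).reshape(T, E)
            attn_out = concat @ P[f"l{l}_wo"].value + P[f"l{l}_bo"].value
            h1 = pre + attn_out
            x2, ln2c = self._ln_forward(h1, P[f"l{l}_ln2_g"].value, P[f"l{l}_ln2_b"].value)
            m1 = x2 @ P[f"l{l}_w1"].value + P[f"l{l}_b1"].value
            a1 = relu(m1)
            m2 = a1 @ P[f"l{l}_w2"].value + P[f"l{l}_b2"].value
            h = h1 + m2
            cache["attn"].append(attn)
            if keep:
                cache["layers"].append(dict(pre=pre, x1=x1, ln1c=ln1c, q=q, k=k, v=v,
                                            attn=attn, vh=vh, concat=concat, h1=h1,
                                            x2=x2, ln2c=ln2c, a1=a1))
        out, lnfc = self._ln_forward(h, P["lnf_g"].value, P["lnf_b"].value)
        latent = out[0]
        logits = P["head_w"].value @ latent.astype(np.float32) + P["head_b"].value
        cache.update(h_final=h, lnfc=lnfc, out=out, latent=latent, logits=logits)
        return cache

    # ------------------------------------------------------------- backward
    def backward(self, cache: dict, dlogits: np.ndarray) -> None:
        cfg = self.config
        P = self.params
        latent = cache["latent"]
        P["head_w"].grad += np.outer(dlogits, latent).astype(np.float32)
        P["head_b"].grad += dlogits.astype(np.float32)
        dout = np.zeros_like(cache["out"])
        dout[0] = P["head_w"].value.astype(np.float64).T @ dlogits
        dh, dg, db = self._ln_backward(dout, cache["lnfc"])
        P["lnf_g"].grad += dg.astype(np.float32)
        P["lnf_b"].grad += db.astype(np.float32)
        E, nh = cfg.embed_dim, cfg.heads
        dh_ = E // nh
        for l in range(cfg.depth - 1, -1, -1):
            c = cache["layers"][l]
            T = c["pre"].shape[0]
            # MLP branch
            da1 = dh @ P[f"l{l}_w2"].value.T
            P[f"l{l}_w2"].grad += (c["a1"].T @ dh).astype(np.float32)
            P[f"l{l}_b2"].grad += dh.sum(axis=0).astype(np.float32)
            dm1 = relu_grad(da1, c["a1"])
            P[f"l{l}_w1"].grad += (c["x2"].T @ dm1).astype(np.float32)
            P[f"l{l}_b1"].grad += dm1.sum(axis=0).astype(np.float32)
            dx2 = dm1 @ P[f"l{l}_w1"].value.T
            dh1_ln, dg, db = self._ln_backward(dx2, c["ln2c"])
            P[f"l{l}_ln2_g"].grad += dg.astype(np.float32)
            P[f"l{l}_ln2_b"].grad += db.astype(np.float32)
            dh1 = dh + dh1_ln
            # attention branch
            dattn_out = dh1
            P[f"l{l}_wo"].grad += (c["concat"].T @ dattn_out).astype(np.float32)
            P[f"l{l}_bo"].grad += dattn_out.sum(axis=0).astype(np.float32)
            dconcat = dattn_out @ P[f"l{l}_wo"].value.T
            dctxh = dconcat.reshape(T, nh, dh_).transpose(1, 0, 2)
            attn, vh = c["attn"], c["vh"]
            dattn = dctxh @ vh.transpose(0, 2, 1)
            dvh = attn.transpose(0, 2, 1) @ dctxh
            dscores = attn * (dattn - (dattn * attn).sum(axis=-1, keepdims=True))
            dscores /= np.sqrt(dh_)
            qh = c["q"].reshape(T, nh, dh_).transpose(1, 0, 2)
            kh = c["k"].reshape(T, nh, dh_).transpose(1, 0, 2)
            dqh = dscores @ kh
            dkh = dscores.transpose(0, 2, 1) @ qh
            dq = dqh.transpose(1, 0, 2).reshape(T, E)
            dk = dkh.transpose(1, 0, 2).reshape(T, E)
            dv = dvh.transpose(1, 0, 2).reshape(T, E)
            x1 = c["x1"]
            dx1 = dq @ P[f"l{l}_wq"].value.T + dk @ P[f"l{l}_wk"].value.T + dv @ P[f"l{l}_wv"].value.T
            for nm, dmat in (("wq", dq), ("wk", dk), ("wv", dv)):
                P[f"l{l}_{nm}"].grad += (x1.T @ dmat).astype(np.float32)
            for nm, dmat in (("bq", dq), ("bk", dk), ("bv", dv)):
                P[f"l{l}_{nm}"].grad += dmat.sum(axis=0).astype(np.float32)
            dpre_ln, dg, db = self._ln_backward(dx1, c["ln1c"])
            P[f"l{l}_ln1_g"].grad += dg.astype(np.float32)
            P[f"l{l}_ln1_b"].grad += db.astype(np.float32)
            dh = dh1 + dpre_ln
        # embedding, positions, context pooling
        P["pos"].grad += dh.astype(np.float32)
        dseq = dh
        dtok = dseq[1:] + dseq[0] / self.config.n_patches
        P["embed_w"].grad += (cache["patches"].astype(np.float64).T @ dtok).astype(np.float32)
        P["embed_b"].grad += dtok.sum(axis=0).astype(np.float32)

    # -------------------------------------------------------------- public
    def logits(self, patches: np.ndarray) -> np.ndarray:
        return self.forward(patches)["logits"]

    def latent(self, patches: np.ndarray) -> np.ndarray:
        return np.asarray(self.forward(patches)["latent"], dtype=np.float64)

    def attention_stack(self, patches: np.ndarray) -> AttentionStack:
        return AttentionStack(self.forward(patches)["attn"])


def build_global_encoder(config: GlobalNetConfig, seed: int = 0) -> GlobalEncoder:
    return GlobalEncoder(config, seed=seed)


def train_global_network(network: GlobalEncoder, volumes, labels,
                         train_config: TrainConfig = TrainConfig()) -> GlobalEncoder:
    """Train the Transformer channel (cross-entropy, Adam, early stopping)."""
    y, classes = _class_codes(labels)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to train")
    cfg = network.config
    patch_sets = []
    for v in volumes:
        data = prepare_global_input(v, cfg.input_shape)
        patches, _, _ = patchify(data, cfg.patch_kernel, cfg.patch_stride)
        patch_sets.append(patches)
    rng = np.random.default_rng(train_config.seed)
    n = len(patch_sets)
    idx = rng.permutation(n)
    n_val = int(round(train_config.val_fraction * n)) if n >= 10 else 0
    val_idx, tr_idx = idx[:n_val], idx[n_val:]
    opt = Adam(network.param_list(), lr=train_config.lr)
    best_val, best_state, stale = np.inf, None, 0
    for epoch in range(train_config.epochs):
        order = rng.permutation(tr_idx)
        ep_loss = 0.0
        for b0 in range(0, len(order), train_config.batch_size):
            batch = order[b0:b0 + train_config.batch_size]
            opt.zero_grad()
            for i in batch:
                cache = network.forward(patch_sets[i], keep=True)
                loss, dlogits = softmax_ce(cache["logits"], int(y[i]))
                network.backward(cache, dlogits.astype(np.float64) / len(batch))
                ep_loss += loss
            opt.step()
        ep_loss /= max(len(order), 1)
        if n_val:
            val_loss = float(np.mean([softmax_ce(network.logits(patch_sets[i]), int(y[i]))[0]
                                      for i in val_idx]))
        else:
            val_loss = ep_loss
        network.train_log.append({"epoch": epoch, "train_loss": ep_loss,
                                  "val_loss": val_loss, "seed": train_config.seed})
        if val_loss < best_val - 1e-6:
            best_val, stale = val_loss, 0
            best_state = {k: p.value.copy() for k, p in network.params.items()}
        else:
            stale += 1
            if stale > train_config.patience:
                break
    if best_state is not None:
        for k, p in network.params.items():
            p.value = best_state[k]
    network.classes_ = classes
    return network


def extract_global_latents(trained: GlobalEncoder, volume: Volume3D | np.ndarray) -> np.ndarray:
    """Context-token representation after the final encoder layer."""
    cfg = trained.config
    data = prepare_global_input(volume, cfg.input_shape)
    patches, _, _ = patchify(data, cfg.patch_kernel, cfg.patch_stride)
    return trained.latent(patches)


def rollout_map(trained: GlobalEncoder, volume: Volume3D | np.ndarray,
                target_shape: tuple[int, int, int] | None = None,
                spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> AttributionVolume:
    """Paint the context-token rollout row onto patch footprints."""
    cfg = trained.config
    data = prepare_global_input(volume, cfg.input_shape)
    patches, _, origins = patchify(data, cfg.patch_kernel, cfg.patch_stride)
    stack = trained.attention_stack(patches)
    roll = attention_rollout(stack)
    scores = roll[0, 1:]
    acc = np.zeros(cfg.input_shape, dtype=np.float64)
    cnt = np.zeros(cfg.input_shape, dtype=np.float64)
    k = cfg.patch_kernel
    for score, (i, j, m) in zip(scores, origins):
        acc[i:i + k, j:j + k, m:m + k] += score
        cnt[i:i + k, j:j + k, m:m + k] += 1.0
    covered = cnt > 0
    acc[covered] /= cnt[covered]
    shape = target_shape or tuple(np.asarray(data.shape))
    if tuple(acc.shape) != tuple(shape):
        acc = ndimage.zoom(acc, [t / s for t, s in zip(shape, acc.shape)], order=1)
        acc = np.maximum(acc, 0.0)
    lo, hi = float(acc.min()), float(acc.max())
    acc = (acc - lo) / (hi - lo) if hi > lo else np.zeros_like(acc)
    return AttributionVolume(acc, target_class=None, source="rollout", spacing=spacing)
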