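"""The local channel: a 3-layer dilated 3-D convolutional encoder.

Architecture: conv(32, 3x3x3, dilation 1) -> ReLU -> conv(64, 3x3x3,
dilation 2) -> ReLU -> conv(128, 3x3x3, dilation 3) -> ReLU -> global
average pooling -> latent vector -> linear softmax head.  Stride-1 "same"
zero padding everywhere, so spatial resolution is maintained and the
effective receptive field grows to 1 + 2*(1+2+3) = 13 voxels per axis.
The latent vector is the pooled last feature map; its entries are named
``Local_latent_0 .. Local_latent_(D-1)``.

Layer-CAM attribution: ``M = ReLU(sum_k ReLU(dy_c/dA_k) * A_k)`` on a named
layer's (post-ReLU) activations, trilinearly upsampled to the input
geometry and min-max normalized to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._nn import (Adam, Param, conv3d_backward, conv3d_same, he_normal, relu,
                  relu_grad, softmax, softmax_ce)
from .volume import AttributionVolume, Volume3D

__all__ = ["LocalNetConfig", "TrainConfig", "LocalEncoder", "build_local_encoder",
           "train_network", "extract_local_latents", "layer_cam",
           "local_latent_names", "prepare_input"]


@dataclass(frozen=True)
class LocalNetConfig:
    input_shape: tuple[int, int, int] = (79, 95, 69)
    #: per-layer (filters, kernel, dilation)
    layers: tuple[tuple[int, int, int], ...] = ((32, 3, 1), (64, 3, 2), (128, 3, 3))
    n_classes: int = 3

    def __post_init__(self) -> None:
        dil = [d for _, _, d in self.layers]
        if any(b <= a for a, b in zip(dil, dil[1:])):
            raise ValueError("dilation rates must be strictly increasing")
        rf = self.receptive_field
        if any(s < rf for s in self.input_shape):
            raise ValueError(f"input {self.input_shape} smaller than receptive field {rf}")

    @property
    def latent_dim(self) -> int:
        return self.layers[-1][0]

    @property
    def receptive_field(self) -> int:
        return 1 + sum(d * (k - 1) for _, k, d in self.layers)

    @staticmethod
    def desk_scale(n_classes: int = 3) -> "LocalNetConfig":
        """Small preset so training runs on one CPU in seconds/minutes."""
        return LocalNetConfig(input_shape=(20, 24, 18),
                              layers=((4, 3, 1), (8, 3, 2), (16, 3, 3)),
                              n_classes=n_classes)


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-3
    epochs: int = 30
    batch_size: int = 16
    val_fraction: float = 0.2
    patience: int = 6
    seed: int = 0
    #: epochs of head-only optimization (linear probe on calibrated latents)
    #: before full fine-tuning; stabilizes the badly scaled GAP pathway
    head_warmup_epochs: int = 8
    head_lr: float = 5e-2


def local_latent_names(dim: int) -> list[str]:
    return [f"Local_latent_{i}" for i in range(dim)]


def prepare_input(volume: Volume3D, shape: tuple[int, int, int]) -> np.ndarray:
    """Resample a (z-scored) volume to the network input grid (trilinear)."""
    data = np.asarray(volume.data, dtype=np.float32)
    if tuple(data.shape) == tuple(shape):
        return data
    zoom = [t / s for t, s in zip(shape, data.shape)]
    return ndimage.zoom(data.astype(np.float64), zoom, order=1).astype(np.float32)


class LocalEncoder:
    """Dilated 3-D CNN with activation/gradient hooks per named conv layer."""

    def __init__(self, config: LocalNetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.params: dict[str, Param] = {}
        cin = 1
        for li, (cout, k, _d) in enumerate(config.layers, start=1):
            self.params[f"conv{li}_w"] = Param(he_normal(rng, (cout, cin * k ** 3), cin * k ** 3))
            self.params[f"conv{li}_b"] = Param(np.zeros(cout, dtype=np.float32))
            cin = cout
        self.params["head_w"] = Param(he_normal(rng, (config.n_classes, cin), cin))
        self.params["head_b"] = Param(np.zeros(config.n_classes, dtype=np.float32))
        # frozen latent standardization (data-dependent init; see calibrate_latent)
        self.latent_mu = np.zeros(cin, dtype=np.float32)
        self.latent_sigma = np.ones(cin, dtype=np.float32)
        self.train_log: list[dict] = []

    # ------------------------------------------------------------- plumbing
    @property
    def layer_names(self) -> list[str]:
        return [f"conv{li}" for li in range(1, len(self.config.layers) + 1)]

    def parameter_count(self) -> int:
        return int(sum(p.value.size for p in self.params.values()))

    def param_list(self) -> list[Param]:
        return list(self.params.values())

    def reset_head(self, n_classes: int, seed: int = 0) -> None:
        """Re-initialize the classifier head (e.g. 4-class pretrain -> 3-class)."""
        from dataclasses import replace

        rng = np.random.default_rng(seed)
        cin = self.config.latent_dim
        self.config = replace(self.config, n_classes=n_classes)
        self.params["head_w"] = Param(he_normal(rng, (n_classes, cin), cin))
        self.params["head_b"] = Param(np.zeros(n_classes, dtype=np.float32))

    # -------------------------------------------------------------- forward
    def forward(self, x: np.ndarray, keep: bool = False) -> dict:
        """x: (D, H, W) float32 -> cache with activations, latent, logits."""
        if tuple(x.shape) != tuple(self.config.input_shape):
            raise ValueError(f"input shape {x.shape} != configured {self.config.input_shape}")
        a = x[None].astype(np.float32)
        cache = {"inputs": [], "acts": []}
        for li, (_cout, k, d) in enumerate(self.config.layers, start=1):
            w = self.params[f"conv{li}_w"].value
            b = self.params[f"conv{li}_b"].value
            if keep:
                cache["inputs"].append(a)
            z = conv3d_same(a, w, b, k, d)
            a = relu(z)
            if keep:
                cache["acts"].append(a)
        pooled = a.reshape(a.shape[0], -1).mean(axis=1)
        latent = (pooled - self.latent_mu) / self.latent_sigma
        logits = self.params["head_w"].value @ latent + self.params["head_b"].value
        cache["last"] = a
        cache["latent"] = latent
        cache["logits"] = logits
        return cache

    def calibrate_latent(self, inputs: list[np.ndarray], eps: float = 1e-6) -> None:
        """Freeze latent standardization stats from the (training) inputs.

        The global average pool of a wide 3-D feature map has tiny variance
        across subjects, which ill-conditions head/conv gradients; this
        data-dependent initialization rescales each pooled channel to unit
        variance once, before optimization, and is then kept fixed.
        """
        self.latent_mu = np.zeros_like(self.latent_mu)
        self.latent_sigma = np.ones_like(self.latent_sigma)
        pooled = np.stack([self.forward(x)["latent"] for x in inputs])
        self.latent_mu = pooled.mean(axis=0).astype(np.float32)
        self.latent_sigma = np.maximum(pooled.std(axis=0, ddof=0), eps).astype(np.float32)

    def predict_logits(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)["logits"]

    def latent(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)["latent"].astype(np.float64)

    # ------------------------------------------------------------- backward
    def backward(self, cache: dict, dlogits: np.ndarray,
                 accumulate: bool = True) -> list[np.ndarray]:
        """Backprop from dlogits; returns d(post-ReLU activation) per layer."""
        latent = cache["latent"]
        hw = self.params["head_w"]
        if accumulate:
            hw.grad += np.outer(dlogits, latent)
            self.params["head_b"].grad += dlogits
        dlatent = (hw.value.T @ dlogits) / self.latent_sigma
        last = cache["last"]
        nvox = last[0].size
        da = np.broadcast_to((dlatent / nvox)[:, None, None, None], last.shape).astype(np.float32)
        dacts: list[np.ndarray] = [None] * len(self.config.layers)
        for li in range(len(self.config.layers), 0, -1):
            (_c, k, d) = self.config.layers[li - 1]
            act = cache["acts"][li - 1]
            dacts[li - 1] = da
            dz = relu_grad(da, act)
            x_in = cache["inputs"][li - 1]
            dx, dw, db = conv3d_backward(dz, x_in, self.params[f"conv{li}_w"].value, k, d)
            if accumulate:
                self.params[f"conv{li}_w"].grad += dw
                self.params[f"conv{li}_b"].grad += db
            da = dx
        return dacts

    def activation_and_gradient(self, x: np.ndarray, class_idx: int, layer: str):
        """Hooks contract: (A^k, dy_c/dA^k) at a named layer, y_c = class logit."""
        if layer not in self.layer_names:
            raise KeyError(f"unknown layer {layer!r}; have {self.layer_names}")
        if not 0 <= class_idx < self.config.n_classes:
            raise IndexError(f"class index {class_idx} out of range")
        cache = self.forward(x, keep=True)
        dlogits = np.zeros(self.config.n_classes, dtype=np.float32)
        dlogits[class_idx] = 1.0
        dacts = self.backward(cache, dlogits, accumulate=False)
        li = self.layer_names.index(layer)
        return cache["acts"][li], dacts[li]


def build_local_encoder(config: LocalNetConfig, seed: int = 0) -> LocalEncoder:
    return LocalEncoder(config, seed=seed)


def _class_codes(labels) -> tuple[np.ndarray, list[str]]:
    classes = sorted(set(labels))
    lut = {c: i for i, c in enumerate(classes)}
    return np.asarray([lut[l] for l in labels]), classes


def train_network(network: LocalEncoder, volumes: list[np.ndarray], labels,
                  train_config: TrainConfig = TrainConfig()) -> LocalEncoder:
    """Train with cross-entropy + Adam; early stop on validation loss.

    ``volumes`` are z-scored grids already resampled to the network input
    shape (see :func:`prepare_input`).  Deterministic given the seed.
    """
    y, classes = _class_codes(labels)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to train")
    if len(classes) != network.config.n_classes:
        raise ValueError(f"{len(classes)} classes present but head has {network.config.n_classes}")
    xs = [np.asarray(v, dtype=np.float32) for v in volumes]
    for x in xs:
        if tuple(x.shape) != tuple(network.config.input_shape):
            raise ValueError("volume shape does not match network input shape")
    rng = np.random.default_rng(train_config.seed)
    n = len(xs)
    idx = rng.permutation(n)
    n_val = int(round(train_config.val_fraction * n)) if n >= 10 else 0
    val_idx, tr_idx = idx[:n_val], idx[n_val:]
    network.calibrate_latent([xs[i] for i in tr_idx])

    # phase 1: linear probe — optimize the head on frozen conv latents
    if train_config.head_warmup_epochs > 0:
        latents = {int(i): network.forward(xs[i])["latent"] for i in idx}
        head = [network.params["head_w"], network.params["head_b"]]
        opt_h = Adam(head, lr=train_config.head_lr)
        hw, hb = head
        for _ in range(train_config.head_warmup_epochs):
            order = rng.permutation(tr_idx)
            for b0 in range(0, len(order), train_config.batch_size):
                batch = order[b0:b0 + train_config.batch_size]
                opt_h.zero_grad()
                for i in batch:
                    lat = latents[int(i)]
                    logits = hw.value @ lat + hb.value
                    _, dlogits = softmax_ce(logits, int(y[i]))
                    hw.grad += np.outer(dlogits, lat) / len(batch)
                    hb.grad += dlogits / len(batch)
                opt_h.step()

    # phase 2: full fine-tuning with early stopping; latent standardization
    # statistics are refreshed each epoch (stop-gradient, batch-norm style)
    # so they track the drifting conv features
    opt = Adam(network.param_list(), lr=train_config.lr)
    best_val = np.inf
    best_state = None
    stale = 0
    for epoch in range(train_config.epochs):
        if epoch > 0:
            network.calibrate_latent([xs[i] for i in tr_idx])
        order = rng.permutation(tr_idx)
        ep_loss = 0.0
        for b0 in range(0, len(order), train_config.batch_size):
            batch = order[b0:b0 + train_config.batch_size]
            opt.zero_grad()
            for i in batch:
                cache = network.forward(xs[i], keep=True)
                loss, dlogits = softmax_ce(cache["logits"], int(y[i]))
                network.backward(cache, dlogits / len(batch))
                ep_loss += loss
            opt.step()
        ep_loss /= max(len(order), 1)
        if n_val:
            val_loss = float(np.mean([softmax_ce(network.predict_logits(xs[i]), int(y[i]))[0]
                                      for i in val_idx]))
        else:
            val_loss = ep_loss
        network.train_log.append({"epoch": epoch, "train_loss": ep_loss,
                                  "val_loss": val_loss, "seed": train_config.seed})
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_state = ({k: p.value.copy() for k, p in network.params.items()},
                          network.latent_mu.copy(), network.latent_sigma.copy())
            stale = 0
        else:
            stale += 1
            if stale > train_config.patience:
                break
    if best_state is not None:
        params, mu, sigma = best_state
        for k, p in network.params.items():
            p.value = params[k]
        network.latent_mu, network.latent_sigma = mu, sigma
    # canonical head gauge: softmax logits are invariant to adding a per-channel
    # constant across classes, so the uncentered initialization component is
    # pure gauge noise; remove it so "positive class evidence" (as read by
    # Layer-CAM's ReLU on head-weight gradients) is well defined
    hw, hb = network.params["head_w"], network.params["head_b"]
    hw.value = hw.value - hw.value.mean(axis=0, keepdims=True)
    hb.value = hb.value - hb.value.mean()
    network.classes_ = classes
    return network


def extract_local_latents(trained: LocalEncoder, volume: Volume3D | np.ndarray) -> np.ndarray:
    """Global-average-pooled last-layer features, Local_latent_0..(D-1)."""
    x = volume if isinstance(volume, np.ndarray) else prepare_input(volume, trained.config.input_shape)
    return trained.latent(np.asarray(x, dtype=np.float32))


def layer_cam(trained: LocalEncoder, volume: Volume3D | np.ndarray, target_class: int,
              layer: str = "conv3", target_shape: tuple[int, int, int] | None = None,
              spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> AttributionVolume:
    """ReLU(sum_k ReLU(grad) * activation), upsampled and min-max normalized."""
    x = volume if isinstance(volume, np.ndarray) else prepare_input(volume, trained.config.input_shape)
    acts, grads = trained.activation_and_gradient(np.asarray(x, np.float32), target_class, layer)
    m = relu((relu(grads.astype(np.float64)) * acts).sum(axis=0))
    shape = target_shape or tuple(x.shape)
    if tuple(m.shape) != tuple(shape):
        m = ndimage.zoom(m, [t / s for t, s in zip(shape, m.shape)], order=1)
        m = np.maximum(m, 0.0)
    lo, hi = float(m.min()), float(m.max())
    m = (m - lo) / (hi - lo) if hi > lo else np.zeros_like(m)
    return AttributionVolume(m, target_class=target_class, source="layer_cam", spacing=spacing)
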