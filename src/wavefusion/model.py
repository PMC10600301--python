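"""The WaveFusion network.

One lightweight three-stage CNN per lead turns each 39 x 11 magnitude
spectrogram into a 32-dimensional feature map.  A squeeze-and-excite
attention module pools each feature map to a scalar, passes the 17 pooled
values through a 17 -> 5 -> 17 bottleneck, and emits one attention weight
per lead through a temperature-flattened sigmoid

    pi_i = exp(a_i / tau) / (exp(a_i / tau) + 1),

where ``a_i`` is the pre-activation of lead ``i`` and ``tau`` (tau_attn)
flattens all weights toward 0.5 as it grows, preventing the attention from
collapsing onto a few leads.  The attention-scaled feature maps are
concatenated and a dense layer produces the 128-d representation ``r``.
During contrastive pretraining a projection head maps ``r`` to a unit-norm
32-d embedding ``z``; for classification a 2-node dense head on ``r``
produces the logits.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn


@dataclass(frozen=True)
class ConvStage:
    """One convolutional stage of the per-lead CNN."""

    kernel: tuple[int, int]
    stride: tuple[int, int]
    padding: tuple[int, int]
    channels: int
    batch_norm: bool
    dropout: float
    activation: str          # "relu" or "none"
    pool: bool               # 2x2 max-pool after the activation


def _default_stages() -> tuple[ConvStage, ...]:
    return (
        ConvStage((5, 4), (2, 1), (2, 1), 16, False, 0.1, "relu", True),
        ConvStage((4, 2), (2, 1), (0, 0), 16, True, 0.1, "relu", True),
        ConvStage((2, 2), (1, 1), (0, 0), 32, True, 0.1, "none", False),
    )


@dataclass(frozen=True)
class LwcnnConfig:
    """Per-lead CNN architecture; defaults give 39x11 -> 32 features."""

    stages: tuple[ConvStage, ...] = field(default_factory=_default_stages)


@dataclass(frozen=True)
class WaveFusionConfig:
    n_leads: int = 17
    input_shape: tuple[int, int] = (39, 11)   # (freq, time)
    lwcnn: LwcnnConfig = field(default_factory=LwcnnConfig)
    sen_bottleneck: int = 5
    encoder_dim: int = 128
    embed_dim: int = 32
    tau_attn: float = 1.0
    use_sen: bool = True

    def __post_init__(self) -> None:
        if self.tau_attn <= 0:
            raise ValueError("tau_attn must be positive")

    def fingerprint(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def sigmoid_attention(a: np.ndarray, tau_attn: float) -> np.ndarray:
    """Temperature-flattened sigmoid: 0.5 at a=0, ->0.5 as tau grows."""
    if tau_attn <= 0:
        raise ValueError("tau_attn must be positive")
    a = np.asarray(a)
    if not np.issubdtype(a.dtype, np.floating):
        a = a.astype(float)
    return 1.0 / (1.0 + np.exp(-a / tau_attn))


class WaveFusionNet:
    """Per-lead CNN bank + squeeze-excite fusion + heads, with backprop.

    ``forward_*`` methods cache intermediate values inside the layer
    objects; each ``backward_*`` call must directly follow the matching
    forward.
    """

    def __init__(self, config: WaveFusionConfig = WaveFusionConfig(),
                 seed: int = 0, dtype=np.float64) -> None:
        self.config = config
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(seed)
        self.rng = rng
        L = config.n_leads
        h, w = config.input_shape
        c_in = 1
        self.feature_layers: list[nn.Layer] = []
        for stage in config.lwcnn.stages:
            conv = nn.LeadConv2d(L, c_in, stage.channels, stage.kernel,
                                 stage.stride, stage.padding, rng)
            self.feature_layers.append(conv)
            h, w = conv.out_shape(h, w)
            if stage.activation == "relu":
                self.feature_layers.append(nn.ReLU())
            if stage.pool:
                self.feature_layers.append(nn.MaxPool2x2())
                h, w = h // 2, w // 2
            if stage.dropout > 0:
                self.feature_layers.append(nn.Dropout(stage.dropout, rng))
            if stage.batch_norm:
                self.feature_layers.append(nn.LeadBatchNorm(L, stage.channels))
            c_in = stage.channels
        if (h, w) != (1, 1):
            raise ValueError(
                f"LWCNN stack must collapse the spectrogram to 1x1 per "
                f"channel; got {h}x{w} for input {config.input_shape}"
            )
        self.feature_dim = c_in
        # index of the activation used for gradient-weighted class
        # activation maps: the last spatially extended stage output
        # (stage-2 ReLU, 4x4 under the default architecture)
        self._cam_index = self._find_cam_index()
        self.sen_fc1 = nn.Dense(L, config.sen_bottleneck, rng)
        self.sen_relu = nn.ReLU()
        self.sen_fc2 = nn.Dense(config.sen_bottleneck, L, rng)
        self.enc_dense = nn.Dense(L * self.feature_dim, config.encoder_dim,
                                  rng)
        self.proj_dense = nn.Dense(config.encoder_dim, config.embed_dim, rng)
        self.cls_dense = nn.Dense(config.encoder_dim, 2, rng)
        self.cam_activation: np.ndarray | None = None
        self.cam_gradient: np.ndarray | None = None
        if self.dtype != np.float64:
            for layers in self._param_groups().values():
                for layer in layers:
                    for k in layer.params:
                        layer.params[k] = layer.params[k].astype(self.dtype)
                    layer.zero_grad()
                    if isinstance(layer, nn.LeadBatchNorm):
                        layer.running_mean = layer.running_mean.astype(
                            self.dtype)
                        layer.running_var = layer.running_var.astype(
                            self.dtype)

    def _find_cam_index(self) -> int:
        """Position (in feature_layers) of the second stage's activation."""
        conv_seen = 0
        for i, layer in enumerate(self.feature_layers):
            if isinstance(layer, nn.LeadConv2d):
                conv_seen += 1
            if conv_seen == 2 and isinstance(layer, nn.ReLU):
                return i
        return max(len(self.feature_layers) - 1, 0)

    # ------------------------------------------------------------------ #
    # layer groups

    def _param_groups(self) -> dict[str, list[nn.Layer]]:
        return {
            "features": [l for l in self.feature_layers if l.params],
            "sen": [self.sen_fc1, self.sen_fc2],
            "encoder": [self.enc_dense],
            "projection": [self.proj_dense],
            "classifier": [self.cls_dense],
        }

    def layers_for(self, parts: tuple[str, ...]) -> list[nn.Layer]:
        groups = self._param_groups()
        out: list[nn.Layer] = []
        for p in parts:
            out.extend(groups[p])
        return out

    def named_parameters(self) -> dict[str, np.ndarray]:
        out = {}
        for group, layers in self._param_groups().items():
            for i, layer in enumerate(layers):
                for key, val in layer.params.items():
                    out[f"{group}.{i}.{key}"] = val
                if isinstance(layer, nn.LeadBatchNorm):
                    out[f"{group}.{i}.running_mean"] = layer.running_mean
                    out[f"{group}.{i}.running_var"] = layer.running_var
        return out

    def load_parameters(self, named: dict[str, np.ndarray]) -> None:
        current = self.named_parameters()
        if set(named) != set(current):
            raise ValueError("parameter name sets differ; wrong architecture")
        for group, layers in self._param_groups().items():
            for i, layer in enumerate(layers):
                for key in layer.params:
                    layer.params[key] = named[f"{group}.{i}.{key}"].copy()
                if isinstance(layer, nn.LeadBatchNorm):
                    layer.running_mean = named[f"{group}.{i}.running_mean"].copy()
                    layer.running_var = named[f"{group}.{i}.running_var"].copy()

    # ------------------------------------------------------------------ #
    # forward

    def forward_features(self, X: np.ndarray, train: bool = False
                         ) -> np.ndarray:
        """Per-lead feature maps U: (B, L, freq, time) -> (B, L, 32)."""
        X = np.asarray(X, dtype=self.dtype)
        if X.ndim == 3:
            X = X[None]
        b, l, h, w = X.shape
        if (l, h, w) != (self.config.n_leads, *self.config.input_shape):
            raise ValueError(
                f"expected input (B, {self.config.n_leads}, "
                f"{self.config.input_shape[0]}, {self.config.input_shape[1]})"
                f", got {X.shape}"
            )
        act = X[:, :, None, :, :]
        for i, layer in enumerate(self.feature_layers):
            act = layer.forward(act, train)
            if i == self._cam_index:
                self.cam_activation = act
        self._U_shape5 = act.shape
        return act.reshape(b, l, self.feature_dim)

    def sen_attention(self, U: np.ndarray, train: bool = False) -> np.ndarray:
        """Attention weights pi in (0,1)^L from feature maps (B, L, F)."""
        if not self.config.use_sen:
            return np.ones(U.shape[:2])
        pooled = U.mean(axis=2)
        h = self.sen_relu.forward(self.sen_fc1.forward(pooled, train), train)
        a = self.sen_fc2.forward(h, train)
        self._pi = sigmoid_attention(a, self.config.tau_attn)
        return self._pi

    def encode(self, X: np.ndarray, train: bool = False
               ) -> tuple[np.ndarray, dict]:
        """Full encoder: spectrogram tensors -> r in R^128."""
        U = self.forward_features(X, train)
        pi = self.sen_attention(U, train)
        V = U * pi[:, :, None]
        flat = V.reshape(len(U), -1)
        r = self.enc_dense.forward(flat, train)
        return r, {"U": U, "pi": pi}

    def forward_embedding(self, X: np.ndarray, train: bool = False
                          ) -> tuple[np.ndarray, dict]:
        """Pretraining path: unit-norm embeddings z in R^32."""
        r, cache = self.encode(X, train)
        v = self.proj_dense.forward(r, train)
        z = nn.l2_normalize(v)
        cache.update(r=r, v=v, z=z)
        return z, cache

    def forward_logits(self, X: np.ndarray, train: bool = False
                       ) -> tuple[np.ndarray, dict]:
        """Classification path: 2 logits."""
        r, cache = self.encode(X, train)
        logits = self.cls_dense.forward(r, train)
        cache.update(r=r, logits=logits)
        return logits, cache

    def lead_forward(self, spectrogram: np.ndarray, lead: int = 0
                     ) -> np.ndarray:
        """Feature map of one lead's CNN on a single 39 x 11 spectrogram."""
        X = np.zeros((1, self.config.n_leads, *self.config.input_shape))
        X[0, lead] = np.asarray(spectrogram).reshape(self.config.input_shape)
        return self.forward_features(X, train=False)[0, lead]

    # ------------------------------------------------------------------ #
    # backward

    def _backward_features(self, dU: np.ndarray) -> None:
        grad = dU.reshape(self._U_shape5)
        for i in range(len(self.feature_layers) - 1, -1, -1):
            grad = self.feature_layers[i].backward(grad)
            if i == self._cam_index + 1:
                self.cam_gradient = grad

    def _backward_from_r(self, dr: np.ndarray, cache: dict) -> None:
        U, pi = cache["U"], cache["pi"]
        dV = self.enc_dense.backward(dr).reshape(U.shape)
        dU = dV * pi[:, :, None]
        if self.config.use_sen:
            dpi = (dV * U).sum(axis=2)
            da = dpi * pi * (1 - pi) / self.config.tau_attn
            dh = self.sen_fc2.backward(da)
            dpooled = self.sen_fc1.backward(self.sen_relu.backward(dh))
            dU = dU + dpooled[:, :, None] / self.feature_dim
        self._backward_features(dU)

    def backward_from_embedding(self, dz: np.ndarray, cache: dict) -> None:
        dz = np.asarray(dz, dtype=self.dtype)
        dv = nn.l2_normalize_backward(cache["v"], dz)
        dr = self.proj_dense.backward(dv)
        self._backward_from_r(dr, cache)

    def backward_from_logits(self, dlogits: np.ndarray, cache: dict) -> None:
        dlogits = np.asarray(dlogits, dtype=self.dtype)
        dr = self.cls_dense.backward(dlogits)
        self._backward_from_r(dr, cache)

    def zero_grad(self) -> None:
        for layers in self._param_groups().values():
            for layer in layers:
                layer.zero_grad()

    def n_parameters(self) -> int:
        return sum(int(np.prod(p.shape))
                   for name, p in self.named_parameters().items()
                   if "running_" not in name)


# ---------------------------------------------------------------------- #
# checkpoints


def save_checkpoint(net: WaveFusionNet, path) -> None:
    """Versioned archive of named parameters + architecture fingerprint."""
    path = Path(path)
    meta = {
        "format_version": 1,
        "fingerprint": net.config.fingerprint(),
        "config": asdict(net.config),
        "dtype": net.dtype.name,
    }
    arrays = dict(net.named_parameters())
    arrays["__meta__"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)


def _config_from_dict(d: dict) -> WaveFusionConfig:
    stages = tuple(
        ConvStage(tuple(s["kernel"]), tuple(s["stride"]), tuple(s["padding"]),
                  s["channels"], s["batch_norm"], s["dropout"],
                  s["activation"], s["pool"])
        for s in d["lwcnn"]["stages"]
    )
    return WaveFusionConfig(
        n_leads=d["n_leads"], input_shape=tuple(d["input_shape"]),
        lwcnn=LwcnnConfig(stages), sen_bottleneck=d["sen_bottleneck"],
        encoder_dim=d["encoder_dim"], embed_dim=d["embed_dim"],
        tau_attn=d["tau_attn"], use_sen=d["use_sen"],
    )


def load_checkpoint(path, expect_fingerprint: str | None = None
                    ) -> WaveFusionNet:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        arrays = {k: z[k] for k in z.files if k != "__meta__"}
    if expect_fingerprint and meta["fingerprint"] != expect_fingerprint:
        raise ValueError(
            f"checkpoint fingerprint {meta['fingerprint']} does not match "
            f"expected {expect_fingerprint}"
        )
    net = WaveFusionNet(_config_from_dict(meta["config"]),
                        dtype=np.dtype(meta.get("dtype", "float64")))
    net.load_parameters(arrays)
    return net
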