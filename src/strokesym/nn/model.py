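"""The multimodal stroke network: modality encoders, cross-modal attention
fusion, weighted-GCN + dilated-TCN spatiotemporal core, and dual task heads.

Architecture (defaults): three modality summaries (skeleton embedding,
12-d kinematic descriptor through a 64-128-128 MLP, 256-d per-frame RGB
features) are fused by cross-modal attention into a 512-d vector; the fused
vector is broadcast-concatenated onto per-joint keypoint embeddings, passed
through a 3-layer GCN over the sport-weighted skeleton adjacency, pooled
over joints, modeled in time by a 4-layer causal TCN with dilations 2^i and
kernel width 5 (receptive field 61 frames), mean-pooled, and fed to a
shared trunk with two classification heads (256-128-64-4 asymmetry,
256-128-64-3 risk).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .autodiff import Tensor, concat, log_softmax, relu
from .layers import (
    MLP,
    BatchNorm,
    CausalDilatedConv1d,
    CrossModalAttention,
    Dropout,
    GCNLayer,
    Linear,
    Module,
    TCN,
)

__all__ = [
    "ModelConfig",
    "MultimodalStrokeNet",
    "receptive_field",
    "gcn_layer_forward",
    "tcn_forward",
    "cross_modal_attention",
    "kinematic_encoder",
    "measure_receptive_field",
]

ALL_MODALITIES = ("rgb", "skeleton", "kinematic")


class ModelConfig(BaseModel):
    """Hyperparameters of the stroke network."""

    gcn_layers: int = 3
    gcn_hidden: int = 48
    node_embed_dim: int = 24
    fused_node_dim: int = 24
    tcn_layers: int = 4
    tcn_kernel: int = 5
    tcn_channels: int = 48
    fusion_dim: int = 512
    kin_mlp_dims: tuple[int, int, int] = (64, 128, 128)
    kin_input_dim: int = 12
    rgb_dim: int = 256
    d_model: int = 128
    d_k: int = 64
    head_dims: tuple[int, int, int] = (256, 128, 64)
    n_asym_classes: int = 4
    n_risk_classes: int = 3
    dropout: float = Field(default=0.5, ge=0.0, lt=1.0)
    attention_row_softmax: bool = True
    modalities: tuple[str, ...] = ALL_MODALITIES
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "ModelConfig":
        unknown = set(self.modalities) - set(ALL_MODALITIES)
        if unknown:
            raise ValueError(f"unknown modalities: {sorted(unknown)}")
        if not self.modalities:
            raise ValueError("at least one modality is required")
        if min(self.fusion_dim, self.d_model, self.d_k, self.tcn_channels) <= 0:
            raise ValueError("dimensions must be positive")
        return self

    @property
    def tcn_dilations(self) -> tuple[int, ...]:
        return tuple(2**i for i in range(self.tcn_layers))


def receptive_field(config: ModelConfig) -> int:
    """Frames seen by one output of the stacked causal dilated convolutions:
    ``1 + (kernel - 1) * sum(dilations)``."""
    return 1 + (config.tcn_kernel - 1) * sum(config.tcn_dilations)


class MultimodalStrokeNet(Module):
    """Full network; see the module docstring for the data flow."""

    def __init__(self, config: ModelConfig) -> None:
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config

        # modality encoders (summaries used by the fusion stage)
        self.rgb_enc = Linear(c.rgb_dim, c.d_model, rng)
        self.kin_mlp = MLP((c.kin_input_dim,) + tuple(c.kin_mlp_dims), rng)
        self.kin_proj = Linear(c.kin_mlp_dims[-1], c.d_model, rng)
        self.skel_embed = Linear(3, c.node_embed_dim, rng)
        self.skel_summary = Linear(c.node_embed_dim, c.d_model, rng)

        self.attention = CrossModalAttention(
            c.d_model, c.d_k, c.fusion_dim, rng, row_softmax=c.attention_row_softmax
        )
        # bypass projection for ablation configs with < 3 modalities
        self.bypass_proj = Linear(c.d_model, c.fusion_dim, rng)
        self.fused_compress = Linear(c.fusion_dim, c.fused_node_dim, rng)

        # spatiotemporal core
        dims = [c.node_embed_dim + c.fused_node_dim] + [c.gcn_hidden] * c.gcn_layers
        self.gcn = [GCNLayer(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
        self.frame_proj = Linear(c.gcn_hidden, c.tcn_channels, rng)
        self.tcn = TCN(c.tcn_channels, c.tcn_layers, c.tcn_kernel, rng)

        # shared trunk and task heads
        self.trunk = Linear(c.tcn_channels, c.head_dims[0], rng)
        self.trunk_norm = BatchNorm(c.head_dims[0])
        self.drop = Dropout(c.dropout, np.random.default_rng(c.seed + 1))
        h = c.head_dims
        self.head_asym = MLP((h[0], h[1], h[2], c.n_asym_classes), rng,
                             final_activation=False)
        self.head_risk = MLP((h[0], h[1], h[2], c.n_risk_classes), rng,
                             final_activation=False)

    # -- forward ----------------------------------------------------------

    def _modality_vectors(
        self,
        coords: np.ndarray,
        kin: Optional[np.ndarray],
        rgb: Optional[np.ndarray],
    ) -> tuple[dict[str, Tensor], Tensor]:
        vecs: dict[str, Tensor] = {}
        node = relu(self.skel_embed(Tensor(coords)))          # (B, T, J, E)
        if "skeleton" in self.config.modalities:
            vecs["skeleton"] = relu(self.skel_summary(node.mean(axis=(1, 2))))
        if "kinematic" in self.config.modalities:
            if kin is None:
                raise ValueError("kinematic features required by this configuration")
            if kin.shape[-1] != self.config.kin_input_dim:
                raise ValueError(
                    f"kinematic input dim {kin.shape[-1]} != {self.config.kin_input_dim}"
                )
            enc = self.kin_mlp(Tensor(kin))                   # (B, Tk, 128)
            vecs["kinematic"] = relu(self.kin_proj(enc.mean(axis=1)))
        if "rgb" in self.config.modalities:
            if rgb is None:
                raise ValueError("rgb features required by this configuration")
            vecs["rgb"] = relu(self.rgb_enc(Tensor(rgb)).mean(axis=1))
        return vecs, node

    def forward(
        self,
        coords: np.ndarray,
        kin: Optional[np.ndarray],
        rgb: Optional[np.ndarray],
        a_norm: np.ndarray,
    ) -> tuple[Tensor, Tensor]:
        """Return (asymmetry logits (B, 4), risk logits (B, 3)).

        coords: (B, T, J, 3) z-normalized keypoints; kin: (B, Tk, 12);
        rgb: (B, T, rgb_dim); a_norm: (J, J) or (B, J, J) normalized
        adjacency (per-sample handedness).
        """
        if coords.ndim != 4 or coords.shape[2] != 17:
            raise ValueError(f"coords must be (B, T, 17, 3), got {coords.shape}")
        vecs, node = self._modality_vectors(coords, kin, rgb)

        if len(self.config.modalities) == 3:
            fused = self.attention([vecs[m] for m in ALL_MODALITIES])
        else:
            # ablation path: average available modality summaries
            total = None
            for v in vecs.values():
                total = v if total is None else total + v
            fused = relu(self.bypass_proj(total * (1.0 / len(vecs))))

        b, t, j, _ = node.shape
        extra = relu(self.fused_compress(fused))              # (B, F)
        extra = extra.reshape(b, 1, 1, extra.shape[-1])
        ones = Tensor(np.ones((1, t, j, 1)))
        h = concat([node, extra * ones], axis=3)              # broadcast-concat

        a = np.asarray(a_norm, float)
        if a.ndim == 2:
            a_t = Tensor(a)
        elif a.ndim == 3:
            a_t = Tensor(a[:, None, :, :])                    # (B, 1, J, J)
        else:
            raise ValueError("a_norm must be (J, J) or (B, J, J)")
        for layer in self.gcn:
            h = layer(h, a_t)
        frame = relu(self.frame_proj(h.mean(axis=2)))         # (B, T, C)
        temporal = self.tcn(frame)                            # (B, T, C)
        pooled = temporal.mean(axis=1)                        # (B, C)
        shared = self.drop(relu(self.trunk_norm(self.trunk(pooled))))
        return self.head_asym(shared), self.head_risk(shared)

    def predict_logits(
        self,
        coords: np.ndarray,
        kin: Optional[np.ndarray],
        rgb: Optional[np.ndarray],
        a_norm: np.ndarray,
    ) -> tuple[np.ndarray, np.ndarray]:
        was_training = self._training
        self.eval()
        try:
            la, lr = self.forward(coords, kin, rgb, a_norm)
        finally:
            self.train(was_training)
        return la.data, lr.data

    def predict_proba(self, *args, **kwargs) -> tuple[np.ndarray, np.ndarray]:
        la, lr = self.predict_logits(*args, **kwargs)

        def _soft(z: np.ndarray) -> np.ndarray:
            z = z - z.max(axis=-1, keepdims=True)
            e = np.exp(z)
            return e / e.sum(axis=-1, keepdims=True)

        return _soft(la), _soft(lr)


# ---------------------------------------------------------------------------
# Functional views of the individual operations
# ---------------------------------------------------------------------------

def gcn_layer_forward(
    h: np.ndarray,
    a_norm: np.ndarray,
    w: np.ndarray,
    activation=None,
) -> np.ndarray:
    """One graph-convolution step ``sigma(A_norm @ H @ W)`` on plain arrays."""
    h = np.asarray(h, float)
    a_norm = np.asarray(a_norm, float)
    w = np.asarray(w, float)
    if h.shape[-1] != w.shape[0] or a_norm.shape[-1] != h.shape[-2]:
        raise ValueError(
            f"shape mismatch: H {h.shape}, A {a_norm.shape}, W {w.shape}"
        )
    out = a_norm @ h @ w
    return activation(out) if activation is not None else out


def tcn_forward(x: np.ndarray, config: ModelConfig, seed: Optional[int] = None) -> np.ndarray:
    """Run a freshly initialized causal dilated stack on (T, C) or (B, T, C).

    Output at frame t depends only on frames <= t; the length is preserved.
    """
    x = np.asarray(x, float)
    single = x.ndim == 2
    if single:
        x = x[None]
    if x.shape[-1] != config.tcn_channels:
        raise ValueError(
            f"channel mismatch: got {x.shape[-1]}, expected {config.tcn_channels}"
        )
    rng = np.random.default_rng(config.seed if seed is None else seed)
    tcn = TCN(config.tcn_channels, config.tcn_layers, config.tcn_kernel, rng)
    out = tcn(Tensor(x)).data
    return out[0] if single else out


def cross_modal_attention(
    features: Sequence[np.ndarray],
    d_k: int = 64,
    fusion_dim: int = 512,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Fuse three (B, d) modality matrices; returns (fused (B, fusion_dim),
    attention (B, 3, 3)).  Raises unless exactly three modalities are given."""
    if len(features) != 3:
        raise ValueError(f"expected 3 modality feature sets, got {len(features)}")
    mats = [np.atleast_2d(np.asarray(f, float)) for f in features]
    d = mats[0].shape[1]
    if any(m.shape != mats[0].shape for m in mats):
        raise ValueError("modality features must share one (B, d) shape")
    rng = np.random.default_rng(seed)
    att = CrossModalAttention(d, d_k, fusion_dim, rng)
    tensors = [Tensor(m) for m in mats]
    weights = att.attention_weights(tensors).data
    fused = att(tensors).data
    return fused, weights


def kinematic_encoder(
    features: np.ndarray, config: Optional[ModelConfig] = None, seed: int = 0
) -> np.ndarray:
    """Per-step 3-layer MLP (12 -> 64 -> 128 -> 128) over a feature sequence."""
    config = config or ModelConfig()
    x = np.asarray(features, float)
    if x.shape[-1] != config.kin_input_dim:
        raise ValueError(f"expected {config.kin_input_dim}-d features, got {x.shape[-1]}")
    rng = np.random.default_rng(seed)
    mlp = MLP((config.kin_input_dim,) + tuple(config.kin_mlp_dims), rng)
    return mlp(Tensor(x)).data


def measure_receptive_field(config: ModelConfig, seed: int = 0) -> int:
    """Empirical receptive field by input-perturbation probing.

    Builds the causal stack, then counts how many input frames influence
    the final-frame output by perturbing one frame at a time.
    """
    rf_upper = receptive_field(config) + 8
    t = rf_upper + 4
    rng = np.random.default_rng(seed)
    base = rng.normal(size=(1, t, config.tcn_channels))
    tcn = TCN(config.tcn_channels, config.tcn_layers, config.tcn_kernel,
              np.random.default_rng(seed + 1))
    ref = tcn(Tensor(base)).data[0, -1]
    influencing = 0
    for frame in range(t):
        probe = base.copy()
        probe[0, frame] += 1.0
        out = tcn(Tensor(probe)).data[0, -1]
        if not np.allclose(out, ref):
            influencing += 1
    return influencing
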