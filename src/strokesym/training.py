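"""Training loop: augmentation, AdamW, uncertainty weighting, early stopping.

Each epoch: augment -> encode modalities -> forward -> cross-entropy +
focal loss -> uncertainty-weighted joint loss -> AdamW step on the network
parameters and the task log-sigmas.  Training stops when the validation
joint loss fails to improve for ``patience`` (default 10) consecutive
epochs, or after ``max_epochs`` (default 100).

The AdamW weight decay (default 1e-4) realizes the L2 penalty of the joint
objective; it is applied once, through the optimizer, never added to the
gradient a second time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .indicators import kinematic_features
from .keypoints import KeypointSequence, mirror_keypoints
from .losses import (
    cross_entropy_from_logits,
    focal_loss_from_logits,
    joint_loss,
    joint_loss_tensor,
    task_weights,
)
from .nn.autodiff import Tensor
from .nn.model import ModelConfig, MultimodalStrokeNet
from .skeleton import build_skeleton_graph, normalized_adjacency
from .synthetic import StrokeSample, render_rgb_features

__all__ = [
    "TrainConfig",
    "TrainState",
    "AdamW",
    "augment",
    "prepare_batch",
    "train",
    "predict_proba",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_SCHEMA = "strokesym/checkpoint-v1"


class TrainConfig(BaseModel):
    """Optimization settings (reported training protocol as defaults)."""

    batch_size: int = Field(default=32, ge=1)
    learning_rate: float = Field(default=1e-4, ge=0)  # 0 freezes the model
    weight_decay: float = Field(default=1e-4, ge=0)
    max_epochs: int = Field(default=100, ge=1)
    patience: int = Field(default=10, ge=1)
    split: tuple[float, float, float] = (0.70, 0.15, 0.15)
    tasks: tuple[str, ...] = ("asym", "risk")
    augment: bool = True
    flip_prob: float = 0.5
    max_shift: int = 5
    noise_std: float = 0.01
    crop_range: tuple[float, float] = (0.8, 1.0)
    brightness: float = 0.2
    contrast: float = 0.2
    focal_gamma: float = 2.0
    focal_alpha: tuple[float, float, float] = (3.0, 1.5, 1.0)
    asym_class_weighting: bool = True
    seed: int = 0


@dataclass
class TrainState:
    """Model parameters plus optimizer/early-stopping bookkeeping."""

    net: MultimodalStrokeNet
    log_sigmas: Tensor
    model_config: ModelConfig
    train_config: TrainConfig
    kin_mean: np.ndarray
    kin_std: np.ndarray
    epoch: int = 0
    best_val_loss: float = np.inf
    patience_counter: int = 0
    stopped_epoch: Optional[int] = None
    history: pd.DataFrame = field(default_factory=pd.DataFrame)

    def sigmas(self) -> np.ndarray:
        return np.exp(self.log_sigmas.data)

    def weights(self) -> np.ndarray:
        return task_weights(self.log_sigmas.data)


class AdamW:
    """AdamW: Adam with decoupled weight decay."""

    def __init__(
        self,
        params: Sequence[Tensor],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
        no_decay: Sequence[Tensor] = (),
    ) -> None:
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.no_decay_ids = {id(p) for p in no_decay}
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            update = (self.m[i] / bc1) / (np.sqrt(self.v[i] / bc2) + self.eps)
            if self.weight_decay and id(p) not in self.no_decay_ids:
                update = update + self.weight_decay * p.data
            p.data -= self.lr * update


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

def augment(
    sample: StrokeSample,
    rng: np.random.Generator,
    *,
    flip_prob: float = 0.5,
    max_shift: int = 5,
    noise_std: float = 0.01,
    crop_range: tuple[float, float] = (0.8, 1.0),
    brightness: float = 0.2,
    contrast: float = 0.2,
) -> StrokeSample:
    """Label-preserving stochastic augmentation of one stroke sample.

    Horizontal flip (labels are side-agnostic, so only the handedness flag
    flips), temporal jitter within +/- ``max_shift`` frames (edge frames
    repeated), Gaussian keypoint noise, and crop/brightness/contrast jitter
    applied to the rendered RGB-feature grid.  Kinematic features must be
    recomputed downstream from the augmented keypoints.
    """
    seq = sample.keypoints
    handedness = sample.handedness
    if flip_prob > 0 and rng.random() < flip_prob:
        seq = mirror_keypoints(seq)
        handedness = "left" if handedness == "right" else "right"

    coords = seq.coords
    thor = seq.thoracic
    if max_shift > 0:
        shift = int(rng.integers(-max_shift, max_shift + 1))
        if shift:
            idx = np.clip(np.arange(coords.shape[0]) - shift, 0, coords.shape[0] - 1)
            coords = coords[idx]
            thor = None if thor is None else thor[idx]
    if noise_std > 0:
        scale = noise_std * sample.body_height
        coords = coords + rng.normal(0.0, scale, size=coords.shape)
        if thor is not None:
            thor = thor + rng.normal(0.0, scale, size=thor.shape)

    new_seq = replace(seq, coords=coords, thoracic=thor)
    crop = float(rng.uniform(*crop_range))
    bright = float(rng.uniform(-brightness, brightness)) if brightness else 0.0
    contr = 1.0 + (float(rng.uniform(-contrast, contrast)) if contrast else 0.0)
    rgb = render_rgb_features(
        new_seq, crop_scale=crop, brightness=bright, contrast=contr
    )
    return StrokeSample(
        keypoints=new_seq,
        stroke_type=sample.stroke_type,
        age=sample.age,
        handedness=handedness,
        body_height=sample.body_height,
        y_asym=sample.y_asym,
        y_injury=sample.y_injury,
        params=sample.params,
        rgb_features=rgb,
        sample_id=sample.sample_id,
    )


# ---------------------------------------------------------------------------
# Feature preparation
# ---------------------------------------------------------------------------

_ADJ_CACHE: dict[str, np.ndarray] = {}


def _adjacency_for(handedness: str) -> np.ndarray:
    if handedness not in _ADJ_CACHE:
        _ADJ_CACHE[handedness] = normalized_adjacency(build_skeleton_graph(handedness))
    return _ADJ_CACHE[handedness]


def prepare_batch(
    samples: Sequence[StrokeSample],
    kin_mean: Optional[np.ndarray] = None,
    kin_std: Optional[np.ndarray] = None,
) -> dict[str, np.ndarray]:
    """Encode samples into network inputs.

    Keypoints are z-normalized per sample (cancelling athlete size);
    kinematic features are standardized with the supplied training-set
    statistics; RGB features are rendered deterministically when the sample
    does not already carry them.
    """
    coords, kins, rgbs, adjs, y_a, y_r = [], [], [], [], [], []
    for s in samples:
        c = s.keypoints.coords
        c = (c - c.mean(axis=(0, 1))) / max(float(c.std()), 1e-9)
        coords.append(c)
        kins.append(kinematic_features(s.keypoints, body_height=s.body_height))
        rgbs.append(
            s.rgb_features
            if s.rgb_features is not None
            else render_rgb_features(s.keypoints)
        )
        adjs.append(_adjacency_for(s.handedness))
        y_a.append(int(s.y_asym))
        y_r.append(int(s.y_injury))
    kin = np.stack(kins)
    if kin_mean is not None:
        kin = (kin - kin_mean) / kin_std
    return {
        "coords": np.stack(coords),
        "kin": kin,
        "rgb": np.stack(rgbs),
        "a_norm": np.stack(adjs),
        "y_asym": np.asarray(y_a),
        "y_risk": np.asarray(y_r),
    }


def _kin_stats(samples: Sequence[StrokeSample]) -> tuple[np.ndarray, np.ndarray]:
    kin = np.stack(
        [kinematic_features(s.keypoints, body_height=s.body_height) for s in samples]
    )
    mean = kin.mean(axis=(0, 1))
    std = np.maximum(kin.std(axis=(0, 1)), 1e-9)
    return mean, std


def split_dataset(
    samples: Sequence[StrokeSample],
    split: tuple[float, float, float],
    seed: int,
) -> tuple[list[StrokeSample], list[StrokeSample], list[StrokeSample]]:
    """Shuffled train/validation/test split (default 70/15/15)."""
    if not np.isclose(sum(split), 1.0, atol=1e-6):
        raise ValueError("split fractions must sum to 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(samples))
    n_train = int(round(split[0] * len(samples)))
    n_val = int(round(split[1] * len(samples)))
    idx_train = order[:n_train]
    idx_val = order[n_train:n_train + n_val]
    idx_test = order[n_train + n_val:]
    if len(idx_train) == 0 or len(idx_val) == 0:
        raise ValueError("empty train or validation split")
    pick = lambda idx: [samples[i] for i in idx]
    return pick(idx_train), pick(idx_val), pick(idx_test)


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

def _epoch_losses(
    net: MultimodalStrokeNet,
    batch: dict[str, np.ndarray],
    tasks: tuple[str, ...],
    cfg: TrainConfig,
    asym_class_weights: Optional[np.ndarray] = None,
) -> tuple[Optional[Tensor], Optional[Tensor]]:
    logits_a, logits_r = net.forward(
        batch["coords"], batch["kin"], batch["rgb"], batch["a_norm"]
    )
    l_asym = (
        cross_entropy_from_logits(logits_a, batch["y_asym"], asym_class_weights)
        if "asym" in tasks else None
    )
    l_risk = (
        focal_loss_from_logits(
            logits_r, batch["y_risk"], gamma=cfg.focal_gamma, alpha=cfg.focal_alpha
        )
        if "risk" in tasks else None
    )
    return l_asym, l_risk


def train(
    samples: Sequence[StrokeSample],
    model_config: Optional[ModelConfig] = None,
    train_config: Optional[TrainConfig] = None,
) -> TrainState:
    """End-to-end training with uncertainty-weighted multi-task loss.

    Deterministic for a fixed seed.  Returns the fitted state; per-epoch
    losses, task weights w_i(t) and noise parameters sigma_i(t) are in
    ``state.history``.
    """
    cfg = train_config or TrainConfig()
    mcfg = model_config or ModelConfig()
    if not cfg.tasks or set(cfg.tasks) - {"asym", "risk"}:
        raise ValueError("tasks must be a non-empty subset of {'asym', 'risk'}")

    train_set, val_set, _ = split_dataset(samples, cfg.split, cfg.seed)
    kin_mean, kin_std = _kin_stats(train_set)

    # inverse-proportion class weights for the imbalanced asymmetry task
    asym_w = None
    if cfg.asym_class_weighting:
        counts = np.bincount([int(s.y_asym) for s in train_set], minlength=4)
        asym_w = len(train_set) / np.maximum(counts, 1).astype(float)

    net = MultimodalStrokeNet(mcfg)
    # log sigma initialized at 0 => sigma = 1 => w = 0.5 each (the fixed
    # equal-weighting baseline at initialization)
    log_sigmas = Tensor(np.zeros(2), requires_grad=True)
    opt = AdamW(
        net.parameters() + [log_sigmas],
        lr=cfg.learning_rate,
        weight_decay=cfg.weight_decay,
        no_decay=[log_sigmas],
    )
    state = TrainState(
        net=net,
        log_sigmas=log_sigmas,
        model_config=mcfg,
        train_config=cfg,
        kin_mean=kin_mean,
        kin_std=kin_std,
    )

    rng = np.random.default_rng(cfg.seed + 1)
    val_batch = prepare_batch(val_set, kin_mean, kin_std)
    train_batch_static = None
    if not cfg.augment:
        train_batch_static = prepare_batch(train_set, kin_mean, kin_std)

    history_rows = []
    for epoch in range(1, cfg.max_epochs + 1):
        state.epoch = epoch
        net.train(True)
        order = rng.permutation(len(train_set))
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            if cfg.augment:
                aug = [
                    augment(
                        train_set[i], rng,
                        flip_prob=cfg.flip_prob,
                        max_shift=cfg.max_shift,
                        noise_std=cfg.noise_std,
                        crop_range=cfg.crop_range,
                        brightness=cfg.brightness,
                        contrast=cfg.contrast,
                    )
                    for i in idx
                ]
                batch = prepare_batch(aug, kin_mean, kin_std)
            else:
                batch = {
                    k: v[idx] for k, v in train_batch_static.items()
                }
            opt.zero_grad()
            l_a, l_r = _epoch_losses(net, batch, cfg.tasks, cfg, asym_w)
            total = joint_loss_tensor(l_a, l_r, log_sigmas)
            total.backward()
            opt.step()
            epoch_loss += float(total.data)
            n_batches += 1

        # validation joint loss (eval mode, full objective incl. L2 term)
        net.train(False)
        vl_a, vl_r = _epoch_losses(net, val_batch, cfg.tasks, cfg, asym_w)
        val_joint = joint_loss(
            float(vl_a.data) if vl_a is not None else 0.0,
            float(vl_r.data) if vl_r is not None else 0.0,
            log_sigmas.data,
            params=[p.data for p in net.parameters()],
            lam=cfg.weight_decay,
        )
        w = task_weights(log_sigmas.data)
        history_rows.append(
            {
                "epoch": epoch,
                "train_loss": epoch_loss / max(n_batches, 1),
                "val_loss": val_joint,
                "val_l_asym": float(vl_a.data) if vl_a is not None else np.nan,
                "val_l_risk": float(vl_r.data) if vl_r is not None else np.nan,
                "w1": w[0],
                "w2": w[1],
                "sigma1": float(np.exp(log_sigmas.data[0])),
                "sigma2": float(np.exp(log_sigmas.data[1])),
            }
        )

        if val_joint < state.best_val_loss - 1e-12:
            state.best_val_loss = val_joint
            state.patience_counter = 0
        else:
            state.patience_counter += 1
            if state.patience_counter >= cfg.patience:
                state.stopped_epoch = epoch
                break

    state.history = pd.DataFrame(history_rows)
    return state


def predict_proba(
    state: TrainState, samples: Sequence[StrokeSample]
) -> tuple[np.ndarray, np.ndarray]:
    """(asymmetry probs (N, 4), risk probs (N, 3)) for a sample list."""
    batch = prepare_batch(samples, state.kin_mean, state.kin_std)
    return state.net.predict_proba(
        batch["coords"], batch["kin"], batch["rgb"], batch["a_norm"]
    )


# ---------------------------------------------------------------------------
# Checkpointing (single-file npz archive: config echo + parameter blobs)
# ---------------------------------------------------------------------------

def save_checkpoint(state: TrainState, path: str | Path) -> None:
    meta = {
        "schema": CHECKPOINT_SCHEMA,
        "model_config": state.model_config.model_dump(),
        "train_config": state.train_config.model_dump(),
        "epoch": state.epoch,
        "best_val_loss": state.best_val_loss,
        "stopped_epoch": state.stopped_epoch,
        "history": state.history.to_dict(orient="list"),
    }
    arrays = {f"net::{k}": v for k, v in state.net.state_arrays().items()}
    np.savez(
        path,
        __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        log_sigmas=state.log_sigmas.data,
        kin_mean=state.kin_mean,
        kin_std=state.kin_std,
        **arrays,
    )


def load_checkpoint(path: str | Path) -> TrainState:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta.get("schema") != CHECKPOINT_SCHEMA:
            raise ValueError(f"unrecognized checkpoint schema: {meta.get('schema')}")
        mcfg = ModelConfig(**meta["model_config"])
        tcfg = TrainConfig(**meta["train_config"])
        net = MultimodalStrokeNet(mcfg)
        net.load_state_arrays(
            {k[len("net::"):]: data[k] for k in data.files if k.startswith("net::")}
        )
        state = TrainState(
            net=net,
            log_sigmas=Tensor(data["log_sigmas"].copy(), requires_grad=True),
            model_config=mcfg,
            train_config=tcfg,
            kin_mean=data["kin_mean"].copy(),
            kin_std=data["kin_std"].copy(),
            epoch=meta["epoch"],
            best_val_loss=meta["best_val_loss"],
            stopped_epoch=meta["stopped_epoch"],
            history=pd.DataFrame(meta["history"]),
        )
    return state
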