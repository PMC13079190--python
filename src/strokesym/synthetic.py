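"""Seeded synthetic stroke-motion generator.

Real adolescent stroke recordings with expert asymmetry labels are access
restricted, so this module synthesizes labeled 30-frame keypoint sequences
with *controllable, recoverable* asymmetries.  The central testability
contract: every asymmetry magnitude is injected additively on the joint
angles **in the same geometric frame the indicator module measures in**, so
on noise-free data the measured indicator at the contact plateau equals the
injected magnitude to machine precision.

A stroke is built per frame by forward construction: pelvis -> hips (pelvic
tilt) -> torso and shoulder axis (trunk rotation, shoulder height offset)
-> thoracic landmark (spinal flexion bow) -> arms (shoulder rotation out of
the torso frontal plane) -> legs (hip flexion).  Bilateral joints are
symmetric whenever all asymmetry parameters are zero.  Injected magnitudes
follow a smooth envelope rising from stroke onset to a plateau that covers
the contact instant (phase 0.7 of the clip) — so the contact-window value
equals the requested magnitude — and ground-truth labels are produced by
running the rule labeler of :mod:`strokesym.indicators` on the noise-free
sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .indicators import (
    INDICATOR_NAMES,
    AsymmetryLabel,
    RiskLevel,
    Thresholds,
    classify_sequence,
    risk_level_sequence,
)
from .keypoints import KeypointSequence
from .skeleton import KEYPOINT_INDEX

__all__ = [
    "StrokeTemplate",
    "AsymmetryParams",
    "CohortConfig",
    "StrokeSample",
    "default_template",
    "generate_stroke",
    "generate_cohort",
    "render_rgb_features",
    "STROKE_TYPES",
]

STROKE_TYPES: tuple[str, ...] = ("forehand_drive", "backhand_push", "serve", "chop")

# body segment geometry, fractions of stature (H = 1)
_HIP_WIDTH = 0.13
_SHOULDER_WIDTH = 0.23
_TORSO_LEN = 0.30
_UPPER_ARM = 0.172
_FOREARM = 0.157
_THIGH = 0.245
_SHANK = 0.246
_HIP_HEIGHT = 0.53
_HEAD_OFFSET = 0.155

#: per-stroke base motion amplitudes (degrees except sway, body units)
_MOTION = {
    # arm_base + arm_amp stays below 45 deg so that an injected rotation
    # asymmetry of up to 44 deg remains inside the measurable (< 90 deg)
    # out-of-plane elevation range
    "forehand_drive": dict(trunk_rot=25.0, arm_base=12.0, arm_amp=30.0,
                           hip_base=15.0, hip_amp=10.0, sway=0.020),
    "backhand_push": dict(trunk_rot=12.0, arm_base=10.0, arm_amp=22.0,
                          hip_base=12.0, hip_amp=6.0, sway=0.010),
    "serve": dict(trunk_rot=30.0, arm_base=14.0, arm_amp=30.0,
                  hip_base=18.0, hip_amp=12.0, sway=0.030),
    "chop": dict(trunk_rot=18.0, arm_base=12.0, arm_amp=26.0,
                 hip_base=20.0, hip_amp=8.0, sway=0.015),
}


@dataclass(frozen=True)
class StrokeTemplate:
    """Parametric description of one stroke type's base (symmetric) motion."""

    stroke_type: str
    duration: int = 30
    preparation: float = 0.25   # phase fraction of the wind-up keyframe
    contact: float = 0.70       # phase fraction of ball contact
    follow_through: float = 1.0
    motion: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stroke_type not in STROKE_TYPES:
            raise ValueError(f"unknown stroke type: {self.stroke_type!r}")
        if not 0.0 < self.contact < 1.0:
            raise ValueError("contact phase fraction must lie in (0, 1)")
        if self.duration < 5:
            raise ValueError("stroke duration must cover at least 5 frames")
        if not self.motion:
            object.__setattr__(self, "motion", dict(_MOTION[self.stroke_type]))

    @property
    def contact_frame(self) -> int:
        return int(round(self.contact * (self.duration - 1)))


def default_template(stroke_type: str, duration: int = 30) -> StrokeTemplate:
    return StrokeTemplate(stroke_type=stroke_type, duration=duration)


@dataclass(frozen=True)
class AsymmetryParams:
    """Injected asymmetry magnitudes (all >= 0; zero = symmetric)."""

    shoulder_rot_asym: float = 0.0      # degrees
    shoulder_height_asym: float = 0.0   # fraction of body height
    spine_flexion: float = 0.0          # degrees
    hip_flexion_asym: float = 0.0       # degrees
    pelvic_tilt: float = 0.0            # degrees
    onset: float = 0.10                 # phase where the deviation starts
    peak: float = 0.45                  # phase where the plateau is reached

    def __post_init__(self) -> None:
        mags = (self.shoulder_rot_asym, self.shoulder_height_asym,
                self.spine_flexion, self.hip_flexion_asym, self.pelvic_tilt)
        if any(m < 0 for m in mags):
            raise ValueError("asymmetry magnitudes must be non-negative")
        if not 0.0 <= self.onset < self.peak <= 1.0:
            raise ValueError("need 0 <= onset < peak <= 1")
        if max(self.shoulder_rot_asym, self.hip_flexion_asym) > 45:
            raise ValueError("angular asymmetries above 45 degrees are not physical")

    def magnitudes(self) -> np.ndarray:
        return np.array([self.shoulder_rot_asym, self.shoulder_height_asym,
                         self.spine_flexion, self.hip_flexion_asym, self.pelvic_tilt])


@dataclass
class StrokeSample:
    """One labeled multimodal stroke sample."""

    keypoints: KeypointSequence          # observed (possibly noisy), world3d
    stroke_type: str
    age: int
    handedness: str
    body_height: float                   # metres
    y_asym: AsymmetryLabel
    y_injury: RiskLevel
    params: AsymmetryParams
    rgb_features: Optional[np.ndarray] = None   # (T, 256) when rendered
    sample_id: str = "sample"


def _envelope(phase: np.ndarray, onset: float, peak: float) -> np.ndarray:
    """Smooth rise from `onset` to a plateau of 1 from `peak` onward."""
    t = np.clip((phase - onset) / (peak - onset), 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * t))


def _swing(phase: np.ndarray, contact: float) -> np.ndarray:
    """Smooth 0 -> 1 -> small profile peaking exactly at the contact phase."""
    k = np.log(0.5) / np.log(contact)
    return np.sin(np.pi * np.clip(phase, 0.0, 1.0) ** k)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.maximum(np.linalg.norm(v, axis=-1, keepdims=True), 1e-12)


def generate_stroke(
    template: StrokeTemplate,
    params: AsymmetryParams,
    seed: int = 0,
    *,
    noise_std: float = 0.0,
    age: int = 14,
    handedness: str = "right",
    body_height: float = 1.60,
    frame_rate: float = 60.0,
    thresholds: Optional[Thresholds] = None,
) -> StrokeSample:
    """Generate one labeled stroke sample (deterministic given ``seed``).

    Asymmetries bias the *right* side; handedness only affects the graph
    weighting downstream (the rule labels are side-agnostic).  ``noise_std``
    is isotropic Gaussian keypoint jitter in body-height units; labels are
    always computed from the noise-free sequence.
    """
    if handedness not in ("left", "right"):
        raise ValueError(f"unknown handedness: {handedness!r}")
    rng = np.random.default_rng(seed)
    T = template.duration
    phase = np.arange(T) / (T - 1)
    env = _envelope(phase, params.onset, params.peak)
    g = _swing(phase, template.contact)
    m = template.motion

    rot_inj = np.radians(params.shoulder_rot_asym) * env
    h_inj = params.shoulder_height_asym * env
    spine_inj = np.radians(params.spine_flexion) * env
    hip_inj = np.radians(params.hip_flexion_asym) * env
    pelvis_inj = np.radians(params.pelvic_tilt) * env

    trunk_rot = np.radians(m["trunk_rot"]) * g
    arm_elev = np.radians(m["arm_base"] + m["arm_amp"] * g)
    hip_flex = np.radians(m["hip_base"] + m["hip_amp"] * g)

    J = len(KEYPOINT_INDEX)
    coords = np.zeros((T, J, 3))
    thoracic = np.zeros((T, 3))
    xhat = np.array([1.0, 0.0, 0.0])
    yhat = np.array([0.0, 1.0, 0.0])

    def put(name: str, t: int, p: np.ndarray) -> None:
        coords[t, KEYPOINT_INDEX[name]] = p

    for t in range(T):
        sway = m["sway"] * np.array([np.sin(2 * np.pi * phase[t]), 0.0,
                                     0.6 * np.sin(np.pi * phase[t])])
        mid_hip = np.array([0.0, _HIP_HEIGHT, 0.0]) + sway

        # hips: pelvic obliquity via exact height offset so that
        # arctan(dh / ||r_hip - l_hip||) recovers the injected angle
        tg = np.tan(pelvis_inj[t])
        dh = _HIP_WIDTH * tg / np.sqrt(max(1.0 - tg * tg, 1e-9))
        r_hip = mid_hip + 0.5 * _HIP_WIDTH * xhat + 0.5 * dh * yhat
        l_hip = mid_hip - 0.5 * _HIP_WIDTH * xhat - 0.5 * dh * yhat
        put("right_hip", t, r_hip)
        put("left_hip", t, l_hip)

        # torso and shoulder axis (trunk rotation about the vertical axis)
        mid_sh = mid_hip + _TORSO_LEN * yhat
        c, s = np.cos(trunk_rot[t]), np.sin(trunk_rot[t])
        axis = np.array([c, 0.0, -s])  # rotated shoulder axis
        r_sh = mid_sh + 0.5 * _SHOULDER_WIDTH * axis + h_inj[t] * yhat
        l_sh = mid_sh - 0.5 * _SHOULDER_WIDTH * axis
        put("right_shoulder", t, r_sh)
        put("left_shoulder", t, l_sh)

        # measurement frame (identical to the indicators module)
        cervical = 0.5 * (r_sh + l_sh)
        lumbar = 0.5 * (r_hip + l_hip)
        u = _unit(cervical - lumbar)
        sh_axis = _unit(r_sh - l_sh)
        lat = sh_axis - np.dot(sh_axis, u) * u
        lat = _unit(lat)
        s_c = float(np.linalg.norm(cervical - lumbar))
        # thoracic bow: alpha = arctan(-b) with b = 4 e_t / s_c
        e_t = -np.tan(spine_inj[t]) * s_c / 4.0
        thoracic[t] = lumbar + 0.5 * s_c * u + e_t * lat

        # arms: elevation out of the torso frontal plane, injected on the right
        up = u
        n = _unit(np.cross(sh_axis, up))
        down = -up
        for side, sh, elev in (("right", r_sh, arm_elev[t] + rot_inj[t]),
                               ("left", l_sh, arm_elev[t])):
            u_arm = np.cos(elev) * down + np.sin(elev) * n
            elbow = sh + _UPPER_ARM * u_arm
            bend = 0.35 + 0.5 * g[t]
            f_dir = _unit(u_arm + bend * n)
            wrist = elbow + _FOREARM * f_dir
            put(f"{side}_elbow", t, elbow)
            put(f"{side}_wrist", t, wrist)

        # legs: hip flexion about the lateral axis, injected on the right
        for side, hip, sh, flex in (("right", r_hip, r_sh, hip_flex[t] + hip_inj[t]),
                                    ("left", l_hip, l_sh, hip_flex[t])):
            v = _unit(sh - hip)
            w = xhat - np.dot(xhat, v) * v
            w = _unit(w)
            thigh = -v * np.cos(flex) + np.cross(w, -v) * np.sin(flex)
            knee = hip + _THIGH * thigh
            shank_ang = 0.3 * flex
            shank = -v * np.cos(shank_ang) + np.cross(w, -v) * np.sin(shank_ang)
            ankle = knee + _SHANK * shank
            put(f"{side}_knee", t, knee)
            put(f"{side}_ankle", t, ankle)

        # head, symmetric about the torso axis
        nose = cervical + _HEAD_OFFSET * u
        put("nose", t, nose)
        put("right_eye", t, nose + 0.030 * sh_axis + 0.020 * u)
        put("left_eye", t, nose - 0.030 * sh_axis + 0.020 * u)
        put("right_ear", t, nose + 0.060 * sh_axis)
        put("left_ear", t, nose - 0.060 * sh_axis)

    clean = KeypointSequence(
        coords=coords * body_height,
        frame_rate=frame_rate,
        coordinate_mode="world3d",
        thoracic=thoracic * body_height,
    )
    y_asym, _ = classify_sequence(clean, thresholds, body_height=body_height)
    y_injury, _ = risk_level_sequence(clean, thresholds, body_height=body_height)

    if noise_std > 0:
        jitter = rng.normal(0.0, noise_std * body_height, size=coords.shape)
        jitter_th = rng.normal(0.0, noise_std * body_height, size=thoracic.shape)
        observed = KeypointSequence(
            coords=coords * body_height + jitter,
            frame_rate=frame_rate,
            coordinate_mode="world3d",
            thoracic=thoracic * body_height + jitter_th,
        )
    else:
        observed = clean

    return StrokeSample(
        keypoints=observed,
        stroke_type=template.stroke_type,
        age=age,
        handedness=handedness,
        body_height=body_height,
        y_asym=y_asym,
        y_injury=y_injury,
        params=params,
    )


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

class CohortConfig(BaseModel):
    """Study-condition configuration for a synthetic cohort.

    Defaults mirror the reported class mix of the adolescent stroke corpus:
    risk levels low/medium/high = 62.8 / 30.5 / 6.7 % (about a 1:15
    high-to-low imbalance) and asymmetry classes normal/shoulder/trunk/hip
    = 38.2 / 27.5 / 21.3 / 13.0 %.  Under the rule labeler "normal" and
    "low risk" coincide, so risk proportions are sampled directly and the
    asymmetry proportions steer which body segment exceeds among the
    non-normal samples (renormalized over shoulder/trunk/hip).
    """

    n_samples: int = Field(default=100, ge=1)
    risk_proportions: tuple[float, float, float] = (0.628, 0.305, 0.067)
    asym_proportions: tuple[float, float, float, float] = (0.382, 0.275, 0.213, 0.130)
    ages: tuple[int, ...] = (12, 13, 14, 15, 16, 17)
    right_handed_fraction: float = Field(default=0.85, ge=0.0, le=1.0)
    noise_std: float = Field(default=0.01, ge=0.0)
    effect_margin: tuple[float, float] = (1.3, 2.2)   # exceedance, x threshold
    subthreshold_cap: float = Field(default=0.6, gt=0.0, lt=1.0)
    duration: int = 30
    frame_rate: float = 60.0
    seed: int = 0

    @model_validator(mode="after")
    def _check_proportions(self) -> "CohortConfig":
        for name, props in (("risk_proportions", self.risk_proportions),
                            ("asym_proportions", self.asym_proportions)):
            arr = np.asarray(props, float)
            if np.any(arr < 0) or not np.isclose(arr.sum(), 1.0, atol=1e-6):
                raise ValueError(f"{name} must be non-negative and sum to 1")
        if not 1.0 < self.effect_margin[0] < self.effect_margin[1]:
            raise ValueError("effect_margin must satisfy 1 < lo < hi")
        return self


_SEGMENTS = ("shoulder", "trunk", "hip")


def _draw_params(
    rng: np.random.Generator,
    risk: RiskLevel,
    seg_probs: np.ndarray,
    thr: Thresholds,
    lo: float,
    hi: float,
    cap: float,
) -> AsymmetryParams:
    """Label-conditional asymmetry magnitudes guaranteeing the rule outcome."""
    seg_thr = {
        "shoulder": (("shoulder_rot_asym", thr.shoulder_rot),
                     ("shoulder_height_asym", thr.shoulder_height)),
        "trunk": (("spine_flexion", thr.spine_flexion),),
        "hip": (("hip_flexion_asym", thr.hip_flexion),
                ("pelvic_tilt", thr.pelvic_tilt)),
    }
    if risk == RiskLevel.LOW:
        exceed: list[str] = []
    elif risk == RiskLevel.MEDIUM:
        exceed = [str(rng.choice(_SEGMENTS, p=seg_probs))]
    else:
        k = 2 if rng.random() < 0.8 else 3
        exceed = list(rng.choice(_SEGMENTS, size=k, replace=False, p=seg_probs))

    mags: dict[str, float] = {}
    for seg in _SEGMENTS:
        fields = seg_thr[seg]
        if seg in exceed:
            # at least one indicator of the segment exceeds; 25 % chance both do
            over = [rng.integers(len(fields))]
            if len(fields) > 1 and rng.random() < 0.25:
                over = list(range(len(fields)))
            for i, (name, t) in enumerate(fields):
                if i in over:
                    mags[name] = t * rng.uniform(lo, hi)
                else:
                    mags[name] = t * rng.uniform(0.0, cap)
        else:
            for name, t in fields:
                mags[name] = t * rng.uniform(0.0, cap)
    # cap angular injections at the physical limit
    mags["shoulder_rot_asym"] = min(mags["shoulder_rot_asym"], 44.0)
    mags["hip_flexion_asym"] = min(mags["hip_flexion_asym"], 44.0)
    return AsymmetryParams(**mags)


def generate_cohort(
    config: CohortConfig,
    thresholds: Optional[Thresholds] = None,
) -> tuple[list[StrokeSample], pd.DataFrame]:
    """Generate a labeled cohort plus a stratified manifest.

    Risk labels are drawn from ``risk_proportions``; the exceeding body
    segments are drawn from the (renormalized) asymmetry proportions, and
    indicator magnitudes from label-conditional ranges, so the rule oracle
    reproduces the drawn labels on the noise-free trajectories.
    """
    thr = thresholds or Thresholds()
    rng = np.random.default_rng(config.seed)
    seg_probs = np.asarray(config.asym_proportions[1:], float)
    if seg_probs.sum() <= 0:
        raise ValueError("asymmetry proportions leave no non-normal mass")
    seg_probs = seg_probs / seg_probs.sum()
    lo, hi = config.effect_margin

    samples: list[StrokeSample] = []
    rows = []
    for i in range(config.n_samples):
        risk = RiskLevel(int(rng.choice(3, p=np.asarray(config.risk_proportions))))
        params = _draw_params(rng, risk, seg_probs, thr, lo, hi, config.subthreshold_cap)
        stroke = str(rng.choice(STROKE_TYPES))
        age = int(rng.choice(config.ages))
        handed = "right" if rng.random() < config.right_handed_fraction else "left"
        height = float(np.clip(rng.normal(1.50 + 0.04 * (age - 12), 0.07), 1.30, 2.00))
        sample = generate_stroke(
            default_template(stroke, config.duration),
            params,
            seed=int(rng.integers(2**31 - 1)),
            noise_std=config.noise_std,
            age=age,
            handedness=handed,
            body_height=height,
            frame_rate=config.frame_rate,
            thresholds=thr,
        )
        sample.sample_id = f"s{i:05d}"
        samples.append(sample)
        rows.append(
            {
                "sample_id": sample.sample_id,
                "stroke_type": stroke,
                "age": age,
                "handedness": handed,
                "body_height": height,
                "y_asym": sample.y_asym.name,
                "y_injury": sample.y_injury.name,
                **{f"inj_{k}": v for k, v in zip(
                    ("shoulder_rot", "shoulder_height", "spine_flexion",
                     "hip_flexion", "pelvic_tilt"),
                    params.magnitudes(),
                )},
            }
        )
    return samples, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Deterministic RGB-modality stand-in
# ---------------------------------------------------------------------------

_RENDER_EDGES: tuple[tuple[str, str], ...] = (
    ("nose", "left_eye"), ("nose", "right_eye"),
    ("left_eye", "left_ear"), ("right_eye", "right_ear"),
    ("left_shoulder", "right_shoulder"),
    ("left_shoulder", "left_elbow"), ("right_shoulder", "right_elbow"),
    ("left_elbow", "left_wrist"), ("right_elbow", "right_wrist"),
    ("left_shoulder", "left_hip"), ("right_shoulder", "right_hip"),
    ("left_hip", "right_hip"),
    ("left_hip", "left_knee"), ("right_hip", "right_knee"),
    ("left_knee", "left_ankle"), ("right_knee", "right_ankle"),
)


def render_rgb_features(
    sample: StrokeSample | KeypointSequence,
    dim: int = 256,
    *,
    points_per_edge: int = 8,
    crop_scale: float = 1.0,
    brightness: float = 0.0,
    contrast: float = 1.0,
) -> np.ndarray:
    """Per-frame stick-figure occupancy encoding, shape (T, dim).

    The frontal projection of the pose is rasterized onto a sqrt(dim) x
    sqrt(dim) occupancy grid (normalized to the clip bounding box) and
    flattened, so the "RGB" modality carries genuine pose information
    without pixels or pretrained networks.  ``crop_scale`` shrinks the pose
    about its centroid (random-crop augmentation); brightness/contrast
    jitter act on grid values.  Deterministic.
    """
    grid = int(round(np.sqrt(dim)))
    if grid * grid != dim:
        raise ValueError(f"dim must be a perfect square, got {dim}")
    seq = sample.keypoints if isinstance(sample, StrokeSample) else sample
    if seq.coordinate_mode == "world3d":
        xy = seq.coords[:, :, :2].copy()      # frontal (x, y) projection
    else:
        xy = seq.coords.copy()
        xy[:, :, 1] *= -1.0
    if crop_scale != 1.0:
        center = xy.reshape(-1, 2).mean(axis=0)
        xy = center + crop_scale * (xy - center)

    lo = xy.reshape(-1, 2).min(axis=0)
    hi = xy.reshape(-1, 2).max(axis=0)
    span = np.maximum(hi - lo, 1e-9)
    norm = (xy - lo) / span    # [0, 1]^2 per clip

    T = norm.shape[0]
    a_idx = [KEYPOINT_INDEX[a] for a, _ in _RENDER_EDGES]
    b_idx = [KEYPOINT_INDEX[b] for _, b in _RENDER_EDGES]
    w = np.linspace(0.0, 1.0, points_per_edge)[None, None, :, None]
    pts = norm[:, a_idx, None, :] * (1 - w) + norm[:, b_idx, None, :] * w
    cells = np.clip((pts * grid).astype(int), 0, grid - 1)   # (T, E, S, 2)
    occupancy = np.zeros((T, grid, grid))
    t_ix = np.repeat(np.arange(T), cells.shape[1] * cells.shape[2])
    col = cells[:, :, :, 0].ravel()
    row = cells[:, :, :, 1].ravel()
    occupancy[t_ix, row, col] = 1.0

    occupancy = np.clip(contrast * (occupancy - 0.5) + 0.5 + brightness, 0.0, 1.0)
    return occupancy.reshape(T, dim)
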