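"""Posture-asymmetry indicators, threshold rules and kinematic features.

Six indicators quantify left-right imbalance of a stroke posture:

========================  =======================================  ========
indicator                 definition                               units
========================  =======================================  ========
``delta_theta_shoulder``  |theta_r - theta_l| shoulder rotation    degrees
``delta_h_shoulder``      |y_r - y_l| / H_body shoulder height     unitless
``alpha_spine``           arctan(-b) of quadratic spine fit        degrees
``trunk_rotation``        shoulder axis vs hip axis (transverse)   degrees
``delta_theta_hip``       |theta_r - theta_l| hip flexion          degrees
``gamma_pelvis``          arctan((h_r - h_l) / d_hip) pelvic tilt  degrees
========================  =======================================  ========

Threshold rules (adolescent defaults): shoulder asymmetry when the rotation
difference exceeds 15 deg or the height ratio exceeds 0.05; trunk asymmetry
when the spinal lateral flexion magnitude exceeds 8 deg; hip asymmetry when
the flexion difference exceeds 10 deg or the pelvic tilt magnitude exceeds
5 deg.  Risk stratification counts body segments (shoulder / trunk / hip)
in simultaneous exceedance: none -> low, one -> medium, two or more -> high.

Coordinate conventions: ``image2d`` uses origin top-left with y increasing
downward (height = -y); ``world3d`` is y-up, right-handed.  All angles are
reported in degrees.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .keypoints import KeypointSequence
from .skeleton import KEYPOINT_INDEX

__all__ = [
    "INDICATOR_NAMES",
    "AsymmetryLabel",
    "RiskLevel",
    "AsymmetryIndicators",
    "Thresholds",
    "AgeNorms",
    "shoulder_rotation_difference",
    "shoulder_height_difference",
    "spinal_lateral_flexion",
    "pelvic_tilt",
    "hip_flexion_difference",
    "trunk_rotation_angle",
    "age_normalize",
    "indicator_series",
    "kinematic_features",
    "classify_asymmetry",
    "assign_risk_level",
    "segment_exceedances",
    "classify_sequence",
    "risk_level_sequence",
    "estimate_body_height",
    "interpolate_low_confidence",
    "lift_to_3d",
    "ANTHROPOMETRIC_RATIOS",
]

INDICATOR_NAMES: tuple[str, ...] = (
    "delta_theta_shoulder",
    "delta_h_shoulder",
    "alpha_spine",
    "trunk_rotation",
    "delta_theta_hip",
    "gamma_pelvis",
)


class AsymmetryLabel(enum.IntEnum):
    """Four-class posture asymmetry label (ordered by rule precedence only)."""

    NORMAL = 0
    SHOULDER = 1
    TRUNK = 2
    HIP = 3


class RiskLevel(enum.IntEnum):
    """Three-level biomechanical vulnerability (higher = more severe)."""

    LOW = 0
    MEDIUM = 1
    HIGH = 2


@dataclass(frozen=True)
class AsymmetryIndicators:
    """One window's worth of the six indicator values."""

    delta_theta_shoulder: float
    delta_h_shoulder: float
    alpha_spine: float
    trunk_rotation: float
    delta_theta_hip: float
    gamma_pelvis: float

    def __post_init__(self) -> None:
        arr = self.as_array()
        if not np.all(np.isfinite(arr)):
            raise ValueError("indicators must be finite")
        if self.delta_theta_shoulder < 0 or self.delta_h_shoulder < 0 or self.delta_theta_hip < 0:
            raise ValueError("difference indicators must be non-negative")
        angles = (self.delta_theta_shoulder, abs(self.alpha_spine),
                  self.trunk_rotation, self.delta_theta_hip, abs(self.gamma_pelvis))
        if any(a >= 180.0 for a in angles):
            raise ValueError("angle magnitudes must lie in [0, 180)")

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.delta_theta_shoulder,
                self.delta_h_shoulder,
                self.alpha_spine,
                self.trunk_rotation,
                self.delta_theta_hip,
                self.gamma_pelvis,
            ]
        )

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "AsymmetryIndicators":
        return cls(*(float(v) for v in arr))


class Thresholds(BaseModel):
    """Clinical decision thresholds (adolescent operating defaults).

    ``adult_reduction`` encodes the 10-15 % tightening of adolescent
    criteria relative to adult reference values: the corresponding adult
    threshold is ``value / (1 - adult_reduction)``.
    """

    shoulder_rot: float = Field(default=15.0, gt=0, description="degrees")
    shoulder_height: float = Field(default=0.05, gt=0, description="fraction of body height")
    spine_flexion: float = Field(default=8.0, gt=0, description="degrees")
    hip_flexion: float = Field(default=10.0, gt=0, description="degrees")
    pelvic_tilt: float = Field(default=5.0, gt=0, description="degrees")
    adult_reduction: float = Field(default=0.125, ge=0.10, le=0.15)

    def adult_reference(self) -> "Thresholds":
        f = 1.0 / (1.0 - self.adult_reduction)
        return Thresholds(
            shoulder_rot=self.shoulder_rot * f,
            shoulder_height=self.shoulder_height * f,
            spine_flexion=self.spine_flexion * f,
            hip_flexion=self.hip_flexion * f,
            pelvic_tilt=self.pelvic_tilt * f,
            adult_reduction=self.adult_reduction,
        )


# ---------------------------------------------------------------------------
# Scalar indicator formulas
# ---------------------------------------------------------------------------

def shoulder_rotation_difference(theta_right: float, theta_left: float) -> float:
    """Absolute left-right shoulder rotation angle difference in degrees."""
    if not (np.isfinite(theta_right) and np.isfinite(theta_left)):
        raise ValueError("rotation angles must be finite")
    return abs(float(theta_right) - float(theta_left))


def shoulder_height_difference(y_right: float, y_left: float, body_height: float) -> float:
    """Shoulder height gap normalized by body height (dimensionless)."""
    if body_height <= 0:
        raise ValueError("body_height must be positive")
    return abs(float(y_right) - float(y_left)) / float(body_height)


def spinal_lateral_flexion(
    cervical: Sequence[float],
    thoracic: Sequence[float],
    lumbar: Sequence[float],
) -> tuple[float, tuple[float, float, float]]:
    """Lateral flexion angle from a quadratic through three spine landmarks.

    The three points are interpreted as (abscissa, ordinate) pairs in the
    spine-aligned frame (abscissa along the cervical-lumbar axis, ordinate
    the lateral deviation).  The interpolating quadratic ``y = a x^2 + b x
    + c`` yields the flexion angle ``arctan(2 a x_vertex)`` which is
    algebraically ``arctan(-b)``; the latter form remains defined for a = 0
    (collinear landmarks, pure lean).  Returns ``(angle_deg, (a, b, c))``.
    """
    pts = np.array([cervical, thoracic, lumbar], dtype=float)
    if pts.shape != (3, 2):
        raise ValueError("each landmark must be an (abscissa, ordinate) pair")
    x, y = pts[:, 0], pts[:, 1]
    if len(np.unique(x)) != 3:
        raise ValueError("degenerate geometry: duplicated spine abscissae")
    # exact interpolation through the three points (Vandermonde solve)
    a, b, c = np.linalg.solve(np.vander(x, 3), y)
    return float(np.degrees(np.arctan(-b))), (float(a), float(b), float(c))


def pelvic_tilt(
    h_right: float,
    h_left: float,
    hip_right: Sequence[float],
    hip_left: Sequence[float],
) -> float:
    """Signed pelvic obliquity ``arctan((h_r - h_l) / d_hip)`` in degrees."""
    d_hip = float(np.linalg.norm(np.asarray(hip_right, float) - np.asarray(hip_left, float)))
    if d_hip <= 1e-12:
        raise ValueError("degenerate geometry: coincident hip joints")
    return float(np.degrees(np.arctan((float(h_right) - float(h_left)) / d_hip)))


def hip_flexion_difference(theta_right: float, theta_left: float) -> float:
    """Absolute left-right hip flexion angle difference in degrees."""
    return shoulder_rotation_difference(theta_right, theta_left)


def trunk_rotation_angle(
    shoulder_line: Sequence[Sequence[float]],
    hip_line: Sequence[Sequence[float]],
) -> float:
    """Unsigned angle between the shoulder axis and the hip axis, in [0, 90].

    3D lines are projected onto the transverse (horizontal) plane first;
    2D lines are compared in the image plane directly.
    """
    s = np.asarray(shoulder_line, float)
    h = np.asarray(hip_line, float)
    vs = s[1] - s[0]
    vh = h[1] - h[0]
    if vs.shape[-1] == 3:  # world3d is y-up: transverse plane drops y
        vs = vs[[0, 2]]
        vh = vh[[0, 2]]
    ns, nh = np.linalg.norm(vs), np.linalg.norm(vh)
    if ns <= 1e-12 or nh <= 1e-12:
        raise ValueError("degenerate geometry: zero-length body axis")
    cosang = abs(float(np.dot(vs, vh)) / (ns * nh))
    return float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))


# ---------------------------------------------------------------------------
# Age normalization
# ---------------------------------------------------------------------------

@dataclass
class AgeNorms:
    """Per-age-group indicator means and standard deviations (ages 12-17)."""

    entries: Mapping[tuple[str, int], tuple[float, float]]

    @classmethod
    def from_cohort(
        cls, indicator_values: pd.DataFrame
    ) -> "AgeNorms":
        """Build norms from a tidy frame with columns indicator, age, value."""
        entries = {}
        for (ind, age), grp in indicator_values.groupby(["indicator", "age"]):
            entries[(str(ind), int(age))] = (
                float(grp["value"].mean()),
                float(grp["value"].std(ddof=1)),
            )
        return cls(entries)


def age_normalize(value: float, age: int, indicator: str, norms: AgeNorms) -> float:
    """Z-score an indicator against same-age peers: (raw - mu) / sigma."""
    key = (indicator, int(age))
    if key not in norms.entries:
        raise ValueError(f"no age norm for {key}")
    mu, sigma = norms.entries[key]
    if not sigma > 0:
        raise ValueError(f"age norm sigma must be positive for {key}")
    return (float(value) - mu) / sigma


# ---------------------------------------------------------------------------
# Per-frame indicator series from a keypoint sequence (vectorized)
# ---------------------------------------------------------------------------

def _norm(v: np.ndarray, axis: int = -1) -> np.ndarray:
    return np.linalg.norm(v, axis=axis, keepdims=True)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.maximum(_norm(v), 1e-12)


def estimate_body_height(seq: KeypointSequence) -> float:
    """Stature proxy: nose-to-mid-ankle span / 0.93, averaged over frames."""
    h = seq.heights()
    nose = h[:, KEYPOINT_INDEX["nose"]]
    ankles = 0.5 * (h[:, KEYPOINT_INDEX["left_ankle"]] + h[:, KEYPOINT_INDEX["right_ankle"]])
    span = float(np.mean(np.abs(nose - ankles)))
    if span <= 0:
        raise ValueError("cannot estimate body height from a degenerate pose")
    return span / 0.93


def _side_shoulder_rotation(seq: KeypointSequence) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame shoulder rotation angle for (right, left), degrees.

    3D: elevation of the upper-arm vector out of the torso frontal plane
    (plane spanned by the shoulder axis and the torso longitudinal axis).
    2D: unsigned angle between the upper-arm vector and the downward torso
    axis (arms hanging along the torso read as zero).
    """
    c = seq.coords
    ls, rs = c[:, KEYPOINT_INDEX["left_shoulder"]], c[:, KEYPOINT_INDEX["right_shoulder"]]
    lh, rh = c[:, KEYPOINT_INDEX["left_hip"]], c[:, KEYPOINT_INDEX["right_hip"]]
    le, re = c[:, KEYPOINT_INDEX["left_elbow"]], c[:, KEYPOINT_INDEX["right_elbow"]]
    mid_sh, mid_hip = 0.5 * (ls + rs), 0.5 * (lh + rh)
    up = _unit(mid_sh - mid_hip)
    u_r, u_l = _unit(re - rs), _unit(le - ls)
    if seq.n_dims == 3:
        axis = _unit(rs - ls)
        n = _unit(np.cross(axis, up))
        sin_r = np.clip(np.abs(np.sum(u_r * n, axis=-1)), 0.0, 1.0)
        sin_l = np.clip(np.abs(np.sum(u_l * n, axis=-1)), 0.0, 1.0)
        return np.degrees(np.arcsin(sin_r)), np.degrees(np.arcsin(sin_l))
    down = -up
    cos_r = np.clip(np.sum(u_r * down, axis=-1), -1.0, 1.0)
    cos_l = np.clip(np.sum(u_l * down, axis=-1), -1.0, 1.0)
    return np.degrees(np.arccos(cos_r)), np.degrees(np.arccos(cos_l))


def _side_hip_flexion(seq: KeypointSequence) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame hip flexion for (right, left): 180 deg minus the angle
    between the hip-to-shoulder and hip-to-knee vectors (0 when standing)."""
    c = seq.coords
    out = []
    for side in ("right", "left"):
        hip = c[:, KEYPOINT_INDEX[f"{side}_hip"]]
        sh = c[:, KEYPOINT_INDEX[f"{side}_shoulder"]]
        knee = c[:, KEYPOINT_INDEX[f"{side}_knee"]]
        v_t, v_k = _unit(sh - hip), _unit(knee - hip)
        cosang = np.clip(np.sum(v_t * v_k, axis=-1), -1.0, 1.0)
        out.append(180.0 - np.degrees(np.arccos(cosang)))
    return out[0], out[1]


def _spine_landmarks(seq: KeypointSequence) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    c = seq.coords
    ls, rs = c[:, KEYPOINT_INDEX["left_shoulder"]], c[:, KEYPOINT_INDEX["right_shoulder"]]
    lh, rh = c[:, KEYPOINT_INDEX["left_hip"]], c[:, KEYPOINT_INDEX["right_hip"]]
    cervical = 0.5 * (ls + rs)
    lumbar = 0.5 * (lh + rh)
    if seq.thoracic is not None:
        thoracic = seq.thoracic
    else:
        # COCO-17 has no spine joints: default proxy is the torso midpoint,
        # which is collinear with the chord, so alpha degenerates to 0.
        thoracic = 0.5 * (cervical + lumbar)
    return cervical, thoracic, lumbar


def _alpha_spine_series(seq: KeypointSequence) -> np.ndarray:
    """Vectorized spinal lateral flexion per frame (degrees, signed)."""
    cervical, thoracic, lumbar = _spine_landmarks(seq)
    c = seq.coords
    ls, rs = c[:, KEYPOINT_INDEX["left_shoulder"]], c[:, KEYPOINT_INDEX["right_shoulder"]]
    u = _unit(cervical - lumbar)  # spine chord, abscissa axis
    # lateral (ordinate) axis: shoulder-axis component orthogonal to the chord
    axis = rs - ls
    lat = axis - np.sum(axis * u, axis=-1, keepdims=True) * u
    lat_n = np.linalg.norm(lat, axis=-1)
    ok = lat_n > 1e-12
    if seq.n_dims == 2:
        # rotate u by 90 degrees where the shoulder axis degenerates
        fallback = np.stack([-u[:, 1], u[:, 0]], axis=-1)
    else:
        fallback = np.cross(u, np.broadcast_to([0.0, 0.0, 1.0], u.shape))
    e = np.where(ok[:, None], lat / np.maximum(lat_n, 1e-12)[:, None], _unit(fallback))
    s_c = np.sum((cervical - lumbar) * u, axis=-1)
    s_t = np.sum((thoracic - lumbar) * u, axis=-1)
    e_t = np.sum((thoracic - lumbar) * e, axis=-1)
    e_c = np.sum((cervical - lumbar) * e, axis=-1)  # 0 up to roundoff
    # interpolating quadratic through (0, 0), (s_t, e_t), (s_c, e_c):
    # slope at the lumbar origin b = (e_t * s_c / s_t - e_c * s_t / s_c) / (s_c - s_t)
    denom = s_t * s_c * (s_c - s_t)
    bad = np.abs(denom) <= 1e-12
    b = np.where(
        bad, 0.0,
        (e_t * s_c**2 - e_c * s_t**2) / np.where(bad, 1.0, denom),
    )
    return np.degrees(np.arctan(-b))


def indicator_series(
    seq: KeypointSequence,
    body_height: Optional[float] = None,
) -> np.ndarray:
    """Per-frame (T, 6) matrix of the six asymmetry indicators.

    Column order follows :data:`INDICATOR_NAMES`.  ``body_height`` (same
    units as the coordinates) is estimated from the pose when omitted.
    """
    if body_height is None:
        body_height = estimate_body_height(seq)
    c = seq.coords
    h = seq.heights()
    th_r, th_l = _side_shoulder_rotation(seq)
    d_theta_sh = np.abs(th_r - th_l)
    d_h_sh = np.abs(
        h[:, KEYPOINT_INDEX["right_shoulder"]] - h[:, KEYPOINT_INDEX["left_shoulder"]]
    ) / body_height
    alpha = _alpha_spine_series(seq)

    ls, rs = c[:, KEYPOINT_INDEX["left_shoulder"]], c[:, KEYPOINT_INDEX["right_shoulder"]]
    lh, rh = c[:, KEYPOINT_INDEX["left_hip"]], c[:, KEYPOINT_INDEX["right_hip"]]
    vs, vh = rs - ls, rh - lh
    if seq.n_dims == 3:
        vs, vh = vs[:, [0, 2]], vh[:, [0, 2]]
    cosang = np.abs(np.sum(_unit(vs) * _unit(vh), axis=-1))
    trunk_rot = np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0)))

    hip_r, hip_l = _side_hip_flexion(seq)
    d_theta_hip = np.abs(hip_r - hip_l)

    d_hip = np.linalg.norm(rh - lh, axis=-1)
    if np.any(d_hip <= 1e-12):
        raise ValueError("degenerate geometry: coincident hip joints")
    gamma = np.degrees(
        np.arctan(
            (h[:, KEYPOINT_INDEX["right_hip"]] - h[:, KEYPOINT_INDEX["left_hip"]]) / d_hip
        )
    )
    return np.stack([d_theta_sh, d_h_sh, alpha, trunk_rot, d_theta_hip, gamma], axis=1)


def kinematic_features(
    seq: KeypointSequence,
    window: int = 5,
    body_height: Optional[float] = None,
) -> np.ndarray:
    """Sliding-window 12-d biomechanical descriptor, shape (T - window + 1, 12).

    Each window yields the six indicators averaged over the window followed
    by their six first temporal derivatives, taken as the end-to-end central
    difference across the window, in indicator units per second.
    """
    if window < 2:
        raise ValueError("window must cover at least 2 frames")
    if seq.n_frames < window:
        raise ValueError(f"sequence has {seq.n_frames} frames; window needs {window}")
    ind = indicator_series(seq, body_height=body_height)
    t_out = seq.n_frames - window + 1
    # windowed mean via cumulative sum
    cs = np.vstack([np.zeros((1, ind.shape[1])), np.cumsum(ind, axis=0)])
    means = (cs[window:] - cs[:-window]) / window
    dt = (window - 1) / seq.frame_rate
    derivs = (ind[window - 1:] - ind[:t_out]) / dt
    return np.concatenate([means, derivs], axis=1)


# ---------------------------------------------------------------------------
# Rule labeler
# ---------------------------------------------------------------------------

def _indicator_matrix(ind) -> np.ndarray:
    if isinstance(ind, AsymmetryIndicators):
        return ind.as_array()[None, :]
    arr = np.asarray(ind, float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.shape[1] != len(INDICATOR_NAMES):
        raise ValueError("expected 6 indicator columns")
    return arr


def _relative_excess(arr: np.ndarray, thr: Thresholds) -> np.ndarray:
    """(N, 3) threshold-relative excess per body segment (shoulder/trunk/hip)."""
    sh = np.maximum(
        (arr[:, 0] - thr.shoulder_rot) / thr.shoulder_rot,
        (arr[:, 1] - thr.shoulder_height) / thr.shoulder_height,
    )
    tr = (np.abs(arr[:, 2]) - thr.spine_flexion) / thr.spine_flexion
    hp = np.maximum(
        (arr[:, 4] - thr.hip_flexion) / thr.hip_flexion,
        (np.abs(arr[:, 5]) - thr.pelvic_tilt) / thr.pelvic_tilt,
    )
    return np.stack([sh, tr, hp], axis=1)


def segment_exceedances(ind, thr: Optional[Thresholds] = None) -> np.ndarray:
    """(N, 3) boolean: does each body segment exceed its threshold(s)?"""
    thr = thr or Thresholds()
    return _relative_excess(_indicator_matrix(ind), thr) > 0


def classify_asymmetry(ind, thr: Optional[Thresholds] = None):
    """Four-class asymmetry label from the threshold rules.

    Multi-segment ties resolve to the segment with the largest
    threshold-relative excess (the lossy single-label compression; the risk
    level is where multi-segment information lives).
    """
    thr = thr or Thresholds()
    arr = _indicator_matrix(ind)
    excess = _relative_excess(arr, thr)
    fired = excess > 0
    seg_labels = np.array([AsymmetryLabel.SHOULDER, AsymmetryLabel.TRUNK, AsymmetryLabel.HIP])
    labels = np.where(
        fired.any(axis=1),
        seg_labels[np.argmax(excess, axis=1)],
        AsymmetryLabel.NORMAL,
    )
    out = np.array([AsymmetryLabel(int(v)) for v in labels], dtype=object)
    if isinstance(ind, AsymmetryIndicators) or np.asarray(ind, float).ndim == 1:
        return out[0]
    return out


def assign_risk_level(ind, thr: Optional[Thresholds] = None):
    """Low / medium / high risk from the count of exceeding body segments."""
    thr = thr or Thresholds()
    arr = _indicator_matrix(ind)
    n_exceed = (_relative_excess(arr, thr) > 0).sum(axis=1)
    levels = np.where(n_exceed == 0, RiskLevel.LOW,
                      np.where(n_exceed == 1, RiskLevel.MEDIUM, RiskLevel.HIGH))
    out = np.array([RiskLevel(int(v)) for v in levels], dtype=object)
    if isinstance(ind, AsymmetryIndicators) or np.asarray(ind, float).ndim == 1:
        return out[0]
    return out


def _majority(labels: np.ndarray, enum_cls) -> "enum.IntEnum":
    """Majority vote; ties resolve to the more severe (higher-valued) class."""
    values = np.array([int(v) for v in labels])
    counts = np.bincount(values, minlength=max(enum_cls) + 1)
    best = np.flatnonzero(counts == counts.max()).max()
    return enum_cls(int(best))


def classify_sequence(
    seq: KeypointSequence,
    thr: Optional[Thresholds] = None,
    window: int = 5,
    body_height: Optional[float] = None,
) -> tuple[AsymmetryLabel, np.ndarray]:
    """Per-sample label = majority vote of per-window labels.

    Returns the aggregate label and the per-window label array.  Windowed
    indicators are the window means (the first six kinematic features).
    """
    feats = kinematic_features(seq, window=window, body_height=body_height)
    per_window = classify_asymmetry(feats[:, :6], thr)
    return _majority(per_window, AsymmetryLabel), per_window


def risk_level_sequence(
    seq: KeypointSequence,
    thr: Optional[Thresholds] = None,
    window: int = 5,
    body_height: Optional[float] = None,
) -> tuple[RiskLevel, np.ndarray]:
    """Per-sample risk level = majority vote of per-window levels."""
    feats = kinematic_features(seq, window=window, body_height=body_height)
    per_window = assign_risk_level(feats[:, :6], thr)
    return _majority(per_window, RiskLevel), per_window


# ---------------------------------------------------------------------------
# Missing-keypoint handling and simplified 2D -> 3D lifting
# ---------------------------------------------------------------------------

CONFIDENCE_FLOOR = 0.3
MAX_MISSING_FRACTION = 0.3

#: Segment length as a fraction of stature (adolescent-adjusted standard
#: anthropometry).  Used by the depth-lifting step.
ANTHROPOMETRIC_RATIOS: dict[str, float] = {
    "torso": 0.300,           # mid-hip to mid-shoulder
    "upper_arm": 0.172,       # shoulder to elbow
    "forearm": 0.157,         # elbow to wrist
    "thigh": 0.245,           # hip to knee
    "shank": 0.246,           # knee to ankle
}


def interpolate_low_confidence(
    seq: KeypointSequence, floor: float = CONFIDENCE_FLOOR
) -> KeypointSequence:
    """Linearly interpolate joints whose confidence falls below ``floor``.

    Raises if any joint is missing in more than 30 % of frames.
    """
    coords = seq.coords.copy()
    conf = seq.confidence.copy()
    t_idx = np.arange(seq.n_frames)
    for j in range(coords.shape[1]):
        bad = conf[:, j] < floor
        if not bad.any():
            continue
        if bad.mean() > MAX_MISSING_FRACTION:
            raise ValueError(
                f"joint {j} missing in {bad.mean():.0%} of frames "
                f"(limit {MAX_MISSING_FRACTION:.0%})"
            )
        good = ~bad
        for d in range(coords.shape[2]):
            coords[bad, j, d] = np.interp(t_idx[bad], t_idx[good], coords[good, j, d])
        conf[bad, j] = floor
    return KeypointSequence(
        coords=coords,
        confidence=conf,
        frame_rate=seq.frame_rate,
        coordinate_mode=seq.coordinate_mode,
        frame_size=seq.frame_size,
        thoracic=seq.thoracic,
    )


def lift_scale(seq2d: KeypointSequence, body_height: float) -> float:
    """Pixels-to-world scale used by :func:`lift_to_3d` (deterministic)."""
    span_px = estimate_body_height(seq2d)
    return body_height / span_px


_LIFT_SEGMENTS: tuple[tuple[str, str, str], ...] = (
    ("left_hip", "left_knee", "thigh"),
    ("right_hip", "right_knee", "thigh"),
    ("left_knee", "left_ankle", "shank"),
    ("right_knee", "right_ankle", "shank"),
    ("left_shoulder", "left_elbow", "upper_arm"),
    ("right_shoulder", "right_elbow", "upper_arm"),
    ("left_elbow", "left_wrist", "forearm"),
    ("right_elbow", "right_wrist", "forearm"),
)


def lift_to_3d(
    seq2d: KeypointSequence,
    body_height: float,
    ratios: Optional[Mapping[str, float]] = None,
    smooth: int = 3,
) -> KeypointSequence:
    """Deterministic anthropometric 2D -> 3D lifting.

    Depth is assigned segment by segment down the kinematic tree: each
    segment's out-of-plane depth increment is the Pythagorean complement of
    its image-plane length against the expected 3D length (anthropometric
    ratio x body height), oriented toward the camera.  The hips define the
    z = 0 reference plane, face joints ride on the shoulder plane, and the
    depth track is smoothed with a centered moving average.  The 2D image
    projection of the output reproduces the input exactly: ``x = X / s``,
    ``y = -Y / s`` with the scale from :func:`lift_scale`.
    """
    if seq2d.coordinate_mode != "image2d":
        raise ValueError("lift_to_3d expects an image2d sequence")
    if body_height <= 0:
        raise ValueError("body_height must be positive")
    ratios = dict(ANTHROPOMETRIC_RATIOS, **(ratios or {}))
    seq2d = interpolate_low_confidence(seq2d)
    s = lift_scale(seq2d, body_height)
    xy = seq2d.coords * s
    xy[:, :, 1] *= -1.0  # image y-down -> world y-up
    T, J = xy.shape[:2]
    z = np.zeros((T, J))

    def planar_len(a: str, b: str) -> np.ndarray:
        return np.linalg.norm(
            xy[:, KEYPOINT_INDEX[a]] - xy[:, KEYPOINT_INDEX[b]], axis=-1
        )

    def depth_step(expected: float, planar: np.ndarray) -> np.ndarray:
        return np.sqrt(np.maximum(expected**2 - planar**2, 0.0))

    # torso: shoulders share one depth increment from the mid-hip plane
    mid_hip = 0.5 * (xy[:, KEYPOINT_INDEX["left_hip"]] + xy[:, KEYPOINT_INDEX["right_hip"]])
    mid_sh = 0.5 * (
        xy[:, KEYPOINT_INDEX["left_shoulder"]] + xy[:, KEYPOINT_INDEX["right_shoulder"]]
    )
    torso_dz = depth_step(ratios["torso"] * body_height, np.linalg.norm(mid_sh - mid_hip, axis=-1))
    for name in ("left_shoulder", "right_shoulder"):
        z[:, KEYPOINT_INDEX[name]] = torso_dz
    for name in ("nose", "left_eye", "right_eye", "left_ear", "right_ear"):
        z[:, KEYPOINT_INDEX[name]] = torso_dz

    for parent, child, seg in _LIFT_SEGMENTS:
        dz = depth_step(ratios[seg] * body_height, planar_len(parent, child))
        z[:, KEYPOINT_INDEX[child]] = z[:, KEYPOINT_INDEX[parent]] + dz

    if smooth > 1 and T >= smooth:
        kernel = np.ones(smooth) / smooth
        pad = smooth // 2
        zp = np.pad(z, ((pad, pad), (0, 0)), mode="edge")
        z = np.apply_along_axis(lambda col: np.convolve(col, kernel, mode="valid"), 0, zp)

    coords3d = np.concatenate([xy, z[:, :, None]], axis=2)
    return KeypointSequence(
        coords=coords3d,
        confidence=seq2d.confidence.copy(),
        frame_rate=seq2d.frame_rate,
        coordinate_mode="world3d",
    )


def indicators_frame(
    seq: KeypointSequence,
    sample_id: str = "sample",
    thr: Optional[Thresholds] = None,
    window: int = 5,
    norms: Optional[AgeNorms] = None,
    age: Optional[int] = None,
    body_height: Optional[float] = None,
) -> pd.DataFrame:
    """Tidy per-window indicator table: sample, window, indicator, value, z_score."""
    feats = kinematic_features(seq, window=window, body_height=body_height)
    rows = []
    for w in range(feats.shape[0]):
        for k, name in enumerate(INDICATOR_NAMES):
            z = np.nan
            if norms is not None and age is not None:
                try:
                    z = age_normalize(feats[w, k], age, name, norms)
                except ValueError:
                    z = np.nan
            rows.append(
                {
                    "sample": sample_id,
                    "window": w,
                    "indicator": name,
                    "value": feats[w, k],
                    "z_score": z,
                }
            )
    return pd.DataFrame(rows)
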