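"""Keypoint sequence container and file I/O.

A :class:`KeypointSequence` holds T frames of the 17 canonical joints in
either ``image2d`` coordinates (pixels, origin top-left, y increasing
downward, so physical "height" is ``-y``) or ``world3d`` coordinates
(normalized body units, y-up, right-handed).  Two interchange formats are
supported and round-trip through the same container:

* COCO-keypoint-style JSON: one annotation per frame with a flat
  ``[x1, y1, v1, ..., x17, y17, v17]`` triplet list;
* a flat CSV dialect with columns ``frame, joint, x, y[, z], confidence``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .skeleton import COCO_KEYPOINTS, KEYPOINT_INDEX, mirror_joint_order

__all__ = [
    "KeypointSequence",
    "mirror_keypoints",
    "read_coco_json",
    "write_coco_json",
    "read_keypoint_csv",
    "write_keypoint_csv",
]

MIN_FRAMES = 5  # sliding-window size; shorter clips carry no dynamics


@dataclass
class KeypointSequence:
    """T frames x 17 joints of 2D or 3D coordinates with confidences.

    Attributes
    ----------
    coords : (T, 17, D) float array, D in {2, 3}
    confidence : (T, 17) float array in [0, 1]
    frame_rate : sampling rate in Hz
    coordinate_mode : "image2d" or "world3d"
    frame_size : optional (width, height) of the image, used for mirroring
    thoracic : optional (T, D) true mid-spine landmark (synthetic data only;
        COCO-17 has no spine joints, see the indicators module)
    """

    coords: np.ndarray
    confidence: Optional[np.ndarray] = None
    frame_rate: float = 60.0
    coordinate_mode: str = "world3d"
    frame_size: Optional[tuple[float, float]] = None
    thoracic: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1] != len(COCO_KEYPOINTS):
            raise ValueError(
                f"coords must be (T, 17, D); got {self.coords.shape} "
                f"(expected 17 joints per frame)"
            )
        if self.coords.shape[2] not in (2, 3):
            raise ValueError("coordinate dimension must be 2 or 3")
        if self.coords.shape[0] < MIN_FRAMES:
            raise ValueError(f"need at least {MIN_FRAMES} frames")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.confidence is None:
            self.confidence = np.ones(self.coords.shape[:2])
        self.confidence = np.asarray(self.confidence, dtype=float)
        if self.confidence.shape != self.coords.shape[:2]:
            raise ValueError("confidence must be (T, 17)")
        if np.any((self.confidence < 0) | (self.confidence > 1)):
            raise ValueError("confidence must lie in [0, 1]")
        if self.coordinate_mode not in ("image2d", "world3d"):
            raise ValueError(f"unknown coordinate_mode: {self.coordinate_mode!r}")
        if self.coordinate_mode == "image2d" and self.coords.shape[2] != 2:
            raise ValueError("image2d sequences must be 2-dimensional")
        if self.thoracic is not None:
            self.thoracic = np.asarray(self.thoracic, dtype=float)
            if self.thoracic.shape != (self.coords.shape[0], self.coords.shape[2]):
                raise ValueError("thoracic must be (T, D)")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_dims(self) -> int:
        return self.coords.shape[2]

    def joint(self, name: str) -> np.ndarray:
        """(T, D) trajectory of one named joint."""
        return self.coords[:, KEYPOINT_INDEX[name], :]

    def heights(self) -> np.ndarray:
        """(T, 17) physical height of each joint (up-positive)."""
        if self.coordinate_mode == "image2d":
            return -self.coords[:, :, 1]
        return self.coords[:, :, 1]

    def copy(self) -> "KeypointSequence":
        return replace(
            self,
            coords=self.coords.copy(),
            confidence=self.confidence.copy(),
            thoracic=None if self.thoracic is None else self.thoracic.copy(),
        )


def mirror_keypoints(seq: KeypointSequence) -> KeypointSequence:
    """Reflect a sequence about the vertical midline and swap left/right.

    For image sequences the midline is ``width / 2`` when the frame size is
    known, otherwise the mean horizontal coordinate of the clip (which makes
    the operation an involution either way).  World sequences reflect about
    the x = 0 plane.  Applying twice is the identity.
    """
    if seq.coordinate_mode == "image2d":
        if seq.frame_size is not None:
            mid = seq.frame_size[0] / 2.0
        else:
            mid = float(seq.coords[:, :, 0].mean())
    else:
        mid = 0.0
    perm = mirror_joint_order()
    coords = seq.coords.copy()
    coords[:, :, 0] = 2.0 * mid - coords[:, :, 0]
    coords = coords[:, perm, :]
    conf = seq.confidence[:, perm]
    thor = None
    if seq.thoracic is not None:
        thor = seq.thoracic.copy()
        thor[:, 0] = 2.0 * mid - thor[:, 0]
    return replace(seq, coords=coords, confidence=conf, thoracic=thor)


# ---------------------------------------------------------------------------
# COCO-style JSON
# ---------------------------------------------------------------------------

def write_coco_json(seq: KeypointSequence, path: str | Path) -> None:
    if seq.n_dims != 2:
        raise ValueError("COCO JSON stores 2D keypoints only")
    annotations = []
    for t in range(seq.n_frames):
        flat: list[float] = []
        for j in range(len(COCO_KEYPOINTS)):
            x, y = seq.coords[t, j]
            v = 2 if seq.confidence[t, j] > 0 else 0
            flat += [float(x), float(y), int(v)]
        annotations.append(
            {
                "image_id": t,
                "category_id": 1,
                "keypoints": flat,
                "num_keypoints": len(COCO_KEYPOINTS),
                "confidence": [float(c) for c in seq.confidence[t]],
            }
        )
    doc = {
        "schema": "strokesym/coco-keypoints-v1",
        "info": {"frame_rate": seq.frame_rate},
        "categories": [
            {"id": 1, "name": "person", "keypoints": list(COCO_KEYPOINTS)}
        ],
        "images": [
            {"id": t, "width": seq.frame_size[0], "height": seq.frame_size[1]}
            if seq.frame_size
            else {"id": t}
            for t in range(seq.n_frames)
        ],
        "annotations": annotations,
    }
    Path(path).write_text(json.dumps(doc))


def read_coco_json(path: str | Path) -> KeypointSequence:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: malformed JSON at line {exc.lineno}: {exc.msg}")
    anns = sorted(doc["annotations"], key=lambda a: a["image_id"])
    n_kp = len(COCO_KEYPOINTS)
    coords = np.empty((len(anns), n_kp, 2))
    conf = np.ones((len(anns), n_kp))
    for t, ann in enumerate(anns):
        flat = ann["keypoints"]
        if len(flat) != 3 * n_kp:
            raise ValueError(
                f"{path}: annotation {ann['image_id']} has {len(flat) // 3} "
                f"joints; expected {n_kp}"
            )
        arr = np.asarray(flat, float).reshape(n_kp, 3)
        coords[t] = arr[:, :2]
        if "confidence" in ann:
            conf[t] = ann["confidence"]
        else:
            conf[t] = (arr[:, 2] > 0).astype(float)
    frame_size = None
    images = doc.get("images") or []
    if images and "width" in images[0]:
        frame_size = (images[0]["width"], images[0]["height"])
    frame_rate = (doc.get("info") or {}).get("frame_rate", 60.0)
    return KeypointSequence(
        coords=coords,
        confidence=conf,
        frame_rate=frame_rate,
        coordinate_mode="image2d",
        frame_size=frame_size,
    )


# ---------------------------------------------------------------------------
# Flat CSV dialect: frame, joint, x, y[, z], confidence
# ---------------------------------------------------------------------------

def write_keypoint_csv(seq: KeypointSequence, path: str | Path) -> None:
    rows = []
    for t in range(seq.n_frames):
        for j, name in enumerate(COCO_KEYPOINTS):
            row = {"frame": t, "joint": name}
            row["x"] = seq.coords[t, j, 0]
            row["y"] = seq.coords[t, j, 1]
            if seq.n_dims == 3:
                row["z"] = seq.coords[t, j, 2]
            row["confidence"] = seq.confidence[t, j]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_keypoint_csv(path: str | Path, frame_rate: float = 60.0) -> KeypointSequence:
    df = pd.read_csv(path)
    required = {"frame", "joint", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    has_z = "z" in df.columns
    joints = set(df["joint"].unique())
    unknown = joints - set(COCO_KEYPOINTS)
    if unknown:
        raise ValueError(f"{path}: unknown joints {sorted(unknown)}")
    if joints != set(COCO_KEYPOINTS):
        raise ValueError(
            f"{path}: found {len(joints)} joints per frame; expected all "
            f"{len(COCO_KEYPOINTS)} canonical joints"
        )
    frames = sorted(df["frame"].unique())
    n_dim = 3 if has_z else 2
    coords = np.empty((len(frames), len(COCO_KEYPOINTS), n_dim))
    conf = np.ones((len(frames), len(COCO_KEYPOINTS)))
    frame_pos = {f: i for i, f in enumerate(frames)}
    jidx = df["joint"].map(KEYPOINT_INDEX).to_numpy()
    fidx = df["frame"].map(frame_pos).to_numpy()
    coords[fidx, jidx, 0] = df["x"].to_numpy()
    coords[fidx, jidx, 1] = df["y"].to_numpy()
    if has_z:
        coords[fidx, jidx, 2] = df["z"].to_numpy()
    if "confidence" in df.columns:
        conf[fidx, jidx] = df["confidence"].to_numpy()
    return KeypointSequence(
        coords=coords,
        confidence=conf,
        frame_rate=frame_rate,
        coordinate_mode="world3d" if has_z else "image2d",
    )
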