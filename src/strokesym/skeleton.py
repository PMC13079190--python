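"""Sport-weighted 17-keypoint skeleton graph.

The skeleton follows the COCO-17 keypoint convention (nose, eyes, ears,
shoulders, elbows, wrists, hips, knees, ankles).  Table-tennis strokes load
the body asymmetrically, so the graph up-weights the kinetic chain of the
racket-holding arm (shoulder–elbow, elbow–wrist, shoulder–hip attachment,
x1.5) and the diagonal force-transfer connections between the racket
shoulder and the opposite hip (x1.3).  All other edges keep the baseline
weight 1.0.  Self-connections are *not* stored on the graph; they are added
only when building the symmetrically normalized adjacency
``D^{-1/2} (W + I) D^{-1/2}`` consumed by the graph-convolution layers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "COCO_KEYPOINTS",
    "KEYPOINT_INDEX",
    "LEFT_RIGHT_PAIRS",
    "SkeletonGraph",
    "build_skeleton_graph",
    "normalized_adjacency",
    "mirror_joint_order",
]

#: Canonical joint order used by every module in the package.
COCO_KEYPOINTS: tuple[str, ...] = (
    "nose",
    "left_eye",
    "right_eye",
    "left_ear",
    "right_ear",
    "left_shoulder",
    "right_shoulder",
    "left_elbow",
    "right_elbow",
    "left_wrist",
    "right_wrist",
    "left_hip",
    "right_hip",
    "left_knee",
    "right_knee",
    "left_ankle",
    "right_ankle",
)

KEYPOINT_INDEX: dict[str, int] = {name: i for i, name in enumerate(COCO_KEYPOINTS)}

#: (left, right) joint-name pairs, used for horizontal mirroring.
LEFT_RIGHT_PAIRS: tuple[tuple[str, str], ...] = tuple(
    (n, n.replace("left_", "right_"))
    for n in COCO_KEYPOINTS
    if n.startswith("left_")
)

# Standard COCO limb/torso/face connectivity.
_BASE_EDGES: tuple[tuple[str, str], ...] = (
    ("nose", "left_eye"),
    ("nose", "right_eye"),
    ("left_eye", "left_ear"),
    ("right_eye", "right_ear"),
    ("left_ear", "left_shoulder"),
    ("right_ear", "right_shoulder"),
    ("left_shoulder", "right_shoulder"),
    ("left_shoulder", "left_elbow"),
    ("right_shoulder", "right_elbow"),
    ("left_elbow", "left_wrist"),
    ("right_elbow", "right_wrist"),
    ("left_shoulder", "left_hip"),
    ("right_shoulder", "right_hip"),
    ("left_hip", "right_hip"),
    ("left_hip", "left_knee"),
    ("right_hip", "right_knee"),
    ("left_knee", "left_ankle"),
    ("right_knee", "right_ankle"),
)


def _canon(edge: tuple[str, str]) -> tuple[str, str]:
    a, b = edge
    return (a, b) if KEYPOINT_INDEX[a] < KEYPOINT_INDEX[b] else (b, a)


@dataclass
class SkeletonGraph:
    """Undirected weighted skeleton graph over the 17 canonical joints."""

    nodes: tuple[str, ...] = COCO_KEYPOINTS
    edges: tuple[tuple[str, str], ...] = ()
    edge_weight: dict[tuple[str, str], float] = field(default_factory=dict)
    handedness: str = "right"

    def __post_init__(self) -> None:
        if tuple(self.nodes) != COCO_KEYPOINTS:
            raise ValueError("SkeletonGraph requires the canonical 17-joint order")
        if self.handedness not in ("left", "right"):
            raise ValueError(f"unknown handedness: {self.handedness!r}")
        canon = tuple(_canon(e) for e in self.edges)
        if len(set(canon)) != len(canon):
            raise ValueError("duplicate edges")
        if any(a == b for a, b in canon):
            raise ValueError("self-pairs are not allowed")
        self.edges = canon
        self.edge_weight = {_canon(e): float(w) for e, w in self.edge_weight.items()}
        unknown = set(self.edge_weight) - set(canon)
        if unknown:
            raise ValueError(f"weights for unknown edges: {sorted(unknown)}")
        if any(w <= 0 for w in self.edge_weight.values()):
            raise ValueError("edge weights must be positive")

    def weight(self, a: str, b: str) -> float:
        return self.edge_weight.get(_canon((a, b)), 1.0)

    def weight_multiset(self) -> tuple[float, ...]:
        return tuple(sorted(self.weight(*e) for e in self.edges))

    def adjacency(self) -> np.ndarray:
        """Weighted symmetric adjacency matrix (no self-connections)."""
        n = len(self.nodes)
        a = np.zeros((n, n))
        for u, v in self.edges:
            i, j = KEYPOINT_INDEX[u], KEYPOINT_INDEX[v]
            a[i, j] = a[j, i] = self.weight(u, v)
        return a

    # -- JSON round trip -------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "schema": "strokesym/skeleton-v1",
            "nodes": list(self.nodes),
            "handedness": self.handedness,
            "edges": [
                {"a": a, "b": b, "weight": self.weight(a, b)} for a, b in self.edges
            ],
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SkeletonGraph":
        doc = json.loads(text)
        edges = tuple((e["a"], e["b"]) for e in doc["edges"])
        weights = {(e["a"], e["b"]): e["weight"] for e in doc["edges"]}
        return cls(
            nodes=tuple(doc["nodes"]),
            edges=edges,
            edge_weight=weights,
            handedness=doc["handedness"],
        )

    def mirror(self) -> "SkeletonGraph":
        """Swap left/right joints and flip handedness."""
        swap: dict[str, str] = {}
        for l, r in LEFT_RIGHT_PAIRS:
            swap[l], swap[r] = r, l
        edges = tuple(_canon((swap.get(a, a), swap.get(b, b))) for a, b in self.edges)
        weights = {
            _canon((swap.get(a, a), swap.get(b, b))): self.weight(a, b)
            for a, b in self.edges
        }
        return SkeletonGraph(
            edges=edges,
            edge_weight=weights,
            handedness="left" if self.handedness == "right" else "right",
        )


def build_skeleton_graph(
    handedness: str = "right",
    *,
    arm_chain_weight: float = 1.5,
    cross_lateral_weight: float = 1.3,
    longitudinal_weight: float = 1.0,
) -> SkeletonGraph:
    """Build the sport-weighted COCO-17 skeleton for a given racket hand.

    Parameters
    ----------
    handedness
        Which arm holds the racket, ``"left"`` or ``"right"``.
    arm_chain_weight
        Multiplier on the racket-arm chain: shoulder–elbow, elbow–wrist and
        the shoulder–torso attachment (shoulder–hip) on the racket side.
    cross_lateral_weight
        Multiplier on the two diagonal shoulder↔opposite-hip edges, added
        explicitly to the COCO topology.
    longitudinal_weight
        Weight of the shoulder–torso–hip longitudinal edges on the
        non-racket side (kept at baseline 1.0 by default).
    """
    if handedness not in ("left", "right"):
        raise ValueError(f"unknown handedness: {handedness!r}")
    dom = handedness
    opp = "left" if dom == "right" else "right"

    cross = (
        (f"{dom}_shoulder", f"{opp}_hip"),
        (f"{dom}_hip", f"{opp}_shoulder"),
    )
    edges = tuple(_canon(e) for e in _BASE_EDGES + cross)

    weights: dict[tuple[str, str], float] = {}
    for e in (
        (f"{dom}_shoulder", f"{dom}_elbow"),
        (f"{dom}_elbow", f"{dom}_wrist"),
        (f"{dom}_shoulder", f"{dom}_hip"),
    ):
        weights[_canon(e)] = arm_chain_weight
    for e in cross:
        weights[_canon(e)] = cross_lateral_weight
    if longitudinal_weight != 1.0:
        weights[_canon((f"{opp}_shoulder", f"{opp}_hip"))] = longitudinal_weight

    return SkeletonGraph(edges=edges, edge_weight=weights, handedness=handedness)


def normalized_adjacency(graph: SkeletonGraph | np.ndarray) -> np.ndarray:
    """Symmetrically normalized adjacency with self-connections.

    Returns ``D^{-1/2} (W + I) D^{-1/2}`` where ``W`` is the weighted
    adjacency and ``D`` the row-sum degree matrix of ``W + I``.
    """
    w = graph.adjacency() if isinstance(graph, SkeletonGraph) else np.asarray(graph, float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(w, w.T):
        raise ValueError("adjacency must be symmetric")
    a_tilde = w + np.eye(w.shape[0])
    d = a_tilde.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(d)
    return d_inv_sqrt[:, None] * a_tilde * d_inv_sqrt[None, :]


def mirror_joint_order() -> np.ndarray:
    """Index permutation that swaps every left joint with its right twin."""
    perm = np.arange(len(COCO_KEYPOINTS))
    for l, r in LEFT_RIGHT_PAIRS:
        i, j = KEYPOINT_INDEX[l], KEYPOINT_INDEX[r]
        perm[i], perm[j] = j, i
    return perm
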