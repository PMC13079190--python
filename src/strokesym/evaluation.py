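"""Evaluation metrics: PCK@50, per-class classification reports, screening
statistics (sensitivity / specificity / PPV / NPV for high-risk detection).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import (
    confusion_matrix,
    precision_recall_fscore_support,
    roc_auc_score,
)

from .keypoints import KeypointSequence
from .skeleton import KEYPOINT_INDEX

__all__ = ["EvalReport", "pck_at_50", "classification_report", "binary_screen_stats"]


def pck_at_50(pred: KeypointSequence, truth: KeypointSequence) -> float:
    """Fraction of keypoints within half the torso diameter of ground truth.

    The torso diameter is the per-frame distance from the left shoulder to
    the right hip; a prediction exactly at the 0.5 x diameter boundary
    counts as correct (inclusive convention).
    """
    if pred.coords.shape != truth.coords.shape:
        raise ValueError("prediction and truth must share joints and frame count")
    torso = np.linalg.norm(
        truth.coords[:, KEYPOINT_INDEX["left_shoulder"]]
        - truth.coords[:, KEYPOINT_INDEX["right_hip"]],
        axis=-1,
    )
    if np.any(torso <= 1e-12):
        raise ValueError("degenerate geometry: zero torso diameter")
    dist = np.linalg.norm(pred.coords - truth.coords, axis=-1)  # (T, J)
    return float(np.mean(dist <= 0.5 * torso[:, None]))


@dataclass
class EvalReport:
    """Classification report for one task."""

    labels: tuple[str, ...]
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    macro_f1: float
    auc: np.ndarray                      # one-vs-rest per class (nan if undefined)
    macro_auc: float
    confusion: np.ndarray
    accuracy: float
    screen: Optional[dict] = None        # binary high-risk screening stats
    strata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def clean(x):
            arr = np.asarray(x, float)
            return [None if not np.isfinite(v) else float(v) for v in arr]

        out = {
            "labels": list(self.labels),
            "precision": clean(self.precision),
            "recall": clean(self.recall),
            "f1": clean(self.f1),
            "support": [int(s) for s in self.support],
            "macro_f1": float(self.macro_f1),
            "auc": clean(self.auc),
            "macro_auc": None if not np.isfinite(self.macro_auc) else float(self.macro_auc),
            "confusion": self.confusion.tolist(),
            "accuracy": float(self.accuracy),
        }
        if self.screen is not None:
            out["screen"] = self.screen
        if self.strata:
            out["strata"] = self.strata
        return out


def binary_screen_stats(
    y_true: Sequence[int], y_pred: Sequence[int], positive: int
) -> dict:
    """Sensitivity / specificity / PPV / NPV of detecting one class."""
    t = np.asarray(y_true) == positive
    p = np.asarray(y_pred) == positive
    tp = int(np.sum(t & p))
    fn = int(np.sum(t & ~p))
    fp = int(np.sum(~t & p))
    tn = int(np.sum(~t & ~p))

    def ratio(a: int, b: int) -> Optional[float]:
        return a / b if b else None

    return {
        "tp": tp, "fn": fn, "fp": fp, "tn": tn,
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
    }


def classification_report(
    y_true: Sequence[int],
    y_pred: Sequence[int],
    y_score: Optional[np.ndarray] = None,
    label_names: Optional[Sequence[str]] = None,
    screen_positive: Optional[int] = None,
    strata: Optional[pd.DataFrame] = None,
) -> EvalReport:
    """Deterministic per-class report with one-vs-rest AUC.

    A class absent from ``y_true`` gets an undefined (NaN) AUC and is
    excluded from the macro averages with a warning.  ``strata`` may carry
    columns (e.g. stroke_type, age_group) for stratified accuracy.
    """
    y_true = np.asarray(y_true, int)
    y_pred = np.asarray(y_pred, int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    n_classes = (
        y_score.shape[1]
        if y_score is not None
        else int(max(y_true.max(), y_pred.max())) + 1
    )
    classes = np.arange(n_classes)
    names = tuple(label_names) if label_names else tuple(str(c) for c in classes)

    prec, rec, f1, support = precision_recall_fscore_support(
        y_true, y_pred, labels=classes, zero_division=0
    )
    present = support > 0
    if not present.all():
        warnings.warn(
            f"classes absent from y_true excluded from macro averages: "
            f"{[names[i] for i in np.flatnonzero(~present)]}"
        )
    macro_f1 = float(f1[present].mean()) if present.any() else np.nan

    auc = np.full(n_classes, np.nan)
    if y_score is not None:
        y_score = np.asarray(y_score, float)
        if y_score.shape != (len(y_true), n_classes):
            raise ValueError("y_score must be (n_samples, n_classes)")
        if np.any(y_score < 0) or not np.allclose(y_score.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("y_score rows must be probability simplexes")
        for c in classes:
            pos = y_true == c
            if pos.any() and (~pos).any():
                auc[c] = roc_auc_score(pos, y_score[:, c])
    finite = np.isfinite(auc)
    macro_auc = float(auc[finite].mean()) if finite.any() else np.nan

    cm = confusion_matrix(y_true, y_pred, labels=classes)
    report = EvalReport(
        labels=names,
        precision=prec,
        recall=rec,
        f1=f1,
        support=support,
        macro_f1=macro_f1,
        auc=auc,
        macro_auc=macro_auc,
        confusion=cm,
        accuracy=float(np.mean(y_true == y_pred)),
    )
    if screen_positive is not None:
        report.screen = binary_screen_stats(y_true, y_pred, screen_positive)
    if strata is not None:
        for col in strata.columns:
            groups = {}
            for value, idx in strata.groupby(col).groups.items():
                idx = np.asarray(idx)
                groups[str(value)] = {
                    "n": int(len(idx)),
                    "accuracy": float(np.mean(y_true[idx] == y_pred[idx])),
                }
            report.strata[col] = groups
    return report


def age_group(age: int, fine: bool = False) -> str:
    """Default stratification bins: 12-14 vs 15-17, or single years."""
    if fine:
        return str(int(age))
    return "12-14" if age <= 14 else "15-17"
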