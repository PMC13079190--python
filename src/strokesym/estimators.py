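"""scikit-learn style estimators over the rule system and the network.

These wrap the package's functional modules in fit/predict/transform
interfaces so they compose with sklearn pipelines and model selection:

* :class:`KinematicFeatures` — transformer turning keypoint sequences into
  the sliding-window 12-d biomechanical descriptor.
* :class:`PostureRuleScreen` — deterministic threshold-rule classifier for
  asymmetry type and injury-risk level.
* :class:`MultimodalStrokeClassifier` — the trainable multimodal network.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .indicators import (
    AsymmetryLabel,
    RiskLevel,
    Thresholds,
    classify_sequence,
    kinematic_features,
    risk_level_sequence,
)
from .keypoints import KeypointSequence
from .nn.model import ModelConfig
from .synthetic import StrokeSample
from .training import TrainConfig, TrainState, predict_proba, train

__all__ = ["KinematicFeatures", "PostureRuleScreen", "MultimodalStrokeClassifier"]


def _as_sequence(x) -> KeypointSequence:
    if isinstance(x, StrokeSample):
        return x.keypoints
    if isinstance(x, KeypointSequence):
        return x
    raise TypeError(f"expected StrokeSample or KeypointSequence, got {type(x)!r}")


def _body_height(x) -> Optional[float]:
    return x.body_height if isinstance(x, StrokeSample) else None


class KinematicFeatures(TransformerMixin, BaseEstimator):
    """Sliding-window biomechanical descriptor as an sklearn transformer.

    ``transform`` maps a list of samples/sequences to an (n, T', 12) array
    (or (n, T' * 12) with ``flatten=True``) of the six asymmetry indicators
    and their temporal derivatives.
    """

    def __init__(self, window: int = 5, flatten: bool = False) -> None:
        self.window = window
        self.flatten = flatten

    def fit(self, X, y=None) -> "KinematicFeatures":
        self.n_features_in_ = len(X)
        return self

    def transform(self, X) -> np.ndarray:
        feats = np.stack(
            [
                kinematic_features(
                    _as_sequence(x), window=self.window, body_height=_body_height(x)
                )
                for x in X
            ]
        )
        if self.flatten:
            return feats.reshape(len(feats), -1)
        return feats


class PostureRuleScreen(ClassifierMixin, BaseEstimator):
    """Threshold-rule screen: asymmetry type and risk level per sample.

    ``predict`` returns the four-class asymmetry label; ``predict_risk``
    the three-level risk.  Both are majority votes of per-window rule
    outcomes (ties to the more severe class).  ``fit`` only validates the
    thresholds — the rules have no trainable state.
    """

    def __init__(
        self,
        shoulder_rot: float = 15.0,
        shoulder_height: float = 0.05,
        spine_flexion: float = 8.0,
        hip_flexion: float = 10.0,
        pelvic_tilt: float = 5.0,
        window: int = 5,
    ) -> None:
        self.shoulder_rot = shoulder_rot
        self.shoulder_height = shoulder_height
        self.spine_flexion = spine_flexion
        self.hip_flexion = hip_flexion
        self.pelvic_tilt = pelvic_tilt
        self.window = window

    def _thresholds(self) -> Thresholds:
        return Thresholds(
            shoulder_rot=self.shoulder_rot,
            shoulder_height=self.shoulder_height,
            spine_flexion=self.spine_flexion,
            hip_flexion=self.hip_flexion,
            pelvic_tilt=self.pelvic_tilt,
        )

    def fit(self, X=None, y=None) -> "PostureRuleScreen":
        self.thresholds_ = self._thresholds()
        self.classes_ = np.array([int(l) for l in AsymmetryLabel])
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "thresholds_")
        return np.array(
            [
                int(
                    classify_sequence(
                        _as_sequence(x), self.thresholds_,
                        window=self.window, body_height=_body_height(x),
                    )[0]
                )
                for x in X
            ]
        )

    def predict_risk(self, X) -> np.ndarray:
        check_is_fitted(self, "thresholds_")
        return np.array(
            [
                int(
                    risk_level_sequence(
                        _as_sequence(x), self.thresholds_,
                        window=self.window, body_height=_body_height(x),
                    )[0]
                )
                for x in X
            ]
        )


class MultimodalStrokeClassifier(ClassifierMixin, BaseEstimator):
    """The multimodal GCN + TCN + attention network as an sklearn estimator.

    ``fit`` consumes a list of labeled :class:`StrokeSample` objects (the
    labels travel with the samples; ``y`` is accepted for API compatibility
    and must match when given).  After fitting, ``predict`` /
    ``predict_proba`` address the asymmetry task and ``predict_risk`` /
    ``predict_risk_proba`` the injury-risk task.
    """

    def __init__(
        self,
        model_config: Optional[dict] = None,
        batch_size: int = 32,
        learning_rate: float = 1e-4,
        weight_decay: float = 1e-4,
        max_epochs: int = 100,
        patience: int = 10,
        augment: bool = True,
        tasks: tuple[str, ...] = ("asym", "risk"),
        seed: int = 0,
    ) -> None:
        self.model_config = model_config
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.max_epochs = max_epochs
        self.patience = patience
        self.augment = augment
        self.tasks = tasks
        self.seed = seed

    def fit(self, X: Sequence[StrokeSample], y=None) -> "MultimodalStrokeClassifier":
        if y is not None:
            given = np.asarray(y, int)
            stored = np.array([int(s.y_asym) for s in X])
            if not np.array_equal(given, stored):
                raise ValueError("y disagrees with the labels carried by the samples")
        mcfg = ModelConfig(**{"seed": self.seed, **(self.model_config or {})})
        tcfg = TrainConfig(
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            weight_decay=self.weight_decay,
            max_epochs=self.max_epochs,
            patience=self.patience,
            augment=self.augment,
            tasks=tuple(self.tasks),
            seed=self.seed,
        )
        self.state_: TrainState = train(X, mcfg, tcfg)
        self.history_ = self.state_.history
        self.classes_ = np.array([int(l) for l in AsymmetryLabel])
        self.risk_classes_ = np.array([int(l) for l in RiskLevel])
        self.n_parameters_ = self.state_.net.n_parameters()
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "state_")
        return predict_proba(self.state_, list(X))[0]

    def predict(self, X) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)

    def predict_risk_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "state_")
        return predict_proba(self.state_, list(X))[1]

    def predict_risk(self, X) -> np.ndarray:
        return np.argmax(self.predict_risk_proba(X), axis=1)

    def score(self, X, y=None) -> float:
        truth = (
            np.asarray(y, int)
            if y is not None
            else np.array([int(s.y_asym) for s in X])
        )
        return float(np.mean(self.predict(X) == truth))
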