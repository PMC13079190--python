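"""Multi-task loss stack: cross-entropy, class-balanced focal loss and
homoscedastic uncertainty weighting.

The asymmetry head trains with plain 4-class cross-entropy.  The risk head
trains with focal loss — cross-entropy modulated by ``(1 - p)^gamma`` and
per-class weights alpha = 3.0 / 1.5 / 1.0 for high / medium / low risk —
because high-risk strokes are outnumbered roughly 1:15 by low-risk ones.
The two task losses combine through learned task-noise parameters sigma_i
(stored as log sigma so positivity is structural):

    L_total = sum_i L_i / (2 sigma_i^2) + sum_i log(sigma_i) + lambda ||Theta||^2

with the effective task weight w_i = 1 / (2 sigma_i^2).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .nn.autodiff import Tensor, log_softmax

__all__ = [
    "cross_entropy",
    "cross_entropy_4class",
    "focal_loss_3class",
    "joint_loss",
    "task_weights",
    "cross_entropy_from_logits",
    "focal_loss_from_logits",
    "LOG_EPS",
]

LOG_EPS = 1e-12  # metric epsilon: log arguments clamped here

#: (high, medium, low) class-balance weights, as reported.
FOCAL_ALPHA_HML: tuple[float, float, float] = (3.0, 1.5, 1.0)
FOCAL_GAMMA: float = 2.0


def _check_simplex(probs: np.ndarray, n_classes: int) -> np.ndarray:
    probs = np.atleast_2d(np.asarray(probs, float))
    if probs.shape[1] != n_classes:
        raise ValueError(f"expected {n_classes} probability columns, got {probs.shape[1]}")
    if np.any(probs < 0) or np.any(probs > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    return probs


def cross_entropy(probs: np.ndarray, labels: Sequence[int], n_classes: int) -> float:
    """Mean negative log-likelihood of the true classes."""
    probs = _check_simplex(probs, n_classes)
    labels = np.asarray(labels, int)
    if labels.shape[0] != probs.shape[0]:
        raise ValueError("labels and probabilities disagree in length")
    p_true = np.clip(probs[np.arange(len(labels)), labels], LOG_EPS, 1.0)
    return float(-np.mean(np.log(p_true)))


def cross_entropy_4class(probs: np.ndarray, labels: Sequence[int]) -> float:
    """Four-class posture-asymmetry cross-entropy."""
    return cross_entropy(probs, labels, 4)


def focal_loss_3class(
    probs: np.ndarray,
    labels: Sequence[int],
    gamma: float = FOCAL_GAMMA,
    alpha: tuple[float, float, float] = FOCAL_ALPHA_HML,
) -> float:
    """Class-balanced focal loss for the 3-level risk task.

    ``alpha`` is given in (high, medium, low) order as reported; labels use
    the package's class ids (0 = low, 1 = medium, 2 = high).  With gamma = 0
    and alpha = (1, 1, 1) this reduces exactly to 3-class cross-entropy.
    """
    probs = _check_simplex(probs, 3)
    labels = np.asarray(labels, int)
    alpha_by_class = np.asarray(alpha, float)[::-1]  # -> (low, medium, high)
    p_true = np.clip(probs[np.arange(len(labels)), labels], LOG_EPS, 1.0)
    a = alpha_by_class[labels]
    return float(-np.mean(a * (1.0 - p_true) ** gamma * np.log(p_true)))


def task_weights(log_sigmas: np.ndarray) -> np.ndarray:
    """Effective task weights w_i = 1 / (2 sigma_i^2)."""
    sigmas = np.exp(np.asarray(log_sigmas, float))
    return 1.0 / (2.0 * sigmas**2)


def joint_loss(
    l_asym: float,
    l_injury: float,
    log_sigmas: Sequence[float],
    params: Optional[Sequence[np.ndarray]] = None,
    lam: float = 1e-4,
) -> float:
    """Uncertainty-weighted multi-task objective (scalar, numpy).

    ``sum_i L_i / (2 sigma_i^2) + sum_i log(sigma_i) + lam * ||Theta||_2^2``.
    The log-sigma regularizer keeps the noise parameters from diverging.
    """
    log_sigmas = np.asarray(log_sigmas, float)
    if log_sigmas.shape != (2,):
        raise ValueError("expected two task-noise parameters")
    w = task_weights(log_sigmas)
    total = w[0] * l_asym + w[1] * l_injury + float(log_sigmas.sum())
    if params is not None and lam > 0:
        total += lam * float(sum(np.sum(np.square(p)) for p in params))
    return float(total)


# ---------------------------------------------------------------------------
# Differentiable versions used by the training loop
# ---------------------------------------------------------------------------

def cross_entropy_from_logits(
    logits: Tensor,
    labels: np.ndarray,
    class_weights: Optional[np.ndarray] = None,
) -> Tensor:
    """Mean cross-entropy from raw logits (stable log-softmax path).

    ``class_weights`` (one per class, mean-one normalized here) implements
    the class-weighted variant used for the imbalanced asymmetry task.
    """
    labels = np.asarray(labels, int)
    onehot = np.zeros(logits.shape)
    onehot[np.arange(len(labels)), labels] = 1.0
    if class_weights is not None:
        w = np.asarray(class_weights, float)
        w = w / w.mean()
        onehot *= w[labels][:, None]
    logp = log_softmax(logits, axis=-1)
    return -(Tensor(onehot) * logp).sum() * (1.0 / len(labels))


def focal_loss_from_logits(
    logits: Tensor,
    labels: np.ndarray,
    gamma: float = FOCAL_GAMMA,
    alpha: tuple[float, float, float] = FOCAL_ALPHA_HML,
) -> Tensor:
    """Differentiable focal loss; alpha in (high, medium, low) order."""
    labels = np.asarray(labels, int)
    onehot = np.zeros(logits.shape)
    onehot[np.arange(len(labels)), labels] = 1.0
    alpha_by_class = np.asarray(alpha, float)[::-1]
    a_row = alpha_by_class[labels][:, None] * onehot
    logp = log_softmax(logits, axis=-1)
    p = logp.exp()
    if gamma == 0:
        modulated = Tensor(a_row) * logp
    else:
        modulated = Tensor(a_row) * (1.0 - p) ** gamma * logp
    return -modulated.sum() * (1.0 / len(labels))


def joint_loss_tensor(
    l_asym: Optional[Tensor],
    l_injury: Optional[Tensor],
    log_sigmas: Tensor,
) -> Tensor:
    """Differentiable uncertainty-weighted sum (L2 handled by AdamW decay)."""
    terms: list[Tensor] = []
    for i, loss in enumerate((l_asym, l_injury)):
        if loss is None:
            continue
        ls = log_sigmas[i:i + 1]
        w = ((ls * 2.0).exp() * 2.0) ** -1.0   # 1 / (2 sigma^2)
        terms.append((loss * w + ls).sum())
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total
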