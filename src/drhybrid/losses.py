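"""Cross-entropy and enhance cross-entropy (E-CE) losses for 5-grade outputs.

The cross-entropy here is the per-component *binary* cross-entropy averaged
over the grade components (not the usual categorical cross-entropy): for a
one-hot label ``y`` and a softmax output ``yhat``,

    CE(y, yhat) = -(1/N) * sum_n [ y_n*ln(yhat_n) + (1-y_n)*ln(1-yhat_n) ]

with ``N`` the number of grades.  The E-CE loss adds a normalized ordinal
penalty ``|G_true - G_pred| / (N-1)``, where ``G_pred`` is either the argmax
grade ("hard" mode; piecewise constant, contributes no gradient) or the
probability-weighted expected grade ("soft" mode; a differentiable surrogate
that is an extension of the published formulation).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LossConfig",
    "LabelVector",
    "validate_probability_vector",
    "predicted_grade",
    "ce_loss",
    "grade_penalty",
    "ece_loss",
    "batch_loss_and_grad",
]

N_GRADES = 5


@dataclass(frozen=True)
class LossConfig:
    n_grades: int = N_GRADES
    epsilon: float = 1e-7
    penalty_mode: str = "hard"  # hard | soft | off
    reduction: str = "mean"

    def __post_init__(self):
        if self.n_grades < 2:
            raise ValueError("n_grades must be >= 2")
        if not 0.0 < self.epsilon < 0.5:
            raise ValueError("epsilon must lie in (0, 0.5)")
        if self.penalty_mode not in ("hard", "soft", "off"):
            raise ValueError(f"unknown penalty_mode {self.penalty_mode!r}")


@dataclass(frozen=True)
class LabelVector:
    """One-hot indicator of the true grade."""

    grade: int
    n_grades: int = N_GRADES

    def __post_init__(self):
        if not 0 <= self.grade < self.n_grades:
            raise ValueError(f"grade {self.grade} outside [0, {self.n_grades})")

    @property
    def values(self) -> np.ndarray:
        v = np.zeros(self.n_grades)
        v[self.grade] = 1.0
        return v


def validate_probability_vector(yhat: np.ndarray, n_grades: int = N_GRADES,
                                atol: float = 1e-6) -> np.ndarray:
    """Check shape, range and normalization; returns the input as float array."""
    yhat = np.asarray(yhat, dtype=float)
    if yhat.shape != (n_grades,):
        raise ValueError(f"expected shape ({n_grades},), got {yhat.shape}")
    if np.any(yhat < -atol) or np.any(yhat > 1 + atol):
        raise ValueError("probabilities outside [0, 1]")
    if abs(yhat.sum() - 1.0) > atol:
        raise ValueError(f"probabilities sum to {yhat.sum()}, not 1")
    return yhat


def predicted_grade(yhat: np.ndarray) -> int:
    """Argmax grade; ties broken toward the lowest grade index."""
    yhat = np.asarray(yhat, dtype=float)
    return int(np.argmax(yhat))


def ce_loss(y: LabelVector, yhat: np.ndarray, cfg: LossConfig | None = None) -> float:
    cfg = cfg or LossConfig()
    yhat = validate_probability_vector(yhat, cfg.n_grades)
    yv = np.zeros(cfg.n_grades)
    yv[y.grade] = 1.0
    p = np.clip(yhat, cfg.epsilon, 1.0 - cfg.epsilon)
    return float(-np.mean(yv * np.log(p) + (1.0 - yv) * np.log(1.0 - p)))


def grade_penalty(y: LabelVector, yhat: np.ndarray, cfg: LossConfig | None = None) -> float:
    """Normalized ordinal distance between true and predicted grade, in [0, 1]."""
    cfg = cfg or LossConfig()
    if cfg.penalty_mode == "off":
        return 0.0
    yhat = validate_probability_vector(yhat, cfg.n_grades)
    if cfg.penalty_mode == "hard":
        g_pred: float = predicted_grade(yhat)
    else:  # soft: expected grade under yhat
        g_pred = float(np.dot(np.arange(cfg.n_grades), yhat))
    return abs(y.grade - g_pred) / (cfg.n_grades - 1)


def ece_loss(y: LabelVector, yhat: np.ndarray, cfg: LossConfig | None = None) -> float:
    cfg = cfg or LossConfig()
    if cfg.penalty_mode == "off":
        raise ValueError("ece_loss requires penalty_mode 'hard' or 'soft'")
    return ce_loss(y, yhat, cfg) + grade_penalty(y, yhat, cfg)


def batch_loss_and_grad(grades: np.ndarray, probs: np.ndarray, loss_name: str = "ce",
                        cfg: LossConfig | None = None) -> tuple[float, float, np.ndarray]:
    """Mean batch loss and its gradient w.r.t. the probability matrix.

    Parameters
    ----------
    grades : (B,) integer true grades
    probs : (B, n_grades) softmax outputs
    loss_name : "ce" or "ece"

    Returns
    -------
    (loss, ce_component, dloss_dprobs) — for CE the two loss values coincide.
    In "hard" penalty mode the penalty term carries no gradient.
    """
    cfg = cfg or LossConfig()
    grades = np.asarray(grades)
    probs = np.asarray(probs, dtype=float)
    b, n = probs.shape
    if n != cfg.n_grades:
        raise ValueError(f"expected {cfg.n_grades} grade columns, got {n}")
    onehot = np.zeros_like(probs)
    onehot[np.arange(b), grades] = 1.0

    p = np.clip(probs, cfg.epsilon, 1.0 - cfg.epsilon)
    ce = float(-np.mean(onehot * np.log(p) + (1.0 - onehot) * np.log(1.0 - p)))
    grad = -(onehot / p - (1.0 - onehot) / (1.0 - p)) / (n * b)
    # clipped components are flat in the true probability
    grad[(probs < cfg.epsilon) | (probs > 1.0 - cfg.epsilon)] = 0.0

    if loss_name == "ce":
        return ce, ce, grad
    if loss_name != "ece":
        raise ValueError(f"unknown loss {loss_name!r}")

    if cfg.penalty_mode == "soft":
        idx = np.arange(n, dtype=float)
        expected = probs @ idx
        diff = expected - grades
        penalty = float(np.mean(np.abs(diff)) / (n - 1))
        grad = grad + (np.sign(diff)[:, None] * idx[None, :]) / ((n - 1) * b)
    else:  # hard: argmax distance, detached from gradients
        pred = probs.argmax(axis=1)
        penalty = float(np.mean(np.abs(pred - grades)) / (n - 1))
    return ce + penalty, ce, grad
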