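"""Focal loss and its cross-entropy baseline.

Focal loss, FL(p_t) = -alpha_t * (1 - p_t)^gamma * log(p_t), is cross entropy
with the contribution of well-classified samples (p_t near 1) damped by the
modulating factor (1 - p_t)^gamma.  alpha_t reweights classes against the
positive/negative imbalance; gamma shifts effort toward hard examples.  With
gamma = 0 and alpha_t = 1 it reduces exactly to cross entropy.

Both losses are exposed two ways: on true-class probabilities (the form used
in analysis and tests), and on logits with an analytic gradient (the form the
training loop consumes).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

P_CLAMP = 1e-12


@dataclass(frozen=True)
class FocalLossParams:
    """alpha: per-class weight(s) in [0, 1]; gamma: focusing exponent >= 0."""

    alpha: float | np.ndarray = 1.0
    gamma: float = 2.0

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")
        a = np.asarray(self.alpha, dtype=np.float64)
        if np.any(a < 0) or np.any(a > 1):
            raise ValueError("alpha entries must lie in [0, 1]")


def _clamp_probs(p_true: np.ndarray | float) -> np.ndarray:
    p = np.asarray(p_true, dtype=np.float64)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("true-class probabilities must lie in [0, 1]")
    return np.maximum(p, P_CLAMP)


def focal_loss(
    p_true: np.ndarray | float, gamma: float = 2.0, alpha: np.ndarray | float = 1.0
) -> float:
    """Mean focal loss over a batch of true-class probabilities."""
    if gamma < 0:
        raise ValueError(f"gamma must be >= 0, got {gamma}")
    p = _clamp_probs(p_true)
    return float(np.mean(-np.asarray(alpha, dtype=np.float64) * (1.0 - p) ** gamma * np.log(p)))


def cross_entropy(p_true: np.ndarray | float, weight: np.ndarray | float = 1.0) -> float:
    """Mean (weighted) cross entropy: -weight * log(p_true)."""
    p = _clamp_probs(p_true)
    return float(np.mean(-np.asarray(weight, dtype=np.float64) * np.log(p)))


def alpha_from_counts(class_counts: np.ndarray) -> np.ndarray:
    """Per-class alpha inversely proportional to frequency, max-normalized to 1."""
    counts = np.asarray(class_counts, dtype=np.float64)
    if np.any(counts <= 0):
        raise ValueError("every class needs at least one training sample")
    inv = 1.0 / counts
    return inv / inv.max()


# ---------------------------------------------------------------------------
# logit-space forms for the training loop

LossFn = Callable[[np.ndarray, np.ndarray], tuple[float, np.ndarray]]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def make_focal_loss(gamma: float = 2.0, alpha: np.ndarray | float = 1.0) -> LossFn:
    """Return (loss, dloss/dlogits) on (logits (N,C), integer targets (N,)).

    dFL/dp_t = alpha * [ gamma (1-p_t)^(gamma-1) log p_t - (1-p_t)^gamma / p_t ]
    chained through dp_t/dz_j = p_t (1[j==t] - p_j).
    """
    alpha_arr = np.asarray(alpha, dtype=np.float64)

    def fn(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
        n = logits.shape[0]
        probs = softmax(logits)
        p_t = np.maximum(probs[np.arange(n), targets], P_CLAMP)
        a_t = alpha_arr[targets] if alpha_arr.ndim else np.full(n, float(alpha_arr))
        one_m = 1.0 - p_t
        loss = float(np.mean(-a_t * one_m**gamma * np.log(p_t)))
        if gamma == 0.0:
            dl_dpt = -a_t / p_t
        else:
            # (1-p_t)^(gamma-1) is safe for gamma >= 1; clamp 1-p_t for gamma < 1
            base = np.maximum(one_m, P_CLAMP)
            dl_dpt = a_t * (gamma * base ** (gamma - 1.0) * np.log(p_t) - base**gamma / p_t)
        onehot = np.zeros_like(probs)
        onehot[np.arange(n), targets] = 1.0
        dpt_dz = p_t[:, None] * (onehot - probs)
        grad = dl_dpt[:, None] * dpt_dz / n
        return loss, grad

    return fn


def make_cross_entropy(weight: np.ndarray | float = 1.0) -> LossFn:
    """Weighted softmax cross entropy with its standard gradient."""
    w_arr = np.asarray(weight, dtype=np.float64)

    def fn(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
        n = logits.shape[0]
        probs = softmax(logits)
        p_t = np.maximum(probs[np.arange(n), targets], P_CLAMP)
        w_t = w_arr[targets] if w_arr.ndim else np.full(n, float(w_arr))
        loss = float(np.mean(-w_t * np.log(p_t)))
        onehot = np.zeros_like(probs)
        onehot[np.arange(n), targets] = 1.0
        grad = w_t[:, None] * (probs - onehot) / n
        return loss, grad

    return fn


def get_loss(name: str, gamma: float = 2.0, alpha: np.ndarray | float = 1.0) -> LossFn:
    """Config-level switch: ``focal`` or ``cross_entropy``."""
    if name == "focal":
        return make_focal_loss(gamma=gamma, alpha=alpha)
    if name == "cross_entropy":
        return make_cross_entropy(weight=alpha)
    raise ValueError(f"unknown loss {name!r} (expected 'focal' or 'cross_entropy')")
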