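"""Polynomially-perturbed cross-entropy (PolyLoss family).

Cross-entropy admits the Taylor decomposition

    -log(P_t) = Σ_{j≥1} (1/j) (1 - P_t)^j

where P_t is the softmax probability of the target class.  The PolyLoss
family perturbs the leading coefficients, 1/j → 1/j + ε_j, giving

    L_poly = -log(P_t) + Σ_{j=1..N} ε_j (1 - P_t)^j,     ε_j ≥ -1/j.

Tuning only the first term (Poly-1) already captures most of the gain:

    L_poly1 = -log(P_t) + ε₁ (1 - P_t),

with ε₁ = 2 by default.  Scalar forms operate on P_t directly; the batch
forms (:func:`cross_entropy`, :func:`poly1_loss`) take logits, support
per-class weights, and are differentiable for training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Tensor

__all__ = [
    "PolyConfig", "normalize_class_weights",
    "taylor_ce", "poly_loss",
    "cross_entropy", "poly1_loss",
]


@dataclass(frozen=True)
class PolyConfig:
    """Perturbation coefficients ε_j for j = 1..N (N = len(epsilons))."""

    epsilons: tuple[float, ...] = (2.0,)

    def __post_init__(self):
        if len(self.epsilons) < 1:
            raise ValueError("PolyConfig needs at least one coefficient")
        for j, eps in enumerate(self.epsilons, start=1):
            if eps < -1.0 / j:
                raise ValueError(
                    f"epsilon_{j} = {eps} violates the lower bound -1/{j} "
                    f"(the perturbed coefficient 1/j + eps_j would be negative)")

    @property
    def order(self) -> int:
        return len(self.epsilons)


def normalize_class_weights(weights: np.ndarray) -> np.ndarray:
    """Validate per-class weights and normalize them to mean 1."""
    w = np.asarray(weights, dtype=np.float64)
    if np.any(w < 0) or not np.any(w > 0):
        raise ValueError("class weights must be non-negative with at least "
                         "one strictly positive entry")
    return w / w.mean()


# ---------------------------------------------------------------------------
# scalar forms on P_t
# ---------------------------------------------------------------------------

def taylor_ce(p_t: float, n: int) -> float:
    """Partial Taylor sum Σ_{j=1..N} (1/j)(1−P_t)^j.

    Increases monotonically in N toward −log(P_t).  P_t must be in (0, 1];
    at P_t = 0 the series diverges.
    """
    if not 0.0 < p_t <= 1.0:
        raise ValueError(f"P_t must be in (0, 1], got {p_t}")
    if n < 1:
        raise ValueError("truncation order must be >= 1")
    q = 1.0 - p_t
    j = np.arange(1, n + 1)
    return float(np.sum(q ** j / j))


def poly_loss(p_t: float, cfg: PolyConfig) -> float:
    """General perturbed loss: −log(P_t) + Σ_j ε_j (1−P_t)^j."""
    if not 0.0 < p_t <= 1.0:
        raise ValueError(f"P_t must be in (0, 1], got {p_t}")
    q = 1.0 - p_t
    j = np.arange(1, cfg.order + 1)
    return float(-np.log(p_t) + np.sum(np.asarray(cfg.epsilons) * q ** j))


# ---------------------------------------------------------------------------
# batch (logit) forms, differentiable
# ---------------------------------------------------------------------------

def _weighted_mean(per_sample: Tensor, targets: np.ndarray,
                   weights: np.ndarray | None) -> Tensor:
    if weights is None:
        return per_sample.mean()
    w = normalize_class_weights(weights)[targets].astype(np.float32)
    return (per_sample * Tensor(w)).sum() * float(1.0 / w.sum())


def _log_pt(logits: Tensor, targets: np.ndarray) -> Tensor:
    targets = np.asarray(targets)
    logp = logits.log_softmax(axis=-1)
    return logp[np.arange(targets.shape[0]), targets]


def cross_entropy(logits: Tensor | np.ndarray, targets: np.ndarray,
                  weights: np.ndarray | None = None) -> Tensor:
    """−log P_t averaged over the batch (weighted mean when per-class
    weights are given), computed via log-softmax for stability."""
    logits = logits if isinstance(logits, Tensor) else Tensor(np.asarray(logits))
    return _weighted_mean(-_log_pt(logits, targets), np.asarray(targets), weights)


def poly1_loss(logits: Tensor | np.ndarray, targets: np.ndarray,
               epsilon1: float = 2.0,
               weights: np.ndarray | None = None) -> Tensor:
    """Poly-1: −log P_t + ε₁(1 − P_t), batch-(weighted-)mean reduced."""
    if epsilon1 < -1.0:
        raise ValueError(f"epsilon1 = {epsilon1} violates the lower bound -1")
    logits = logits if isinstance(logits, Tensor) else Tensor(np.asarray(logits))
    targets = np.asarray(targets)
    log_pt = _log_pt(logits, targets)
    per_sample = -log_pt + float(epsilon1) * (1.0 - log_pt.exp())
    return _weighted_mean(per_sample, targets, weights)
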