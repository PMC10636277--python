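"""Multi-class cross-entropy and focal loss.

Focal loss rescales the cross-entropy of each sample by ``(1 - p_true)**gamma``
so that samples the model already classifies confidently contribute little,
shifting the gradient budget towards hard, under-represented classes.  With
``gamma = 0`` the modulating factor is 1 and focal loss reduces exactly to
cross-entropy.  Natural logarithms are used throughout.

Two surfaces are provided:

* :func:`cross_entropy` / :func:`focal_loss` — analytic functions on
  probability vectors, used for evaluation and as oracles.
* :func:`focal_loss_from_logits` — the differentiable training objective on
  :class:`~tcrspec.autodiff.Tensor` logits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor

DEFAULT_GAMMA = 2.0  # focal-loss authors' recommendation for single runs
CLAMP_EPS = 1e-12


@dataclass
class LossConfig:
    """Settings for the focal objective.

    gamma >= 0 is the focusing parameter; epsilon clamps probabilities away
    from zero before the log; reduction picks sum or mean over a batch.
    """

    gamma: float = DEFAULT_GAMMA
    epsilon: float = CLAMP_EPS
    reduction: str = "mean"

    def __post_init__(self):
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.reduction not in ("sum", "mean"):
            raise ValueError("reduction must be 'sum' or 'mean'")


@dataclass
class LossDiagnostics:
    """Counts of numerically degenerate inputs encountered."""

    clamped: int = 0


def _validate(probs: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    probs = np.atleast_2d(np.asarray(probs, dtype=np.float64))
    target = np.atleast_2d(np.asarray(target, dtype=np.float64))
    if probs.shape != target.shape:
        raise ValueError(f"shape mismatch: probs {probs.shape} vs target {target.shape}")
    if not np.allclose(target.sum(axis=1), 1.0) or not np.all((target == 0) | (target == 1)):
        raise ValueError("target must be one-hot")
    return probs, target


def cross_entropy(
    probs: np.ndarray,
    target: np.ndarray,
    config: LossConfig | None = None,
    diagnostics: LossDiagnostics | None = None,
) -> float:
    """CE = -sum_i t_i * ln f(s_i), for one-hot targets -ln p_true."""
    config = config or LossConfig(gamma=0.0)
    probs, target = _validate(probs, target)
    p_true = (probs * target).sum(axis=1)
    n_clamped = int(np.sum(p_true < config.epsilon))
    if diagnostics is not None:
        diagnostics.clamped += n_clamped
    p_true = np.clip(p_true, config.epsilon, None)
    per_sample = -np.log(p_true)
    return float(per_sample.sum() if config.reduction == "sum" else per_sample.mean())


def focal_loss(
    probs: np.ndarray,
    target: np.ndarray,
    config: LossConfig | None = None,
    diagnostics: LossDiagnostics | None = None,
) -> float:
    """FL = -sum_i t_i * (1 - f(s_i))**gamma * ln f(s_i)."""
    config = config or LossConfig()
    probs, target = _validate(probs, target)
    p_true = (probs * target).sum(axis=1)
    n_clamped = int(np.sum(p_true < config.epsilon))
    if diagnostics is not None:
        diagnostics.clamped += n_clamped
    p_true = np.clip(p_true, config.epsilon, None)
    per_sample = (1.0 - p_true) ** config.gamma * (-np.log(p_true))
    return float(per_sample.sum() if config.reduction == "sum" else per_sample.mean())


def focal_loss_from_logits(logits: Tensor, label_ids: np.ndarray,
                           gamma: float = DEFAULT_GAMMA,
                           reduction: str = "mean") -> Tensor:
    """Differentiable focal loss on raw logits (batch, num_classes).

    The gradient flows through both the log-probability and the modulating
    factor.  ``gamma = 0`` gives plain cross-entropy.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    label_ids = np.asarray(label_ids, dtype=np.intp)
    n, c = logits.shape
    onehot = np.zeros((n, c))
    onehot[np.arange(n), label_ids] = 1.0
    ls = logits.log_softmax(axis=-1)
    ls_true = (ls * Tensor(onehot)).sum(axis=1)          # log p_true, (n,)
    p_true = ls_true.exp()
    if gamma == 0.0:
        per_sample = -ls_true
    else:
        per_sample = (1.0 - p_true) ** gamma * (-ls_true)
    return per_sample.sum() if reduction == "sum" else per_sample.mean()
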