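"""Agreement metrics and training losses.

The regression target is the PHQ-8 score and the headline metric is Lin's
concordance correlation coefficient (CCC),

    CCC = 2 * S_xy / (S_x^2 + S_y^2 + (x_bar - y_bar)^2),

with population (divide-by-n) moments.  Unlike Pearson's r, CCC penalizes
mean and variance bias, so it rewards predictions on the right scale, not
just the right ordering.  Training minimizes 1 - CCC for the regression
task plus a cross-entropy term for the auxiliary 5-class severity task:

    Loss = a * L_re + b * L_cl.

Both losses exist in two forms: plain NumPy for evaluation, and tape-based
(:mod:`maft.autodiff`) for gradient computation.  The loss-path CCC is
computed per training batch; the metric-path CCC once over the full
evaluation set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor

_EPS = 1e-12


class DegenerateInputError(ValueError):
    """CCC undefined: both vectors constant with equal means."""


@dataclass(frozen=True)
class LossWeights:
    """Multi-task mixing coefficients: ``a`` on regression, ``b`` on
    classification.  (1.0, 0.0) is single-task; (0.9, 0.1) the multi-task
    default."""

    a: float = 0.9
    b: float = 0.1

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0:
            raise ValueError("loss weights must be non-negative")
        if self.a == 0 and self.b == 0:
            raise ValueError("loss weights must not both be zero")


def ccc(y: np.ndarray, y_hat: np.ndarray, *, on_degenerate: str = "error") -> float:
    """Lin's concordance correlation coefficient, in [-1, 1].

    Uses population variance/covariance.  When both inputs are constant and
    equal the coefficient is 0/0-undefined; ``on_degenerate`` selects
    ``"error"`` (raise) or ``"one"`` (return 1.0, the agreement limit).
    """
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if y.shape != y_hat.shape or y.ndim != 1:
        raise ValueError("ccc expects two equal-length 1-d vectors")
    if y.size < 2:
        raise ValueError("ccc needs at least 2 observations")
    vy = y.var()
    vh = y_hat.var()
    mean_gap = y_hat.mean() - y.mean()
    denom = vh + vy + mean_gap**2
    if denom == 0.0:
        if on_degenerate == "one":
            return 1.0
        raise DegenerateInputError(
            "CCC undefined: both vectors constant with equal means"
        )
    cov = ((y - y.mean()) * (y_hat - y_hat.mean())).mean()
    return float(2.0 * cov / denom)


def ccc_loss(y: np.ndarray, y_hat: np.ndarray) -> float:
    """1 - CCC, in [0, 2]."""
    return 1.0 - ccc(y, y_hat)


def ccc_loss_t(pred: Tensor, target: np.ndarray, eps: float = 1e-8) -> Tensor:
    """Differentiable 1 - CCC of a predicted batch against fixed targets.

    ``eps`` stabilizes the denominator when the batch predictions collapse
    to a constant equal to the target mean.
    """
    target = np.asarray(target, dtype=np.float64)
    ty = Tensor(target)
    pm = pred.mean()
    ym = float(target.mean())
    pc = pred - pm
    yc = ty - ym
    cov = (pc * yc).mean()
    var_p = (pc * pc).mean()
    var_y = float(target.var())
    denom = var_p + var_y + (pm - ym) ** 2.0 + eps
    return 1.0 - (2.0 * cov) / denom


def cross_entropy(
    probs: np.ndarray,
    labels: np.ndarray,
    *,
    from_logits: bool = False,
    clip: float = 1e-12,
) -> float:
    """Mean negative log-likelihood of the true class.

    ``probs`` is n x C with rows summing to 1, or raw logits when
    ``from_logits`` is set (normalized internally via log-sum-exp).
    Probabilities are clipped at ``clip`` so a zero never produces a NaN.
    """
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels)
    n, n_classes = probs.shape
    if labels.shape != (n,):
        raise ValueError("labels must be a vector matching the probability rows")
    if labels.min() < 0 or labels.max() >= n_classes:
        raise ValueError(f"labels must lie in [0, {n_classes - 1}]")
    if from_logits:
        log_p = probs - _logsumexp(probs)
    else:
        log_p = np.log(np.clip(probs, clip, None))
    return float(-log_p[np.arange(n), labels].mean())


def _logsumexp(x: np.ndarray) -> np.ndarray:
    m = x.max(axis=1, keepdims=True)
    return m + np.log(np.exp(x - m).sum(axis=1, keepdims=True))


def cross_entropy_t(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Differentiable cross-entropy on logits (log-sum-exp normalized)."""
    labels = np.asarray(labels, dtype=int)
    n, n_classes = logits.shape
    onehot = np.zeros((n, n_classes))
    onehot[np.arange(n), labels] = 1.0
    lse = logits.logsumexp(axis=1)  # (n, 1)
    ll = (logits * onehot).sum(axis=1, keepdims=True)
    return (lse - ll).mean()


def multitask_loss(
    y: np.ndarray,
    y_hat: np.ndarray,
    probs: np.ndarray,
    labels: np.ndarray,
    weights: LossWeights,
    *,
    from_logits: bool = False,
) -> float:
    """a * (1 - CCC) + b * cross-entropy; either term skipped at weight 0."""
    total = 0.0
    if weights.a > 0:
        total += weights.a * ccc_loss(y, y_hat)
    if weights.b > 0:
        total += weights.b * cross_entropy(probs, labels, from_logits=from_logits)
    return total


def multitask_loss_t(
    pred: Tensor,
    target: np.ndarray,
    logits: Tensor,
    labels: np.ndarray,
    weights: LossWeights,
) -> Tensor:
    """Differentiable multi-task loss on a training batch."""
    terms = []
    if weights.a > 0:
        terms.append(weights.a * ccc_loss_t(pred, target))
    if weights.b > 0:
        terms.append(weights.b * cross_entropy_t(logits, labels))
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total


def rmse(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Root mean square error."""
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if y.shape != y_hat.shape:
        raise ValueError("rmse expects equal-length vectors")
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))
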