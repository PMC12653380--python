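"""Overlap metrics, the hybrid training loss, and run-aggregation statistics.

Binary masks are NumPy arrays with values in {0, 1}; probability maps are
arrays in [0, 1] (sigmoid of network logits).  With A the ground-truth and
B the predicted mask,

    IoU  = |A ∩ B| / |A ∪ B|
    Dice = 2 |A ∩ B| / (|A| + |B|)

so Dice = 2·IoU / (1 + IoU).  Both are defined as 1 when A and B are both
empty (perfect agreement on absence).  Dice weights true positives more
heavily, which matters here because the myocardial ring occupies only a few
percent of the image.

The training loss is the equal-weight sum of binary cross-entropy and a
smoothed soft-Dice loss, the standard combination for small-foreground
binary segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "iou",
    "dice",
    "binarize",
    "soft_dice_loss",
    "bce_loss",
    "hybrid_loss",
    "AggregateStats",
    "aggregate",
    "compare_runs",
]

_CLAMP = 1e-7  # probability clamp for the cross-entropy logarithms
DICE_SMOOTHING = 1.0


def _check_binary(a: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(a)
    if not np.isin(a, (0, 1)).all():
        raise ValueError(f"{name} must be strictly binary (values in {{0,1}})")
    return a


def _check_same_shape(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union of two binary masks; 1.0 if both are empty."""
    a = _check_binary(a, "a")
    b = _check_binary(b, "b")
    _check_same_shape(a, b)
    inter = float(np.logical_and(a, b).sum())
    union = float(np.logical_or(a, b).sum())
    if union == 0:
        return 1.0
    return inter / union


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice coefficient of two binary masks; 1.0 if both are empty."""
    a = _check_binary(a, "a")
    b = _check_binary(b, "b")
    _check_same_shape(a, b)
    sa, sb = float(a.sum()), float(b.sum())
    if sa + sb == 0:
        return 1.0
    inter = float(np.logical_and(a, b).sum())
    return 2.0 * inter / (sa + sb)


def binarize(p: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability map to a {0,1} mask (ties go to foreground)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    return (np.asarray(p) >= threshold).astype(np.uint8)


def soft_dice_loss(p: np.ndarray, t: np.ndarray,
                   smoothing: float = DICE_SMOOTHING) -> float:
    """Differentiable Dice loss ``1 − (2·Σpt + ε) / (Σp + Σt + ε)``.

    ``p`` is a probability map, ``t`` a binary target of the same shape.
    The smoothing term ε (default 1) keeps the loss defined on empty
    targets and bounds it in [0, 1).
    """
    p = np.asarray(p, dtype=np.float64)
    t = np.asarray(t, dtype=np.float64)
    _check_same_shape(p, t)
    num = 2.0 * float((p * t).sum()) + smoothing
    den = float(p.sum()) + float(t.sum()) + smoothing
    return 1.0 - num / den


def bce_loss(p: np.ndarray, t: np.ndarray) -> float:
    """Mean binary cross-entropy with probabilities clamped to [1e-7, 1−1e-7]."""
    p = np.clip(np.asarray(p, dtype=np.float64), _CLAMP, 1.0 - _CLAMP)
    t = np.asarray(t, dtype=np.float64)
    _check_same_shape(p, t)
    return float(-(t * np.log(p) + (1.0 - t) * np.log(1.0 - p)).mean())


def hybrid_loss(p: np.ndarray, t: np.ndarray) -> float:
    """Equal-weight sum of binary cross-entropy and soft-Dice loss."""
    return 0.5 * bce_loss(p, t) + 0.5 * soft_dice_loss(p, t)


@dataclass(frozen=True)
class AggregateStats:
    """Avg/min/max and sample (n−1) standard deviation over per-run means."""
    avg: float
    min: float
    max: float
    std_dev: float

    def __post_init__(self):
        assert self.min <= self.avg <= self.max and self.std_dev >= 0


def aggregate(per_run_means: list[float] | np.ndarray) -> AggregateStats:
    """Descriptive statistics over a collection of per-run mean metrics.

    Requires at least two values; the standard deviation uses the n−1
    (sample) denominator.
    """
    x = np.asarray(per_run_means, dtype=np.float64)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("aggregate requires at least 2 per-run values")
    return AggregateStats(avg=float(x.mean()), min=float(x.min()),
                          max=float(x.max()), std_dev=float(x.std(ddof=1)))


def compare_runs(a: list[float] | np.ndarray, b: list[float] | np.ndarray) -> float:
    """Two-sided Welch t-test p-value between two sets of per-run means.

    Used to ask whether two architectures differ significantly in mean Dice
    (or IoU) across their independent training runs.  Two identical
    zero-variance samples are defined as p = 1 (no evidence of difference).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("compare_runs requires >= 2 values per group")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)
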