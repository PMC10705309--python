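"""Training losses for the three segmentation approaches.

Multi-class segmentation (softmax head, mutually exclusive label channels)
uses categorical cross-entropy; binary segmentation (single sigmoid channel)
uses binary cross-entropy; multi-label segmentation averages the binary
cross-entropy of its three region channels.  All losses are means over
pixels, and probabilities are clipped to [eps, 1-eps] before the logs.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "EPS",
    "multiclass_cross_entropy",
    "binary_cross_entropy",
    "multilabel_loss",
]

EPS = 1e-7


def _as_prob_target(p, y):
    p = np.asarray(p, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError(f"prediction shape {p.shape} != target shape {y.shape}")
    return np.clip(p, EPS, 1.0 - EPS), y


def multiclass_cross_entropy(p: np.ndarray, y: np.ndarray, *, channel_axis: int = 0) -> float:
    """Categorical cross-entropy, mean over pixels.

    ``p`` and ``y`` are (..., C, ...) stacks with the class axis at
    ``channel_axis``; ``y`` must be one-hot.  Per pixel the loss is
    -sum_c y_c log p_c, and the total is the average over all pixels.
    """
    p, y = _as_prob_target(p, y)
    onehot = np.allclose(y.sum(axis=channel_axis), 1.0) and set(np.unique(y)) <= {0.0, 1.0}
    if not onehot:
        raise ValueError("multi-class target must be one-hot per pixel")
    per_pixel = -(y * np.log(p)).sum(axis=channel_axis)
    return float(per_pixel.mean())


def binary_cross_entropy(p: np.ndarray, y: np.ndarray) -> float:
    """Binary cross-entropy -[y log p + (1-y) log(1-p)], mean over pixels."""
    p, y = _as_prob_target(p, y)
    per_pixel = -(y * np.log(p) + (1.0 - y) * np.log1p(-p))
    return float(per_pixel.mean())


def multilabel_loss(p: np.ndarray, y: np.ndarray, *, channel_axis: int = 0) -> float:
    """Mean of the three per-region binary cross-entropies (et, tc, wt)."""
    p = np.asarray(p)
    y = np.asarray(y)
    if p.shape[channel_axis] != 3:
        raise ValueError(f"multi-label loss expects 3 region channels, got {p.shape[channel_axis]}")
    losses = [binary_cross_entropy(np.take(p, c, axis=channel_axis),
                                   np.take(y, c, axis=channel_axis))
              for c in range(3)]
    return float(np.mean(losses))
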