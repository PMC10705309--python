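"""Brute-force reference implementations used only by the test suite.

These recompute the evaluation metrics with explicit voxel loops and
pairwise distance enumeration — no distance transforms, no set algebra
shortcuts — so they stay independent of the library code paths they check.
"""

from __future__ import annotations

import math

import numpy as np


def brute_counts(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, int, int, int]:
    """(|T|, |P|, |T∩P|, |T^c∩P^c|) by explicit iteration."""
    nt = npred = inter = tn = 0
    for t, p in zip(np.asarray(y_true).ravel(), np.asarray(y_pred).ravel()):
        t, p = bool(t), bool(p)
        nt += t
        npred += p
        inter += t and p
        tn += (not t) and (not p)
    return nt, npred, inter, tn


def brute_dsc(y_true, y_pred) -> float:
    nt, npred, inter, _ = brute_counts(y_true, y_pred)
    if nt + npred == 0:
        return 1.0
    return 2.0 * inter / (nt + npred)


def brute_sensitivity(y_true, y_pred) -> float:
    nt, _, inter, _ = brute_counts(y_true, y_pred)
    return math.nan if nt == 0 else inter / nt


def brute_specificity(y_true, y_pred) -> float:
    t = np.asarray(y_true, dtype=bool)
    neg = t.size - int(t.sum())
    _, _, _, tn = brute_counts(y_true, y_pred)
    return math.nan if neg == 0 else tn / neg


def brute_hd95(y_true, y_pred, spacing=(1.0, 1.0, 1.0)) -> float:
    """Max of directed 95th percentiles over all pairwise voxel distances."""
    t = np.argwhere(np.asarray(y_true, dtype=bool)) * np.asarray(spacing)
    p = np.argwhere(np.asarray(y_pred, dtype=bool)) * np.asarray(spacing)
    if len(t) == 0 or len(p) == 0:
        return math.nan

    def directed(src, dst):
        dists = []
        for a in src:
            best = math.inf
            for b in dst:
                d = math.dist(a, b)
                if d < best:
                    best = d
            dists.append(best)
        return np.percentile(dists, 95)

    return float(max(directed(t, p), directed(p, t)))
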