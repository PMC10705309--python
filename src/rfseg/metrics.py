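"""Segmentation evaluation metrics: DSC, sensitivity, specificity, HD95.

All four operate on pairs of binary masks on a common voxel grid with a
physical spacing in mm.  Conventions:

* ``dsc`` returns 1.0 when both masks are empty (no tumor, none predicted
  — a perfect delineation of "nothing").
* ``sensitivity`` / ``specificity`` return NaN when their denominator
  (true positives resp. true negatives of the reference) is empty.
* ``hd95`` is the max of the two directed 95th-percentile surface
  distances between positive voxel sets, computed on voxel centers scaled
  by the spacing; NaN when either mask is empty.  A pooled variant (single
  95th percentile of the concatenated directed distances) is available via
  ``mode="pooled"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["MetricReport", "dsc", "sensitivity", "specificity", "hd95", "evaluate_pair"]


@dataclass
class MetricReport:
    dsc: float
    hd95: float
    sensitivity: float
    specificity: float

    def as_dict(self) -> dict[str, float]:
        return {"dsc": self.dsc, "hd95": self.hd95,
                "sensitivity": self.sensitivity, "specificity": self.specificity}


def _pair(y_true, y_pred):
    t = np.asarray(y_true, dtype=bool)
    p = np.asarray(y_pred, dtype=bool)
    if t.shape != p.shape:
        raise ValueError(f"mask grids differ: {t.shape} vs {p.shape}")
    return t, p


def dsc(y_true, y_pred) -> float:
    """Dice similarity coefficient 2|T∩P| / (|T|+|P|); 1.0 if both empty."""
    t, p = _pair(y_true, y_pred)
    denom = int(t.sum()) + int(p.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((t & p).sum()) / denom


def sensitivity(y_true, y_pred) -> float:
    """|T∩P| / |T| (true-positive rate); NaN if the truth is empty."""
    t, p = _pair(y_true, y_pred)
    nt = int(t.sum())
    if nt == 0:
        return math.nan
    return int((t & p).sum()) / nt


def specificity(y_true, y_pred) -> float:
    """|T^c∩P^c| / |T^c| (true-negative rate); NaN if the truth fills the grid."""
    t, p = _pair(y_true, y_pred)
    neg = int((~t).sum())
    if neg == 0:
        return math.nan
    return int((~t & ~p).sum()) / neg


def _directed_distances(src: np.ndarray, dst: np.ndarray, spacing) -> np.ndarray:
    """Euclidean distance from every positive voxel of src to the set dst."""
    # EDT of the complement gives, at each voxel, the distance to the
    # nearest dst-positive voxel (exact Euclidean, spacing-aware).
    dist_to_dst = ndimage.distance_transform_edt(~dst, sampling=spacing)
    return dist_to_dst[src]


def hd95(y_true, y_pred, spacing=(1.0, 1.0, 1.0), *, mode: str = "max") -> float:
    """95th-percentile Hausdorff distance in mm between positive voxel sets.

    ``mode="max"`` (default): max of the two directed 95th percentiles
    (linear-interpolated).  ``mode="pooled"``: 95th percentile of the
    pooled directed distances.  NaN when either mask is empty.
    """
    t, p = _pair(y_true, y_pred)
    if not t.any() or not p.any():
        return math.nan
    d_tp = _directed_distances(t, p, spacing)
    d_pt = _directed_distances(p, t, spacing)
    if mode == "max":
        return float(max(np.percentile(d_tp, 95), np.percentile(d_pt, 95)))
    if mode == "pooled":
        return float(np.percentile(np.concatenate([d_tp, d_pt]), 95))
    raise ValueError(f"unknown hd95 mode {mode!r}")


def evaluate_pair(y_true, y_pred, spacing=(1.0, 1.0, 1.0)) -> MetricReport:
    """All four metrics for one reference/prediction mask pair."""
    return MetricReport(
        dsc=dsc(y_true, y_pred),
        hd95=hd95(y_true, y_pred, spacing),
        sensitivity=sensitivity(y_true, y_pred),
        specificity=specificity(y_true, y_pred),
    )
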