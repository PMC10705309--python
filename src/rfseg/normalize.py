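"""Intensity standardization for skull-stripped MRI volumes.

MRI intensities are not on a physical scale: the same tissue lands at
different raw values depending on scanner model, coil and acquisition
settings.  Two standardizations are provided, both computed over the brain
mask (the nonzero foreground of skull-stripped data) and applied
per modality, per patient:

* **Z-score** — subtract the foreground mean, divide by the foreground
  standard deviation.
* **Nyul piecewise-linear histogram matching** — learn a standard scale
  from a training population by averaging affinely aligned percentile
  landmarks, then map each new volume's own landmarks onto that scale
  with linear interpolation between landmarks (and linear extrapolation
  beyond the outermost ones).

Background voxels are set to 0 on output in both cases.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "DEFAULT_RANKS",
    "DEFAULT_STANDARD_RANGE",
    "NyulState",
    "zscore_normalize",
    "nyul_train",
    "nyul_apply",
    "foreground_percentiles",
]

#: default percentile landmark ranks: decile interior plus robust 1/99 tails
DEFAULT_RANKS: tuple[float, ...] = (1, 10, 20, 30, 40, 50, 60, 70, 80, 90, 99)
DEFAULT_STANDARD_RANGE: tuple[float, float] = (0.0, 100.0)


class DegenerateInputError(ValueError):
    """Raised when a volume has no intensity spread over its mask."""


@dataclass
class NyulState:
    """Learned standard scale for Nyul histogram matching."""

    percentile_landmarks: tuple[float, ...]
    standard_scale_values: tuple[float, ...]
    standard_range: tuple[float, float]
    clip: bool = field(default=False)

    def __post_init__(self) -> None:
        ranks = np.asarray(self.percentile_landmarks, dtype=float)
        vals = np.asarray(self.standard_scale_values, dtype=float)
        if ranks.ndim != 1 or ranks.size < 2:
            raise ValueError("need at least two percentile landmarks")
        if vals.shape != ranks.shape:
            raise ValueError("landmark ranks and scale values differ in length")
        if not np.all(np.diff(ranks) > 0):
            raise ValueError("percentile ranks must be strictly increasing")
        if not np.all((ranks > 0) & (ranks < 100)):
            raise ValueError("percentile ranks must lie in (0, 100)")
        if not np.all(np.diff(vals) > 0):
            raise ValueError("standard scale values must be strictly increasing")
        lo, hi = self.standard_range
        if vals[0] < lo - 1e-9 or vals[-1] > hi + 1e-9:
            raise ValueError("standard scale values must lie within standard_range")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "percentile_landmarks": list(self.percentile_landmarks),
            "standard_scale_values": list(self.standard_scale_values),
            "standard_range": list(self.standard_range),
            "clip": self.clip,
        }, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "NyulState":
        d = json.loads(Path(path).read_text())
        return cls(percentile_landmarks=tuple(d["percentile_landmarks"]),
                   standard_scale_values=tuple(d["standard_scale_values"]),
                   standard_range=tuple(d["standard_range"]),
                   clip=bool(d.get("clip", False)))


def _foreground(volume: np.ndarray, mask: np.ndarray) -> np.ndarray:
    volume = np.asarray(volume, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if volume.shape != mask.shape:
        raise ValueError(f"volume grid {volume.shape} != mask grid {mask.shape}")
    fg = volume[mask]
    if fg.size < 2:
        raise ValueError("mask must cover at least two voxels")
    return fg


def zscore_normalize(volume: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Standardize to zero mean / unit SD over the mask; background -> 0."""
    fg = _foreground(volume, mask)
    mean = fg.mean()
    sd = fg.std()
    if sd == 0:
        raise DegenerateInputError("zero intensity variance over the mask")
    out = (np.asarray(volume, dtype=np.float64) - mean) / sd
    out[~np.asarray(mask, dtype=bool)] = 0.0
    return out


def foreground_percentiles(volume: np.ndarray, mask: np.ndarray,
                           ranks: Sequence[float]) -> np.ndarray:
    """Linear-interpolated percentiles of the masked intensities."""
    fg = _foreground(volume, mask)
    return np.percentile(fg, list(ranks))


def _strictly_increasing(values: np.ndarray, min_step: float,
                         upper: float | None = None) -> np.ndarray:
    """Tie-adjust an almost-sorted landmark vector to be strictly increasing.

    When ``upper`` is given the adjusted vector is additionally pulled back
    under that bound (ties near the top are resolved downward instead).
    """
    out = values.copy()
    for i in range(1, out.size):
        if out[i] <= out[i - 1]:
            out[i] = out[i - 1] + min_step
    if upper is not None and out[-1] > upper:
        out[-1] = upper
        for i in range(out.size - 2, -1, -1):
            if out[i] >= out[i + 1]:
                out[i] = out[i + 1] - min_step
    return out


def nyul_train(volumes: Sequence[np.ndarray], masks: Sequence[np.ndarray],
               ranks: Sequence[float] = DEFAULT_RANKS,
               standard_range: tuple[float, float] = DEFAULT_STANDARD_RANGE,
               *, clip: bool = False) -> NyulState:
    """Learn the Nyul standard scale from a training population.

    Each volume's foreground percentiles at ``ranks`` are affinely mapped so
    its outermost landmarks hit ``standard_range``; the standard scale is the
    per-rank mean of those mapped landmarks (tie-adjusted to stay strictly
    increasing).
    """
    if len(volumes) == 0:
        raise ValueError("need at least one training volume")
    if len(volumes) != len(masks):
        raise ValueError("volumes and masks differ in length")
    ranks_arr = np.asarray(ranks, dtype=float)
    if not (np.all(np.diff(ranks_arr) > 0) and np.all((ranks_arr > 0) & (ranks_arr < 100))):
        raise ValueError("ranks must be strictly increasing within (0, 100)")
    s_min, s_max = float(standard_range[0]), float(standard_range[1])
    if not s_max > s_min:
        raise ValueError("standard_range must satisfy s_min < s_max")

    mapped = []
    for vol, msk in zip(volumes, masks):
        lm = foreground_percentiles(vol, msk, ranks_arr)
        span = lm[-1] - lm[0]
        if span <= 0:
            raise DegenerateInputError("volume has no spread between outer landmarks")
        mapped.append(s_min + (lm - lm[0]) * (s_max - s_min) / span)
    scale = np.mean(mapped, axis=0)
    scale = _strictly_increasing(scale, min_step=(s_max - s_min) * 1e-9, upper=s_max)
    return NyulState(percentile_landmarks=tuple(ranks_arr.tolist()),
                     standard_scale_values=tuple(scale.tolist()),
                     standard_range=(s_min, s_max), clip=clip)


def nyul_apply(volume: np.ndarray, mask: np.ndarray, state: NyulState) -> np.ndarray:
    """Map a volume onto the learned standard scale; background -> 0.

    The volume's own foreground landmarks are sent exactly to the standard
    scale values, with linear interpolation between landmarks and linear
    extrapolation beyond the outermost ones (or clipping, if the state was
    trained with ``clip=True``).  The map is monotone non-decreasing.
    """
    lm = foreground_percentiles(volume, mask, state.percentile_landmarks)
    if lm[-1] - lm[0] <= 0:
        raise DegenerateInputError("volume has no spread between outer landmarks")
    lm = _strictly_increasing(lm, min_step=(lm[-1] - lm[0]) * 1e-12 + 1e-30)
    sv = np.asarray(state.standard_scale_values, dtype=np.float64)

    x = np.asarray(volume, dtype=np.float64)
    out = np.interp(x, lm, sv)
    if not state.clip:
        lo_slope = (sv[1] - sv[0]) / (lm[1] - lm[0])
        hi_slope = (sv[-1] - sv[-2]) / (lm[-1] - lm[-2])
        below = x < lm[0]
        above = x > lm[-1]
        out[below] = sv[0] + (x[below] - lm[0]) * lo_slope
        out[above] = sv[-1] + (x[above] - lm[-1]) * hi_slope
    out[~np.asarray(mask, dtype=bool)] = 0.0
    return out
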