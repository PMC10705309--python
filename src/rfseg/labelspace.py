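"""Conversions between BraTS label codes, overlapping tumor regions, and
the per-approach network target encodings.

BraTS ground truth is a single integer map over {0, 1, 2, 4}: background,
necrotic core (NCR), peritumoral edema (ED) and enhancing tumor (ET).
Evaluation, however, is done on three *overlapping* regions:

* ET — enhancing tumor, label 4;
* TC — tumor core, labels {1, 4};
* WT — whole tumor, labels {1, 2, 4}.

By construction ET ⊆ TC ⊆ WT.  The three segmentation approaches consume
different encodings of the same truth: ``multi_class`` uses mutually
exclusive one-hot label channels (softmax head), ``multi_label`` uses the
three region masks jointly (sigmoid head), and ``binary`` uses a single
region mask per model (sigmoid head).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "LABEL_CODES",
    "REGIONS",
    "APPROACHES",
    "LabelVolume",
    "RegionMaskSet",
    "TargetEncoding",
    "labels_to_regions",
    "regions_to_labels",
    "encode_target",
    "region_probability",
]

LABEL_CODES = (0, 1, 2, 4)
#: fixed region order used for multi_label channel stacks
REGIONS = ("et", "tc", "wt")
#: fixed approach order, also the tie-break order for candidate selection
APPROACHES = ("multi_class", "multi_label", "binary")

#: multi_class channel order: background, NCR(1), ED(2), ET(4)
MULTICLASS_CLASSES = (0, 1, 2, 4)

Approach = Literal["multi_class", "multi_label", "binary"]
Region = Literal["et", "tc", "wt"]


@dataclass
class LabelVolume:
    """Integer 3D label map over the BraTS codes {0, 1, 2, 4}."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        _check_codes(self.values)


@dataclass
class RegionMaskSet:
    """The three overlapping evaluation masks; invariant et ⊆ tc ⊆ wt."""

    et: np.ndarray
    tc: np.ndarray
    wt: np.ndarray

    def as_stack(self) -> np.ndarray:
        """Region-ordered (3, ...) boolean stack (et, tc, wt)."""
        return np.stack([self.et, self.tc, self.wt]).astype(bool)

    def __getitem__(self, region: str) -> np.ndarray:
        return getattr(self, region)


@dataclass
class TargetEncoding:
    """Channel stack fed to a network head for one approach."""

    approach: Approach
    channels: np.ndarray  # (C, ...) binary
    region: Region | None = None  # binary approach only


def _check_codes(values: np.ndarray) -> None:
    bad = np.setdiff1d(np.unique(values), LABEL_CODES)
    if bad.size:
        raise ValueError(f"unknown BraTS label codes: {bad.tolist()}")


def labels_to_regions(labels: LabelVolume | np.ndarray) -> RegionMaskSet:
    """Expand a BraTS label map into the overlapping ET/TC/WT masks."""
    v = labels.values if isinstance(labels, LabelVolume) else np.asarray(labels)
    _check_codes(v)
    et = v == 4
    tc = (v == 1) | et
    wt = (v == 2) | tc
    return RegionMaskSet(et=et, tc=tc, wt=wt)


def regions_to_labels(regions: RegionMaskSet,
                      spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
                      ) -> LabelVolume:
    """Collapse (possibly inconsistent) region masks back to label codes.

    The nesting hierarchy is repaired first by OR-ing downward (an ET voxel
    forces TC, a TC voxel forces WT) so every predicted tumor voxel is kept;
    then codes are assigned from the most specific region outward.
    """
    et = np.asarray(regions.et, dtype=bool)
    tc = np.asarray(regions.tc, dtype=bool) | et
    wt = np.asarray(regions.wt, dtype=bool) | tc
    out = np.zeros(et.shape, dtype=np.uint8)
    out[wt] = 2
    out[tc] = 1
    out[et] = 4
    return LabelVolume(values=out, spacing=spacing)


def encode_target(labels: LabelVolume | np.ndarray, approach: Approach,
                  region: Region | None = None) -> TargetEncoding:
    """Build the training target for one approach.

    multi_class -> 4 one-hot channels (background, NCR, ED, ET);
    multi_label -> the 3 region channels (et, tc, wt);
    binary      -> the single requested region channel.
    """
    v = labels.values if isinstance(labels, LabelVolume) else np.asarray(labels)
    if approach == "binary":
        if region is None:
            raise ValueError("binary approach requires a target region")
    elif region is not None:
        raise ValueError(f"region is only valid for the binary approach, got approach={approach!r}")

    if approach == "multi_class":
        _check_codes(v)
        channels = np.stack([v == c for c in MULTICLASS_CLASSES])
    elif approach == "multi_label":
        channels = labels_to_regions(v).as_stack()
    elif approach == "binary":
        channels = labels_to_regions(v)[region][None]
    else:
        raise ValueError(f"unknown approach {approach!r}")
    return TargetEncoding(approach=approach,
                          channels=channels.astype(np.float32),
                          region=region)


def region_probability(prediction: np.ndarray, approach: Approach,
                       region: Region, *, atol: float = 1e-3) -> np.ndarray:
    """Collapse a per-channel probability stack onto one region.

    This is what lets heterogeneous ensemble members (softmax multi-class
    heads next to sigmoid region heads) be averaged on a common region:
    for a multi_class stack the probability of a region is the *sum* of its
    constituent class probabilities (e.g. p(TC) = p(NCR) + p(ET)), while
    multi_label / binary stacks already carry the region channel.
    """
    p = np.asarray(prediction)
    if region not in REGIONS:
        raise ValueError(f"unknown region {region!r}")
    if approach == "binary":
        if p.shape[0] != 1:
            raise ValueError("binary prediction must have exactly one channel")
        return p[0]
    if approach == "multi_label":
        if p.shape[0] != 3:
            raise ValueError("multi_label prediction must have three channels")
        return p[REGIONS.index(region)]
    if approach == "multi_class":
        if p.shape[0] != 4:
            raise ValueError("multi_class prediction must have four channels")
        total = p.sum(axis=0)
        if not np.allclose(total, 1.0, atol=atol):
            raise ValueError("multi_class probabilities must sum to 1 per voxel")
        idx = {"et": [3], "tc": [1, 3], "wt": [1, 2, 3]}[region]
        return p[idx].sum(axis=0)
    raise ValueError(f"unknown approach {approach!r}")
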