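"""Patient-level splitting and assembly of 2D / 2.5D / 3D training samples.

Splitting is patient-level (no slice of one patient ever crosses splits):
70% training, 15% validation, 15% internal test, with round-half-up on the
train and validation counts and the remainder going to test.

2D samples stack the four modalities of one axial slice (C=4).  2.5D
samples add the previous and next slice of each modality in modality-major
order (t1[N-1], t1[N], t1[N+1], t1ce[...], ...; C=12), padding the missing
neighbor at the volume ends with an all-zero slice.  3D sampling extracts a
single patch centered on the brain-mask centroid, zero-padded symmetrically
where the volume is smaller than the patch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .labelspace import LabelVolume, TargetEncoding, encode_target
from .volume import MODALITIES, MultiModalVolume

__all__ = [
    "SplitAssignment",
    "SliceSample",
    "split_patients",
    "collect_2d",
    "collect_25d",
    "extract_3d_patch",
    "augment",
    "stack_slices_2d",
    "stack_slices_25d",
]

TRAIN_FRAC, VAL_FRAC = 0.70, 0.15


@dataclass
class SplitAssignment:
    train_ids: list[str]
    val_ids: list[str]
    test_ids: list[str]

    def __post_init__(self) -> None:
        all_ids = self.train_ids + self.val_ids + self.test_ids
        if len(set(all_ids)) != len(all_ids):
            raise ValueError("splits overlap or contain duplicate patient ids")


@dataclass
class SliceSample:
    image: np.ndarray  # (H, W, C) float32
    target: TargetEncoding  # channels (Ct, H, W)
    patient_id: str
    slice_index: int


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def split_patients(ids: Sequence[str], seed: int) -> SplitAssignment:
    """Shuffle and split patient ids 70/15/15; deterministic per seed."""
    ids = list(ids)
    if len(ids) < 3:
        raise ValueError("need at least 3 patients to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    shuffled = [ids[i] for i in order]
    n = len(ids)
    n_train = _round_half_up(TRAIN_FRAC * n)
    n_val = _round_half_up(VAL_FRAC * n)
    n_test = n - n_train - n_val
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(f"split of {n} patients leaves an empty subset "
                         f"({n_train}/{n_val}/{n_test})")
    return SplitAssignment(train_ids=shuffled[:n_train],
                           val_ids=shuffled[n_train:n_train + n_val],
                           test_ids=shuffled[n_train + n_val:])


def stack_slices_2d(volume: MultiModalVolume) -> np.ndarray:
    """(n_slices, H, W, 4) stack of axial slices, modalities last."""
    if volume.shape[2] == 0:
        raise ValueError("volume has no axial slices")
    return np.moveaxis(volume.data, (0, 3), (3, 0)).astype(np.float32)


def stack_slices_25d(volume: MultiModalVolume) -> np.ndarray:
    """(n_slices, H, W, 12) stacks: per modality the (N-1, N, N+1) triplet.

    Channel order is modality-major; the missing neighbor at the first and
    last slice is an all-zero slice.
    """
    d = volume.data.astype(np.float32)  # (4, H, W, S)
    zeros = np.zeros(d.shape[:3] + (1,), dtype=np.float32)
    prev = np.concatenate([zeros, d[..., :-1]], axis=3)
    nxt = np.concatenate([d[..., 1:], zeros], axis=3)
    # (4, 3, H, W, S): modality-major triplets
    trip = np.stack([prev, d, nxt], axis=1)
    trip = trip.reshape(len(MODALITIES) * 3, *d.shape[1:])
    return np.moveaxis(trip, (0, 3), (3, 0))


def _collect(volume: MultiModalVolume, labels: LabelVolume, approach, region,
             stacker) -> list[SliceSample]:
    if volume.shape != labels.values.shape:
        raise ValueError(f"modality grid {volume.shape} != label grid {labels.values.shape}")
    images = stacker(volume)
    target = encode_target(labels, approach, region)  # (Ct, X, Y, Z)
    return [SliceSample(image=images[k],
                        target=TargetEncoding(approach=approach,
                                              channels=target.channels[..., k],
                                              region=region),
                        patient_id="", slice_index=k)
            for k in range(images.shape[0])]


def collect_2d(volume: MultiModalVolume, labels: LabelVolume, approach,
               region=None, patient_id: str = "") -> list[SliceSample]:
    """One 4-channel sample per axial slice."""
    samples = _collect(volume, labels, approach, region, stack_slices_2d)
    for s in samples:
        s.patient_id = patient_id
    return samples


def collect_25d(volume: MultiModalVolume, labels: LabelVolume, approach,
                region=None, patient_id: str = "") -> list[SliceSample]:
    """One 12-channel (3 slices x 4 modalities) sample per axial slice."""
    samples = _collect(volume, labels, approach, region, stack_slices_25d)
    for s in samples:
        s.patient_id = patient_id
    return samples


def _center_crop_pad(arr: np.ndarray, center: np.ndarray, size: tuple[int, ...]) -> np.ndarray:
    """Crop ``size`` around ``center`` over the trailing ndim axes, zero-padding."""
    spatial = arr.shape[-len(size):]
    out = np.zeros(arr.shape[:-len(size)] + tuple(size), dtype=arr.dtype)
    src, dst = [], []
    for ax, (s, want, c) in enumerate(zip(spatial, size, center)):
        start = int(round(c)) - want // 2
        lo = max(start, 0)
        hi = min(start + want, s)
        if hi <= lo:
            return out
        src.append(slice(lo, hi))
        dst.append(slice(lo - start, hi - start))
    lead = (slice(None),) * (arr.ndim - len(size))
    out[lead + tuple(dst)] = arr[lead + tuple(src)]
    return out


def extract_3d_patch(volume: MultiModalVolume, labels: LabelVolume,
                     patch_size: tuple[int, int, int],
                     center: Sequence[float] | None = None,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Single 3D patch centered on the brain-mask centroid (or ``center``).

    Returns (image patch (4, *patch_size), label patch (*patch_size,)); the
    volume is zero-padded symmetrically wherever it is smaller than the patch.
    """
    if any(p <= 0 for p in patch_size):
        raise ValueError("patch_size must be positive per axis")
    if center is None:
        if volume.brain_mask.any():
            center = np.asarray(ndimage.center_of_mass(volume.brain_mask))
        else:
            center = (np.asarray(volume.shape) - 1) / 2.0
    center = np.asarray(center, dtype=float)
    img = _center_crop_pad(volume.data, center, tuple(patch_size))
    lab = _center_crop_pad(labels.values, center, tuple(patch_size))
    return img, lab


def augment(sample: SliceSample, seed: int) -> SliceSample:
    """Random flip/rotate augmentation, applied identically to image and target.

    Independent horizontal and vertical flips (p=0.5 each) and a rotation by
    an angle uniform in [-15, +15] degrees; the image is resampled with
    linear interpolation, the target with nearest-neighbor so that the
    encoding stays binary.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    flip_h = rng.random() < 0.5
    flip_v = rng.random() < 0.5
    angle = rng.uniform(-15.0, 15.0)

    img = sample.image
    tgt = sample.target.channels
    if flip_h:
        img = img[:, ::-1]
        tgt = tgt[:, :, ::-1]
    if flip_v:
        img = img[::-1]
        tgt = tgt[:, ::-1]
    img = ndimage.rotate(img, angle, axes=(0, 1), reshape=False, order=1,
                         mode="constant", cval=0.0)
    tgt = ndimage.rotate(tgt, angle, axes=(1, 2), reshape=False, order=0,
                         mode="constant", cval=0.0)
    if sample.target.approach == "multi_class":
        # rotation can push a pixel's one-hot entirely into the padding;
        # re-assert background there so exclusivity survives
        empty = tgt.sum(axis=0) == 0
        tgt[0][empty] = 1.0
    return SliceSample(image=np.ascontiguousarray(img, dtype=np.float32),
                       target=TargetEncoding(approach=sample.target.approach,
                                             channels=np.ascontiguousarray(tgt, dtype=np.float32),
                                             region=sample.target.region),
                       patient_id=sample.patient_id,
                       slice_index=sample.slice_index)
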