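"""Training and per-region evaluation of one grid candidate.

A *candidate* is one (segmentation approach x intensity normalization)
combination of a U-net variant.  Training minimizes the approach's loss
with Adam (defaults: lr 1e-4, batch 16, 100 epochs for the slice-based
variants, batch 4 / 150 epochs for 3D), logging per-epoch training and
validation loss.  Evaluation thresholds the region probability at 0.5 and
scores mean DSC over patients against the ground-truth region masks.

Normalization states (Nyul standard scales) are fitted on the training
split only; the evaluator refuses to score a candidate on any patient that
contributed to its normalization fit (leakage guard).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import objectives
from .datasetbuild import SplitAssignment, augment, collect_2d, collect_25d, extract_3d_patch
from .labelspace import REGIONS, encode_target, labels_to_regions, region_probability
from .metrics import dsc
from .normalize import NyulState, nyul_apply, nyul_train, zscore_normalize
from .phantom import PhantomPatient
from .nn import Adam
from .unet import TrainedModel, UNet, UNetConfig, predict_volume, sigmoid, softmax
from .volume import MODALITIES, MultiModalVolume

__all__ = ["TrainConfig", "CandidateScore", "Normalizer", "fit_normalizer",
           "train_candidate", "evaluate_candidate", "LeakageError"]

NORMALIZATIONS = ("zscore", "nyul")


class LeakageError(RuntimeError):
    """Normalization state was fitted on evaluation patients."""


@dataclass
class TrainConfig:
    epochs: int = 100          # paper-scale default for the slice-based variants
    batch_size: int = 16
    learning_rate: float = 1e-4
    seed: int = 0
    augmentation: bool = True

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


@dataclass
class CandidateScore:
    candidate_id: str          # "<normalization>/<approach>"
    approach: str
    normalization_id: str
    region_dsc: dict[str, float]
    split_seed: int = 0


@dataclass
class Normalizer:
    """Per-modality intensity standardization, tagged with its fit provenance."""

    method: str                           # "zscore" | "nyul"
    states: dict[str, NyulState] = field(default_factory=dict)
    fit_ids: tuple[str, ...] = ()

    def apply(self, volume: MultiModalVolume) -> MultiModalVolume:
        out = np.empty_like(volume.data, dtype=np.float32)
        for mi, name in enumerate(MODALITIES):
            if self.method == "zscore":
                out[mi] = zscore_normalize(volume.data[mi], volume.brain_mask)
            elif self.method == "nyul":
                out[mi] = nyul_apply(volume.data[mi], volume.brain_mask, self.states[name])
            else:
                raise ValueError(f"unknown normalization {self.method!r}")
        return MultiModalVolume(data=out, brain_mask=volume.brain_mask,
                                spacing=volume.spacing)


def fit_normalizer(method: str, patients: Sequence[PhantomPatient]) -> Normalizer:
    """Fit a normalizer on a training population.

    Z-score is a per-volume statistic and needs no fit; Nyul learns one
    standard scale per modality from the given patients.
    """
    if method == "zscore":
        return Normalizer(method="zscore")
    if method == "nyul":
        states = {}
        for mi, name in enumerate(MODALITIES):
            vols = [p.volume.data[mi] for p in patients]
            masks = [p.volume.brain_mask for p in patients]
            states[name] = nyul_train(vols, masks)
        return Normalizer(method="nyul", states=states,
                          fit_ids=tuple(p.patient_id for p in patients))
    raise ValueError(f"unknown normalization {method!r}")


def _loss_fn(approach):
    # batches are (B, C, *spatial): the class/region axis is 1
    if approach == "multi_class":
        return lambda p, y: objectives.multiclass_cross_entropy(p, y, channel_axis=1)
    if approach == "multi_label":
        return lambda p, y: objectives.multilabel_loss(p, y, channel_axis=1)
    return objectives.binary_cross_entropy


def _collect_slices(patients, normalizer, approach, region, in_channels):
    collector = collect_25d if in_channels == 12 else collect_2d
    samples = []
    for p in patients:
        vol = normalizer.apply(p.volume)
        samples.extend(collector(vol, p.labels, approach, region, patient_id=p.patient_id))
    return samples


def _collect_patches(patients, normalizer, approach, region, patch_size):
    samples = []
    for p in patients:
        vol = normalizer.apply(p.volume)
        img, lab = extract_3d_patch(vol, p.labels, patch_size)
        target = encode_target(lab, approach, region)
        samples.append((img.astype(np.float32), target.channels))
    return samples


def _batch_arrays(samples, idx, use_aug, aug_seeds):
    """Assemble (B, C, *S) inputs and (B, Ct, *S) targets from sample records.

    Samples are either SliceSample (2D/2.5D, HWC images; augmentable) or
    plain (image, target) array pairs (3D patches, channels-first).
    """
    xs, ys = [], []
    for j, i in enumerate(idx):
        s = samples[i]
        if isinstance(s, tuple):
            xs.append(s[0])
            ys.append(s[1])
            continue
        if use_aug:
            s = augment(s, int(aug_seeds[j]))
        xs.append(np.moveaxis(s.image, 2, 0))
        ys.append(s.target.channels)
    return np.stack(xs), np.stack(ys)


def _epoch_loss(net: UNet, samples, batch_size, loss_fn):
    """Mean loss over samples in eval mode (validation monitoring)."""
    losses = []
    for i in range(0, len(samples), batch_size):
        idx = range(i, min(i + batch_size, len(samples)))
        x, y = _batch_arrays(samples, idx, False, None)
        losses.append(loss_fn(net.forward(x, train=False), y))
    return float(np.mean(losses))


def train_candidate(cohort: Sequence[PhantomPatient], split: SplitAssignment,
                    approach: str, normalization, unet_config: UNetConfig,
                    train_config: TrainConfig, region: str | None = None,
                    ) -> TrainedModel:
    """Train one candidate on the training split.

    ``normalization`` is either a method name ("zscore"/"nyul"), in which
    case the state is fitted on the training split, or a prefit
    :class:`Normalizer`.  Returns the final-epoch model with its per-epoch
    training/validation loss log.
    """
    by_id = {p.patient_id: p for p in cohort}
    train_patients = [by_id[i] for i in split.train_ids]
    val_patients = [by_id[i] for i in split.val_ids]
    if isinstance(normalization, Normalizer):
        normalizer = normalization
    else:
        normalizer = fit_normalizer(normalization, train_patients)

    loss_fn = _loss_fn(approach)
    rng = np.random.default_rng(train_config.seed)
    net = UNet(unet_config, seed=int(rng.integers(2 ** 31)))
    opt = Adam(net.parameters(), lr=train_config.learning_rate)

    if unet_config.dims == 3:
        # one brain-centered patch per patient, sized to the pooling factor
        factor = 2 ** unet_config.depth
        patch = tuple(-(-s // factor) * factor for s in cohort[0].volume.shape)
        samples = _collect_patches(train_patients, normalizer, approach, region, patch)
        val_samples = _collect_patches(val_patients, normalizer, approach, region,
                                       patch) if val_patients else []
        use_aug = False
    else:
        samples = _collect_slices(train_patients, normalizer, approach, region,
                                  unet_config.in_channels)
        val_samples = _collect_slices(val_patients, normalizer, approach, region,
                                      unet_config.in_channels) if val_patients else []
        use_aug = train_config.augmentation

    n_classes = unet_config.out_channels
    log: list[dict] = []
    for epoch in range(train_config.epochs):
        order = rng.permutation(len(samples))
        epoch_losses = []
        for i in range(0, len(order), train_config.batch_size):
            idx = order[i:i + train_config.batch_size]
            aug_seeds = rng.integers(2 ** 31, size=len(idx))
            x, y = _batch_arrays(samples, idx, use_aug, aug_seeds)
            logits = net.forward_logits(x, train=True)
            p = softmax(logits, axis=1) if unet_config.head == "softmax" else sigmoid(logits)
            loss = loss_fn(p, y)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: {loss} "
                    f"(approach={approach}, lr={train_config.learning_rate})")
            epoch_losses.append(loss)
            resid = (p - y).astype(np.float32)
            if unet_config.head == "softmax":
                g = resid * (n_classes / resid.size)   # mean over pixels
            else:
                g = resid / resid.size                 # mean over pixel-channels
            opt.zero_grad()
            net.backward(g)
            opt.step()
        entry = {"epoch": epoch, "train_loss": float(np.mean(epoch_losses))}
        if val_samples:
            entry["val_loss"] = _epoch_loss(net, val_samples,
                                            train_config.batch_size, loss_fn)
        log.append(entry)

    return TrainedModel(config=unet_config, approach=approach,
                        normalization_id=normalizer.method, network=net,
                        training_log=log, norm_fit_ids=normalizer.fit_ids,
                        region=region, seed=train_config.seed)


def predict_regions(model: TrainedModel, patient: PhantomPatient,
                    normalizer: Normalizer, regions: Sequence[str]) -> dict[str, np.ndarray]:
    """Region probability volumes for one patient, one forward pass."""
    vol = normalizer.apply(patient.volume)
    probs = predict_volume(model, vol, normalization_id=normalizer.method)
    return {r: region_probability(probs, model.approach, r) for r in regions}


def _check_leakage(model: TrainedModel, patients: Sequence[PhantomPatient]) -> None:
    overlap = set(model.norm_fit_ids) & {p.patient_id for p in patients}
    if overlap:
        raise LeakageError(
            f"normalization state was fitted on evaluation patients: {sorted(overlap)}")


def evaluate_candidate(model: TrainedModel, patients: Sequence[PhantomPatient],
                       region: str, normalizer: Normalizer,
                       *, threshold: float = 0.5,
                       all_regions: bool = False) -> CandidateScore:
    """Mean DSC of a trained candidate over held-out patients.

    Predicts each patient's volume, collapses the prediction onto the
    region(s), thresholds at ``threshold`` and compares against the
    ground-truth region masks.  ``all_regions`` also scores every region the
    approach can express (for score tables).
    """
    if not patients:
        raise ValueError("empty patient list")
    _check_leakage(model, patients)
    if all_regions and model.approach != "binary":
        regions = list(REGIONS)
    else:
        regions = [region]
    sums = {r: 0.0 for r in regions}
    for p in patients:
        region_probs = predict_regions(model, p, normalizer, regions)
        truth = labels_to_regions(p.labels)
        for r in regions:
            sums[r] += dsc(truth[r], region_probs[r] >= threshold)
    return CandidateScore(
        candidate_id=f"{model.normalization_id}/{model.approach}",
        approach=model.approach, normalization_id=model.normalization_id,
        region_dsc={r: sums[r] / len(patients) for r in regions})
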