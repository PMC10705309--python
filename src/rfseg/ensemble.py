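"""Region-focused selection (RFS / RFS+) over a candidate grid.

RFS+ trains one candidate per (segmentation approach x intensity
normalization) combination, scores every candidate on the internal test
split for the target region, keeps the top three by DSC, and fuses their
per-voxel region probabilities with DSC-proportional weights
(w_i = DSC_i / sum_j DSC_j) before thresholding.  Heterogeneous members
(softmax multi-class heads next to sigmoid region heads) are aligned on the
common region via ``region_probability`` prior to weighting.

The predecessor RFS instead combines the three thresholded member masks by
voxelwise union.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .labelspace import APPROACHES, REGIONS, labels_to_regions
from .metrics import MetricReport, evaluate_pair
from .phantom import PhantomPatient
from .datasetbuild import SplitAssignment, split_patients
from .training import (CandidateScore, Normalizer, TrainConfig, fit_normalizer,
                       predict_regions, train_candidate, evaluate_candidate,
                       NORMALIZATIONS)
from .unet import TrainedModel, UNetConfig

__all__ = ["EnsembleSpec", "GridResult", "RFSPlusConfig", "RFSPlusResult",
           "run_grid", "select_top3", "compute_weights", "ensemble_predict",
           "union_combine", "rfsplus_run"]

_VARIANT_IN_CHANNELS = {"2d": (2, 4), "2.5d": (2, 12), "3d": (3, 4)}


@dataclass
class EnsembleSpec:
    region: str
    members: tuple[str, str, str]          # candidate ids
    weights: tuple[float, float, float]
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if len(set(self.members)) != 3:
            raise ValueError("ensemble needs exactly 3 distinct members")
        w = np.asarray(self.weights, dtype=float)
        if w.min() < 0 or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be non-negative and sum to 1")
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "region": self.region, "members": list(self.members),
            "weights": list(self.weights), "threshold": self.threshold}, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "EnsembleSpec":
        d = json.loads(Path(path).read_text())
        return cls(region=d["region"], members=tuple(d["members"]),
                   weights=tuple(d["weights"]), threshold=d["threshold"])


@dataclass
class GridResult:
    scores: list[CandidateScore]
    models: dict[str, TrainedModel]
    normalizers: dict[str, Normalizer]


def _candidate_order(candidate_id: str) -> tuple[int, int]:
    norm, approach = candidate_id.split("/")
    return (APPROACHES.index(approach), NORMALIZATIONS.index(norm))


def run_grid(cohort: Sequence[PhantomPatient], split: SplitAssignment,
             approaches: Sequence[str], normalizations: Sequence[str],
             region: str, unet_config: UNetConfig, train_config: TrainConfig,
             ) -> GridResult:
    """Train and score one candidate per approach x normalization cell.

    Candidates are scored on the internal test split for the target region
    (and on every region they can express, for the score table).  Binary
    candidates are trained on the target region.  Per-candidate seeds are
    derived deterministically from the candidate's grid cell so the score
    table is invariant to training order.
    """
    if not approaches or not normalizations:
        raise ValueError("need at least one approach and one normalization")
    by_id = {p.patient_id: p for p in cohort}
    train_patients = [by_id[i] for i in split.train_ids]
    test_patients = [by_id[i] for i in split.test_ids]
    normalizers = {n: fit_normalizer(n, train_patients) for n in normalizations}

    scores, models = [], {}
    for norm_id in normalizations:
        for approach in approaches:
            cid = f"{norm_id}/{approach}"
            cfg = replace(unet_config,
                          out_channels={"multi_class": 4, "multi_label": 3, "binary": 1}[approach],
                          head="softmax" if approach == "multi_class" else "sigmoid")
            cand_seed = (train_config.seed * 997
                         + 101 * APPROACHES.index(approach)
                         + 11 * NORMALIZATIONS.index(norm_id)) % (2 ** 31)
            cand_train = replace(train_config, seed=cand_seed)
            try:
                model = train_candidate(
                    cohort, split, approach, normalizers[norm_id], cfg, cand_train,
                    region=region if approach == "binary" else None)
            except Exception as exc:
                raise RuntimeError(f"training failed for candidate {cid}") from exc
            score = evaluate_candidate(model, test_patients, region,
                                       normalizers[norm_id], all_regions=True)
            models[cid] = model
            scores.append(score)
    return GridResult(scores=scores, models=models, normalizers=normalizers)


def select_top3(scores: Sequence[CandidateScore], region: str) -> list[str]:
    """The three highest region-DSC candidate ids, descending.

    Ties are broken by the fixed candidate ordering: approaches in the
    order multi_class, multi_label, binary; normalizations zscore, nyul.
    """
    usable = [s for s in scores if region in s.region_dsc]
    if len(usable) < 3:
        raise ValueError(f"need at least 3 candidates scored on {region!r}, "
                         f"got {len(usable)}")
    ranked = sorted(usable, key=lambda s: (-s.region_dsc[region],
                                           _candidate_order(s.candidate_id)))
    return [s.candidate_id for s in ranked[:3]]


def compute_weights(scores: Sequence[float], *, equal: bool = False) -> np.ndarray:
    """DSC-proportional ensemble weights w_i = DSC_i / sum_j DSC_j."""
    s = np.asarray(scores, dtype=float)
    if s.shape != (3,):
        raise ValueError("exactly three member scores required")
    if equal:
        return np.full(3, 1.0 / 3.0)
    if np.any(s <= 0):
        raise ValueError("member scores must be > 0 for DSC-proportional "
                         "weights (pass equal=True to fall back)")
    return s / s.sum()


def ensemble_predict(spec: EnsembleSpec, members: dict[str, TrainedModel],
                     patient: PhantomPatient,
                     normalizers: dict[str, Normalizer]) -> np.ndarray:
    """Weighted-probability ensemble mask for one patient.

    Each member sees the patient through its *own* normalization; the
    weighted mean of the members' region probabilities is thresholded.
    """
    missing = [m for m in spec.members if m not in members]
    if missing:
        raise ValueError(f"members missing from model registry: {missing}")
    p = None
    for cid, w in zip(spec.members, spec.weights):
        model = members[cid]
        if f"{model.normalization_id}/{model.approach}" != cid:
            raise ValueError(f"model registered under {cid} is tagged "
                             f"{model.normalization_id}/{model.approach}")
        prob = predict_regions(model, patient, normalizers[model.normalization_id],
                               [spec.region])[spec.region]
        p = w * prob if p is None else p + w * prob
    return p >= spec.threshold


def union_combine(masks: Sequence[np.ndarray]) -> np.ndarray:
    """Voxelwise OR of region masks (the RFS combiner)."""
    masks = [np.asarray(m, dtype=bool) for m in masks]
    if len({m.shape for m in masks}) != 1:
        raise ValueError("masks must share one grid")
    out = masks[0].copy()
    for m in masks[1:]:
        out |= m
    return out


@dataclass
class RFSPlusConfig:
    approaches: tuple[str, ...] = APPROACHES
    normalizations: tuple[str, ...] = NORMALIZATIONS
    variant: str = "2d"
    unet_depth: int = 4
    unet_base_channels: int = 64
    train: TrainConfig = field(default_factory=TrainConfig)
    split_seed: int = 0
    threshold: float = 0.5
    equal_weights: bool = False

    def unet_config(self) -> UNetConfig:
        dims, in_ch = _VARIANT_IN_CHANNELS[self.variant]
        return UNetConfig(dims=dims, in_channels=in_ch, out_channels=1,
                          depth=self.unet_depth, base_channels=self.unet_base_channels,
                          head="sigmoid")


@dataclass
class RFSPlusResult:
    spec: EnsembleSpec
    report: MetricReport                     # mean over held-out patients
    grid: GridResult
    split: SplitAssignment
    member_dsc: dict[str, float]             # held-out DSC per member
    union_dsc: float


def scores_table(scores: Sequence[CandidateScore]) -> pd.DataFrame:
    """Score table shaped like the candidate-grid comparison: one row per
    normalization x approach, one column per region (DSC)."""
    rows = []
    for s in scores:
        row = {"normalization": s.normalization_id, "approach": s.approach}
        row.update({r: s.region_dsc.get(r, np.nan) for r in REGIONS})
        rows.append(row)
    return pd.DataFrame(rows)


def rfsplus_run(cohort: Sequence[PhantomPatient], region: str,
                config: RFSPlusConfig, out_dir: str | Path | None = None,
                ) -> RFSPlusResult:
    """End-to-end RFS+: split, normalize, grid, select, weight, ensemble.

    The candidate grid is scored on the internal test split; the ensemble
    of the top three is then evaluated on the same held-out patients with
    all four metrics (metric means over patients; HD95 averaged over the
    patients where it is defined).
    """
    split = split_patients([p.patient_id for p in cohort], config.split_seed)
    grid = run_grid(cohort, split, config.approaches, config.normalizations,
                    region, config.unet_config(), config.train)

    top3 = select_top3(grid.scores, region)
    score_of = {s.candidate_id: s.region_dsc[region] for s in grid.scores}
    weights = compute_weights([score_of[c] for c in top3], equal=config.equal_weights)
    spec = EnsembleSpec(region=region, members=tuple(top3),
                        weights=tuple(float(w) for w in weights),
                        threshold=config.threshold)

    by_id = {p.patient_id: p for p in cohort}
    test_patients = [by_id[i] for i in split.test_ids]
    reports, member_masks_dsc = [], {c: [] for c in top3}
    union_dscs = []
    for patient in test_patients:
        truth = labels_to_regions(patient.labels)[region]
        member_masks = {}
        for cid in top3:
            model = grid.models[cid]
            prob = predict_regions(model, patient, grid.normalizers[model.normalization_id],
                                   [region])[region]
            member_masks[cid] = prob >= config.threshold
            member_masks_dsc[cid].append(evaluate_pair(truth, member_masks[cid]).dsc)
        mask = ensemble_predict(spec, grid.models, patient, grid.normalizers)
        reports.append(evaluate_pair(truth, mask, spacing=patient.labels.spacing))
        union_dscs.append(evaluate_pair(truth, union_combine(list(member_masks.values()))).dsc)

    hd = [r.hd95 for r in reports if np.isfinite(r.hd95)]
    report = MetricReport(
        dsc=float(np.mean([r.dsc for r in reports])),
        hd95=float(np.mean(hd)) if hd else float("nan"),
        sensitivity=float(np.nanmean([r.sensitivity for r in reports])),
        specificity=float(np.nanmean([r.specificity for r in reports])),
    )
    result = RFSPlusResult(
        spec=spec, report=report, grid=grid, split=split,
        member_dsc={c: float(np.mean(v)) for c, v in member_masks_dsc.items()},
        union_dsc=float(np.mean(union_dscs)))

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        spec.to_json(out_dir / "ensemble_spec.json")
        scores_table(grid.scores).to_csv(out_dir / "candidate_scores.csv", index=False)
        pd.DataFrame([report.as_dict()]).to_csv(out_dir / "ensemble_metrics.csv", index=False)
        for cid, model in grid.models.items():
            model.save(out_dir / "models" / cid.replace("/", "_"))
    return result
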