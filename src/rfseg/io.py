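"""NIfTI volume I/O and cohort layout.

Patients are stored BraTS-style, one compressed NIfTI per modality plus one
label file::

    <out>/<patient_id>/<patient_id>_t1.nii.gz
                       <patient_id>_t1ce.nii.gz
                       <patient_id>_t2.nii.gz
                       <patient_id>_flair.nii.gz
                       <patient_id>_seg.nii.gz

with a cohort-level ``manifest.csv`` (patient_id, scanner_id, paths).
Volumes are used in array index space; no reorientation is performed, but a
warning is emitted if the modality headers disagree.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .labelspace import LabelVolume
from .phantom import PhantomPatient
from .volume import MODALITIES, MultiModalVolume

__all__ = ["write_patient", "write_cohort", "read_patient", "read_cohort", "write_mask"]

log = logging.getLogger(__name__)


def _affine(spacing: Sequence[float]) -> np.ndarray:
    return np.diag(list(spacing) + [1.0])


def _save(arr: np.ndarray, spacing, path: Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(arr), _affine(spacing)), str(path))


def write_patient(patient: PhantomPatient, out_dir: str | Path) -> dict[str, Path]:
    """One file per modality plus the label file; returns the paths."""
    pdir = Path(out_dir) / patient.patient_id
    pdir.mkdir(parents=True, exist_ok=True)
    spacing = patient.volume.spacing
    paths = {}
    for mi, name in enumerate(MODALITIES):
        paths[name] = pdir / f"{patient.patient_id}_{name}.nii.gz"
        _save(patient.volume.data[mi].astype(np.float32), spacing, paths[name])
    paths["seg"] = pdir / f"{patient.patient_id}_seg.nii.gz"
    _save(patient.labels.values.astype(np.uint8), spacing, paths["seg"])
    return paths


def write_cohort(cohort: Sequence[PhantomPatient], out_dir: str | Path) -> Path:
    """Write every patient and the cohort manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    rows = []
    for p in cohort:
        paths = write_patient(p, out_dir)
        row = {"patient_id": p.patient_id, "scanner_id": p.scanner_id}
        row.update({k: str(v.relative_to(out_dir)) for k, v in paths.items()})
        rows.append(row)
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_patient(modality_paths: dict[str, str | Path], label_path: str | Path,
                 ) -> tuple[MultiModalVolume, LabelVolume]:
    """Load four modalities plus labels; grids and spacings must agree.

    The brain mask is taken as the union of nonzero voxels across the
    modalities (skull-stripped convention).
    """
    arrays, spacings = [], []
    for name in MODALITIES:
        if name not in modality_paths or not Path(modality_paths[name]).exists():
            raise FileNotFoundError(f"missing modality file: {name}")
        img = nib.load(str(modality_paths[name]))
        arrays.append(np.asarray(img.dataobj, dtype=np.float32))
        spacings.append(tuple(float(z) for z in img.header.get_zooms()[:3]))
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValueError(f"modality grids differ: {sorted(shapes)}")
    if len(set(spacings)) != 1:
        raise ValueError(f"modality spacings differ: {sorted(set(spacings))}")

    seg = nib.load(str(label_path))
    seg_arr = np.asarray(seg.dataobj)
    if seg_arr.shape != arrays[0].shape:
        raise ValueError(f"label grid {seg_arr.shape} != modality grid {arrays[0].shape}")
    affines = [nib.load(str(modality_paths[n])).affine for n in MODALITIES]
    if not all(np.allclose(affines[0], a) for a in affines[1:]):
        log.warning("modality headers disagree on orientation; using array index space")

    data = np.stack(arrays)
    mask = (np.abs(data) > 0).any(axis=0)
    vol = MultiModalVolume(data=data, brain_mask=mask, spacing=spacings[0])
    labels = LabelVolume(values=seg_arr.astype(np.uint8), spacing=spacings[0])
    return vol, labels


def read_cohort(cohort_dir: str | Path) -> list[PhantomPatient]:
    """Load a cohort written by :func:`write_cohort` from its manifest."""
    cohort_dir = Path(cohort_dir)
    manifest = pd.read_csv(cohort_dir / "manifest.csv")
    patients = []
    for _, row in manifest.iterrows():
        paths = {name: cohort_dir / row[name] for name in MODALITIES}
        vol, labels = read_patient(paths, cohort_dir / row["seg"])
        patients.append(PhantomPatient(patient_id=row["patient_id"], volume=vol,
                                       labels=labels, scanner_id=row["scanner_id"]))
    return patients


def write_mask(mask: np.ndarray | LabelVolume, reference: str | Path | None,
               path: str | Path, spacing=(1.0, 1.0, 1.0)) -> Path:
    """Write a binary region mask (as 0/1 uint8) or a label volume.

    If ``reference`` is given, its grid must match and its affine/spacing
    metadata is copied onto the output.
    """
    if isinstance(mask, LabelVolume):
        arr = mask.values.astype(np.uint8)
        spacing = mask.spacing
    else:
        arr = np.asarray(mask)
        if arr.dtype == bool or set(np.unique(arr)).issubset({0, 1}):
            arr = arr.astype(np.uint8)
        else:
            raise ValueError("region mask must be binary; use LabelVolume for label maps")
    if reference is not None:
        ref = nib.load(str(reference))
        if tuple(ref.shape[:3]) != arr.shape:
            raise ValueError(f"mask grid {arr.shape} != reference grid {tuple(ref.shape[:3])}")
        img = nib.Nifti1Image(arr, ref.affine, header=ref.header.copy())
        img.set_data_dtype(np.uint8)
    else:
        img = nib.Nifti1Image(arr, _affine(spacing))
    nib.save(img, str(path))
    return Path(path)
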