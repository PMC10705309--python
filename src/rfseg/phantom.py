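"""Synthetic multi-modal phantom cohorts with BraTS-like tumor geometry.

Each phantom patient is an ellipsoidal "brain" containing a nested family
of axis-aligned tumor ellipsoids: whole tumor (WT) ⊃ tumor core (TC) ⊃
necrotic core (NCR), with the enhancing tumor (ET) as the TC shell around
the core and edema (ED) as the WT rim outside the core.  Labels follow the
BraTS coding (NCR=1, ED=2, ET=4), so ET ⊆ TC ⊆ WT holds by construction.

Intensities emulate the modality contrasts that drive real segmentation:
ET is bright on post-contrast T1 (T1ce) relative to T1, and the whole
tumor (ED/ET) is bright on FLAIR relative to healthy brain.  On top of the
per-tissue means the generator adds a smooth multiplicative bias field, IID
Gaussian noise, and a per-patient scanner gain/offset — the minimal model
of inter-scanner intensity variation that normalization must undo.

Everything is deterministic given (seed, patient index).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .labelspace import LabelVolume
from .volume import MODALITIES, MultiModalVolume

__all__ = [
    "DEFAULT_CONTRAST",
    "PhantomConfig",
    "PhantomPatient",
    "TumorSizingError",
    "generate_patient",
    "generate_cohort",
    "apply_scanner_affine",
]


class TumorSizingError(ValueError):
    """Requested tumor volume fraction cannot fit inside the brain."""


#: per-tissue mean intensity for (t1, t1ce, t2, flair).  These defaults are
#: fixtures; only the ordering constraints (ET bright on T1ce vs T1, tumor
#: bright on FLAIR vs brain) are meaningful.
DEFAULT_CONTRAST: dict[str, tuple[float, float, float, float]] = {
    "background": (0.0, 0.0, 0.0, 0.0),
    "brain": (100.0, 100.0, 80.0, 70.0),
    "ncr": (60.0, 55.0, 95.0, 85.0),
    "ed": (80.0, 85.0, 110.0, 130.0),
    "et": (90.0, 160.0, 100.0, 120.0),
}

_TISSUE_OF_LABEL = {0: "brain", 1: "ncr", 2: "ed", 4: "et"}


@dataclass
class PhantomConfig:
    shape: tuple[int, int, int] = (64, 64, 32)
    n_patients: int = 10
    tumor_volume_fraction_range: tuple[float, float] = (0.03, 0.10)
    contrast_table: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CONTRAST))
    noise_sd: float = 5.0
    bias_field_amplitude: float = 0.10
    scanner_gain_range: tuple[float, float] = (0.8, 1.2)
    scanner_offset_range: tuple[float, float] = (-10.0, 10.0)
    n_scanners: int = 3
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(d < 16 for d in self.shape):
            raise ValueError("shape must be 3D with every dim >= 16")
        if any(d > m for d, m in zip(self.shape, (240, 240, 155))):
            raise ValueError("shape exceeds the 240x240x155 maximum grid")
        lo, hi = self.tumor_volume_fraction_range
        if not (0 < lo <= hi < 1):
            raise ValueError("tumor volume fraction bounds must lie in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        ct = self.contrast_table
        m = {name: i for i, name in enumerate(MODALITIES)}
        if not ct["et"][m["t1ce"]] > ct["et"][m["t1"]]:
            raise ValueError("contrast_table must put ET brighter on t1ce than on t1")
        for tumor in ("ed", "et"):
            if not ct[tumor][m["flair"]] > ct["brain"][m["flair"]]:
                raise ValueError(f"contrast_table must put {tumor} brighter than brain on flair")


@dataclass
class PhantomPatient:
    patient_id: str
    volume: MultiModalVolume
    labels: LabelVolume
    scanner_id: str


def _ellipsoid(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return acc <= 1.0


def _bias_field(shape, amplitude, rng) -> np.ndarray:
    """Smooth multiplicative field 1 ± amplitude from a random quadratic."""
    coords = [np.linspace(-1.0, 1.0, s) for s in shape]
    x, y, z = np.meshgrid(*coords, indexing="ij")
    basis = [x, y, z, x * y, x * z, y * z, x ** 2, y ** 2, z ** 2]
    coef = rng.normal(size=len(basis))
    p = sum(c * b for c, b in zip(coef, basis))
    peak = np.abs(p).max()
    if peak > 0:
        p = p / peak
    return 1.0 + amplitude * p


def _scanner_affine_params(config: PhantomConfig, scanner_index: int) -> tuple[float, float]:
    rng = np.random.default_rng([config.seed, 7919, scanner_index])
    gain = rng.uniform(*config.scanner_gain_range)
    offset = rng.uniform(*config.scanner_offset_range)
    return float(gain), float(offset)


def apply_scanner_affine(volume: MultiModalVolume, gain: float, offset: float) -> MultiModalVolume:
    """Affine intensity change gain*x + offset on brain voxels; background stays 0."""
    data = volume.data.astype(np.float32, copy=True)
    data[:, volume.brain_mask] = gain * data[:, volume.brain_mask] + offset
    return MultiModalVolume(data=data, brain_mask=volume.brain_mask, spacing=volume.spacing)


def generate_patient(config: PhantomConfig, index: int) -> PhantomPatient:
    """One phantom patient, deterministic given (config.seed, index)."""
    if not 0 <= index < config.n_patients:
        raise ValueError(f"index {index} outside 0..{config.n_patients - 1}")
    rng = np.random.default_rng([config.seed, index])
    shape = np.asarray(config.shape, dtype=float)

    brain_center = (shape - 1) / 2.0
    brain_radii = 0.45 * shape
    brain = _ellipsoid(config.shape, brain_center, brain_radii)

    # WT ellipsoid sized to a target fraction of the brain volume, with
    # mild random anisotropy (volume-preserving jitter).
    frac = rng.uniform(*config.tumor_volume_fraction_range)
    jitter = rng.uniform(0.8, 1.25, size=3)
    jitter /= np.prod(jitter) ** (1.0 / 3.0)
    wt_radii = frac ** (1.0 / 3.0) * brain_radii * jitter
    if np.any(wt_radii >= brain_radii):
        raise TumorSizingError(
            f"tumor fraction {frac:.3f} does not fit inside the brain along every axis")

    # sufficient containment: (|offset_i| + r_i)^2 / a_i^2 summed <= 1
    for _ in range(200):
        offset = rng.uniform(-1.0, 1.0, size=3) * (brain_radii - wt_radii)
        if np.sum(((np.abs(offset) + wt_radii) / brain_radii) ** 2) <= 1.0:
            break
        offset *= 0.5
        if np.sum(((np.abs(offset) + wt_radii) / brain_radii) ** 2) <= 1.0:
            break
    else:
        raise TumorSizingError("could not place the tumor inside the brain")
    center = brain_center + offset

    tc_radii = wt_radii * rng.uniform(0.55, 0.75)
    core_radii = np.maximum(tc_radii * rng.uniform(0.45, 0.70), 1.2)
    core_radii = np.minimum(core_radii, 0.9 * tc_radii)

    wt = _ellipsoid(config.shape, center, wt_radii) & brain
    tc = _ellipsoid(config.shape, center, tc_radii) & brain
    core = _ellipsoid(config.shape, center, core_radii) & brain

    labels = np.zeros(config.shape, dtype=np.uint8)
    labels[wt] = 2            # ED rim
    labels[tc] = 4            # ET shell
    labels[core] = 1          # NCR core

    contrast = config.contrast_table
    data = np.zeros((len(MODALITIES),) + tuple(config.shape), dtype=np.float32)
    for code, tissue in _TISSUE_OF_LABEL.items():
        sel = brain & (labels == code)
        for mi in range(len(MODALITIES)):
            data[mi][sel] = contrast[tissue][mi]

    for mi in range(len(MODALITIES)):
        bias = _bias_field(config.shape, config.bias_field_amplitude, rng)
        noisy = data[mi] * bias + rng.normal(0.0, config.noise_sd, size=config.shape)
        data[mi] = np.where(brain, noisy, 0.0).astype(np.float32)

    scanner_index = index % max(config.n_scanners, 1)
    gain, offs = _scanner_affine_params(config, scanner_index)
    vol = apply_scanner_affine(
        MultiModalVolume(data=data, brain_mask=brain, spacing=config.spacing), gain, offs)
    return PhantomPatient(
        patient_id=f"phantom{index:03d}",
        volume=vol,
        labels=LabelVolume(values=labels, spacing=config.spacing),
        scanner_id=f"scanner{scanner_index}",
    )


def generate_cohort(config: PhantomConfig) -> list[PhantomPatient]:
    """All n_patients phantoms with independent tumor geometry."""
    return [generate_patient(config, i) for i in range(config.n_patients)]


def clean_config(config: PhantomConfig) -> PhantomConfig:
    """Copy of the config with the scanner affine switched off (gain 1, offset 0)."""
    return replace(config, scanner_gain_range=(1.0, 1.0), scanner_offset_range=(0.0, 0.0))
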