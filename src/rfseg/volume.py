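"""In-memory container for co-registered multi-modal MRI."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MODALITIES", "MultiModalVolume"]

#: fixed modality stacking order used everywhere in the package
MODALITIES = ("t1", "t1ce", "t2", "flair")


@dataclass
class MultiModalVolume:
    """Four aligned 3D intensity volumes plus brain mask and voxel spacing.

    ``data`` has shape (4, X, Y, Z) in the order t1, t1ce, t2, flair;
    ``brain_mask`` is the skull-stripped foreground on the same grid.
    """

    data: np.ndarray
    brain_mask: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        if self.data.ndim != 4 or self.data.shape[0] != len(MODALITIES):
            raise ValueError(f"data must be ({len(MODALITIES)}, X, Y, Z), got {self.data.shape}")
        if self.brain_mask.shape != self.data.shape[1:]:
            raise ValueError("brain mask grid does not match the modality grids")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    def modality(self, name: str) -> np.ndarray:
        """One modality volume by name (t1, t1ce, t2, flair)."""
        return self.data[MODALITIES.index(name)]
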