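"""YAML run configuration for the end-to-end pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .phantom import PhantomConfig
from .ensemble import RFSPlusConfig
from .training import TrainConfig

__all__ = ["RunConfig", "load_run_config"]

_TOP_KEYS = {"output_dir", "region", "phantom", "cohort_dir", "split_seed",
             "grid", "train", "threshold", "equal_weights"}
_GRID_KEYS = {"approaches", "normalizations", "variant", "depth", "base_channels"}


@dataclass
class RunConfig:
    region: str = "tc"
    output_dir: str = "rfseg_out"
    phantom: PhantomConfig | None = field(default_factory=PhantomConfig)
    cohort_dir: str | None = None
    rfsplus: RFSPlusConfig = field(default_factory=RFSPlusConfig)


def load_run_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run config; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    grid = raw.get("grid", {})
    bad = set(grid) - _GRID_KEYS
    if bad:
        raise ValueError(f"unknown grid keys: {sorted(bad)}")
    train = TrainConfig(**raw.get("train", {}))
    rfsplus = RFSPlusConfig(
        approaches=tuple(grid.get("approaches", ("multi_class", "multi_label", "binary"))),
        normalizations=tuple(grid.get("normalizations", ("zscore", "nyul"))),
        variant=grid.get("variant", "2d"),
        unet_depth=int(grid.get("depth", 4)),
        unet_base_channels=int(grid.get("base_channels", 64)),
        train=train,
        split_seed=int(raw.get("split_seed", 0)),
        threshold=float(raw.get("threshold", 0.5)),
        equal_weights=bool(raw.get("equal_weights", False)),
    )
    phantom_cfg = None
    if raw.get("cohort_dir") is None:
        ph = raw.get("phantom", {})
        if "shape" in ph:
            ph["shape"] = tuple(ph["shape"])
        phantom_cfg = PhantomConfig(**ph)
    return RunConfig(region=raw.get("region", "tc"),
                     output_dir=raw.get("output_dir", "rfseg_out"),
                     phantom=phantom_cfg,
                     cohort_dir=raw.get("cohort_dir"),
                     rfsplus=rfsplus)
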