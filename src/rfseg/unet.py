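"""U-net encoder-decoder variants (2D, 2.5D, 3D) with approach-specific heads.

The architecture is the canonical U-net: ``depth`` encoder blocks of
(conv 3x3, batch-norm, ReLU) x2 followed by 2x max-pooling, a bottleneck
block, and a mirrored decoder using 2x transposed-convolution upsampling
with channel-concatenation skip connections, closed by a 1x1 convolution
and the head.  Feature widths start at ``base_channels`` and double per
pooling; the full-size configuration (base 64, depth 4) has the classic
64/128/256/512 encoder widths and a 1024-channel bottleneck.  "Same"
padding keeps the output grid equal to the input grid.

The 2.5D variant is the same 2D network with 12 input channels (a
previous/current/next slice triplet per modality); the 3D variant uses
volumetric kernels on a single brain-centered patch.

Heads: softmax for the multi-class approach (mutually exclusive label
channels), sigmoid for the multi-label and binary approaches (independent
overlapping region channels).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .datasetbuild import stack_slices_2d, stack_slices_25d
from .nn import BatchNorm, Conv, ConvTranspose2x, MaxPool2x, Parameter, ReLU
from .volume import MultiModalVolume

__all__ = ["UNetConfig", "UNet", "TrainedModel", "build_unet", "predict_volume",
           "softmax", "sigmoid"]

_HEAD_OF_APPROACH = {"multi_class": ("softmax", 4),
                     "multi_label": ("sigmoid", 3),
                     "binary": ("sigmoid", 1)}


@dataclass
class UNetConfig:
    dims: int = 2
    in_channels: int = 4
    out_channels: int = 4
    depth: int = 4
    base_channels: int = 64
    head: str = "softmax"

    def __post_init__(self) -> None:
        if self.dims not in (2, 3):
            raise ValueError("dims must be 2 or 3")
        if self.head not in ("softmax", "sigmoid"):
            raise ValueError("head must be softmax or sigmoid")
        if min(self.in_channels, self.out_channels, self.depth, self.base_channels) < 1:
            raise ValueError("channel/depth counts must be positive")

    @classmethod
    def for_approach(cls, approach: str, *, dims: int = 2, in_channels: int | None = None,
                     depth: int = 4, base_channels: int = 64) -> "UNetConfig":
        """Config with the head/out_channels the approach dictates."""
        head, out = _HEAD_OF_APPROACH[approach]
        if in_channels is None:
            in_channels = 4
        return cls(dims=dims, in_channels=in_channels, out_channels=out,
                   depth=depth, base_channels=base_channels, head=head)

    @property
    def encoder_widths(self) -> tuple[int, ...]:
        return tuple(self.base_channels * 2 ** d for d in range(self.depth))

    @property
    def bottleneck_channels(self) -> int:
        return self.base_channels * 2 ** self.depth


def softmax(x: np.ndarray, axis: int = 1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class _DoubleConv:
    def __init__(self, ndim, cin, cout, rng):
        self.layers = [Conv(ndim, cin, cout, 3, rng), BatchNorm(cout), ReLU(),
                       Conv(ndim, cout, cout, 3, rng), BatchNorm(cout), ReLU()]

    def forward(self, x, train):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]

    def norms(self):
        return [layer for layer in self.layers if isinstance(layer, BatchNorm)]


class UNet:
    """Encoder-decoder network; ``forward`` returns head probabilities."""

    def __init__(self, config: UNetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        nd, b, depth = config.dims, config.base_channels, config.depth
        widths = config.encoder_widths
        self.encoder, self.pools = [], []
        cin = config.in_channels
        for w in widths:
            self.encoder.append(_DoubleConv(nd, cin, w, rng))
            self.pools.append(MaxPool2x(nd))
            cin = w
        self.bottleneck = _DoubleConv(nd, widths[-1], config.bottleneck_channels, rng)
        self.ups, self.decoder = [], []
        up_in = config.bottleneck_channels
        for w in reversed(widths):
            self.ups.append(ConvTranspose2x(nd, up_in, w, rng))
            self.decoder.append(_DoubleConv(nd, 2 * w, w, rng))
            up_in = w
        self.final = Conv(nd, widths[0], config.out_channels, 1, rng)
        if config.head == "sigmoid":
            # rare-class bias init: start region probabilities near the tumor
            # prior (~2%) rather than 0.5, so the initial background gradient
            # does not push features into an all-suppressing basin
            self.final.bias.value[...] = -4.0

    # --- plumbing -------------------------------------------------------
    def _blocks(self):
        return self.encoder + [self.bottleneck] + self.decoder

    def parameters(self) -> list[Parameter]:
        params = []
        for blk in self._blocks():
            params += blk.parameters()
        for up in self.ups:
            params += up.parameters()
        params += self.final.parameters()
        return params

    def _norm_layers(self):
        return [n for blk in self._blocks() for n in blk.norms()]

    def state_arrays(self) -> list[np.ndarray]:
        arrays = [p.value for p in self.parameters()]
        for bn in self._norm_layers():
            arrays += [bn.running_mean, bn.running_var]
        return arrays

    def load_state_arrays(self, arrays: Sequence[np.ndarray]) -> None:
        params = self.parameters()
        for p, a in zip(params, arrays[:len(params)]):
            if p.value.shape != a.shape:
                raise ValueError("checkpoint does not match network config")
            p.value = np.ascontiguousarray(a, dtype=np.float32)
        rest = arrays[len(params):]
        for bn, mean, var in zip(self._norm_layers(), rest[0::2], rest[1::2]):
            bn.running_mean = np.ascontiguousarray(mean, dtype=np.float32)
            bn.running_var = np.ascontiguousarray(var, dtype=np.float32)

    # --- forward / backward --------------------------------------------
    def _check_spatial(self, x):
        factor = 2 ** self.config.depth
        spatial = x.shape[2:]
        if any(s % factor for s in spatial):
            raise ValueError(
                f"spatial dims {tuple(spatial)} must be divisible by 2^depth = {factor}")

    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._check_spatial(x)
        x = np.ascontiguousarray(x, dtype=np.float32)
        skips = []
        for blk, pool in zip(self.encoder, self.pools):
            s = blk.forward(x, train)
            skips.append(s)
            x = pool.forward(s, train)
        x = self.bottleneck.forward(x, train)
        self._skip_channels = []
        for up, dec, skip in zip(self.ups, self.decoder, reversed(skips)):
            x = up.forward(x, train)
            self._skip_channels.append(skip.shape[1])
            x = np.concatenate([skip, x], axis=1)
            x = dec.forward(x, train)
        return self.final.forward(x, train)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        logits = self.forward_logits(x, train)
        return softmax(logits, axis=1) if self.config.head == "softmax" else sigmoid(logits)

    def backward(self, g_logits: np.ndarray) -> None:
        g = self.final.backward(g_logits)
        skip_grads = []
        for up, dec, c_skip in zip(reversed(self.ups), reversed(self.decoder),
                                   reversed(self._skip_channels)):
            g = dec.backward(g)
            skip_grads.append(g[:, :c_skip])
            g = up.backward(g[:, c_skip:])
        g = self.bottleneck.backward(g)
        # skip_grads were collected shallow-to-deep; the encoder unwinds deep-to-shallow
        for blk, pool, sg in zip(reversed(self.encoder), reversed(self.pools),
                                 reversed(skip_grads)):
            g = pool.backward(g) + sg
            g = blk.backward(g)


def build_unet(config: UNetConfig, seed: int = 0) -> UNet:
    """Construct a randomly initialized network for the given config."""
    return UNet(config, seed=seed)


@dataclass
class TrainedModel:
    """A network tagged with its approach and normalization provenance."""

    config: UNetConfig
    approach: str
    normalization_id: str
    network: UNet
    training_log: list[dict] = field(default_factory=list)
    norm_fit_ids: tuple[str, ...] = ()
    region: str | None = None  # binary approach only
    seed: int = 0

    def save(self, run_dir: str | Path) -> None:
        run_dir = Path(run_dir)
        run_dir.mkdir(parents=True, exist_ok=True)
        arrays = self.network.state_arrays()
        np.savez_compressed(run_dir / "checkpoint.npz",
                            **{f"arr_{i}": a for i, a in enumerate(arrays)})
        sidecar = {"config": asdict(self.config), "approach": self.approach,
                   "normalization_id": self.normalization_id,
                   "norm_fit_ids": list(self.norm_fit_ids),
                   "region": self.region, "seed": self.seed,
                   "training_log": self.training_log}
        (run_dir / "model.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, run_dir: str | Path) -> "TrainedModel":
        run_dir = Path(run_dir)
        sidecar = json.loads((run_dir / "model.json").read_text())
        cfg = sidecar["config"]
        cfg["head"] = str(cfg["head"])
        config = UNetConfig(**cfg)
        net = UNet(config, seed=sidecar.get("seed", 0))
        with np.load(run_dir / "checkpoint.npz") as z:
            arrays = [z[f"arr_{i}"] for i in range(len(z.files))]
        net.load_state_arrays(arrays)
        return cls(config=config, approach=sidecar["approach"],
                   normalization_id=sidecar["normalization_id"], network=net,
                   training_log=sidecar.get("training_log", []),
                   norm_fit_ids=tuple(sidecar.get("norm_fit_ids", [])),
                   region=sidecar.get("region"), seed=sidecar.get("seed", 0))


def _pad_to_multiple(arr: np.ndarray, factor: int) -> tuple[np.ndarray, list[tuple[int, int]]]:
    pads = [(0, 0)] * 2
    for s in arr.shape[2:]:
        extra = (-s) % factor
        pads.append((extra // 2, extra - extra // 2))
    return np.pad(arr, pads), pads


def predict_volume(model: TrainedModel, volume: MultiModalVolume,
                   *, batch_size: int = 16,
                   normalization_id: str | None = None) -> np.ndarray:
    """Per-channel probability volume (C, X, Y, Z) for one patient.

    2D/2.5D models run slice-wise and are reassembled along the axial axis;
    3D models run on the whole (zero-padded) volume and the padding is
    cropped off.  If ``normalization_id`` is given it must match the
    normalization the model was trained with.
    """
    if normalization_id is not None and normalization_id != model.normalization_id:
        raise ValueError(
            f"volume normalized with {normalization_id!r} but model expects "
            f"{model.normalization_id!r}")
    net = model.network
    cfg = model.config
    if cfg.dims == 2:
        stacker = stack_slices_25d if cfg.in_channels == 12 else stack_slices_2d
        images = stacker(volume)  # (S, H, W, C)
        x = np.moveaxis(images, 3, 1)  # (S, C, H, W)
        factor = 2 ** cfg.depth
        xp, pads = _pad_to_multiple(x, factor)
        chunks = [net.forward(xp[i:i + batch_size], train=False)
                  for i in range(0, xp.shape[0], batch_size)]
        probs = np.concatenate(chunks, axis=0)
        h0, h1 = pads[2][0], pads[2][0] + x.shape[2]
        w0, w1 = pads[3][0], pads[3][0] + x.shape[3]
        probs = probs[:, :, h0:h1, w0:w1]
        return np.ascontiguousarray(np.moveaxis(probs, 0, 3))  # (C, H, W, S)
    x = volume.data[None].astype(np.float32)  # (1, 4, X, Y, Z)
    xp, pads = _pad_to_multiple(x, 2 ** cfg.depth)
    probs = net.forward(xp, train=False)[0]
    slices = tuple(slice(p[0], p[0] + s) for p, s in zip(pads[2:], volume.shape))
    return np.ascontiguousarray(probs[(slice(None),) + slices])
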