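"""Acquisition geometry and channel configuration.

The default constants describe a confocal high-content acquisition of
nano-plankton samples: square 2048-pixel fields of view, 385.62 µm wide,
sampled at 0.188 x 0.188 x 1.090 µm voxels, tiled as a rectangular mosaic
with 10 % overlap in X and Y.  Five channels are recorded per position:
bright field plus four fluorescence channels (DNA, intracellular membranes,
cell surface, chlorophyll autofluorescence).  Only the fluorescence
channels participate in mask construction; the bright-field channel
contributes image features only.

Axis convention: image arrays are indexed ``(x, y, z)`` with ``x`` the
fastest-varying axis in files.  Pixel coordinates are 0-based and regions
are half-open intervals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

#: channel kinds, in the canonical acquisition order
CHANNEL_KINDS = ("bright_field", "dna", "membranes", "surface", "chlorophyll")

#: printed defaults of the acquisition
DEFAULT_VOXEL_XY_UM = 0.188
DEFAULT_VOXEL_Z_UM = 1.090
DEFAULT_FIELD_WIDTH_UM = 385.62
DEFAULT_FRAME_PIXELS = 2048
DEFAULT_OVERLAP_FRACTION = 0.10

#: detection / feature-extraction constants (see detect / features modules)
THRESHOLD_SIGMA_MULTIPLIER = 1.5
THRESHOLD_FLOOR = 1.0
MIN_OBJECT_AREA_UM2 = 12.6
MIN_SUBOBJECT_VOLUME_UM3 = 0.5
N_FEATURES = 480
N_TREES = 500
MIN_SPECIMENS_PER_CATEGORY = 30


@dataclass(frozen=True)
class ChannelRole:
    """One acquisition channel and its role in the pipeline."""

    name: str
    kind: str
    use_for_masking: bool

    def __post_init__(self) -> None:
        if self.kind not in CHANNEL_KINDS:
            raise ValueError(f"unknown channel kind {self.kind!r}")
        if self.use_for_masking == (self.kind == "bright_field"):
            raise ValueError(
                "use_for_masking must be false exactly for the bright-field "
                f"channel (channel {self.name!r}, kind {self.kind!r})"
            )


def default_channels() -> tuple[ChannelRole, ...]:
    return tuple(
        ChannelRole(name=k, kind=k, use_for_masking=(k != "bright_field"))
        for k in CHANNEL_KINDS
    )


@dataclass(frozen=True)
class AcquisitionConfig:
    """Physical acquisition geometry plus the channel layout.

    ``field_width_um`` must agree with ``frame_pixels * voxel_size_xy_um``
    to within 1 %; the slight mismatch in the printed defaults
    (2048 x 0.188 = 385.024 vs 385.62) is within that band.
    """

    voxel_size_xy_um: float = DEFAULT_VOXEL_XY_UM
    voxel_size_z_um: float = DEFAULT_VOXEL_Z_UM
    field_width_um: float = DEFAULT_FIELD_WIDTH_UM
    frame_pixels: int = DEFAULT_FRAME_PIXELS
    overlap_fraction: float = DEFAULT_OVERLAP_FRACTION
    channels: tuple[ChannelRole, ...] = field(default_factory=default_channels)
    z_planes: int = 21

    def __post_init__(self) -> None:
        if self.voxel_size_xy_um <= 0 or self.voxel_size_z_um <= 0:
            raise ValueError("voxel sizes must be positive")
        if not (0 <= self.overlap_fraction < 0.5):
            raise ValueError("overlap_fraction must be in [0, 0.5)")
        if self.z_planes < 1:
            raise ValueError("z_planes must be >= 1")
        expected = self.frame_pixels * self.voxel_size_xy_um
        if abs(self.field_width_um - expected) > 0.01 * self.field_width_um:
            raise ValueError(
                f"field_width_um {self.field_width_um} inconsistent with "
                f"frame_pixels*voxel_size_xy = {expected:.3f} (>1% off)"
            )
        n_bf = sum(c.kind == "bright_field" for c in self.channels)
        if n_bf != 1:
            raise ValueError("exactly one channel must have role bright_field")
        if len({c.name for c in self.channels}) != len(self.channels):
            raise ValueError("channel names must be unique")

    # -- channel helpers -------------------------------------------------
    @property
    def channel_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.channels)

    @property
    def maskable_channels(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.channels if c.use_for_masking)

    @property
    def brightfield_channel(self) -> str:
        return next(c.name for c in self.channels if c.kind == "bright_field")

    # -- physical scaling ------------------------------------------------
    @property
    def pixel_area_um2(self) -> float:
        return self.voxel_size_xy_um**2

    @property
    def voxel_volume_um3(self) -> float:
        return self.voxel_size_xy_um**2 * self.voxel_size_z_um

    def pixels_to_um(self, pix: np.ndarray | Sequence[float]) -> np.ndarray:
        return np.asarray(pix, dtype=float) * self.voxel_size_xy_um

    def um_to_pixels(self, um: np.ndarray | Sequence[float]) -> np.ndarray:
        return np.asarray(um, dtype=float) / self.voxel_size_xy_um

    # -- (de)serialization ----------------------------------------------
    def to_dict(self) -> dict:
        return {
            "voxel_size_xy_um": self.voxel_size_xy_um,
            "voxel_size_z_um": self.voxel_size_z_um,
            "field_width_um": self.field_width_um,
            "frame_pixels": self.frame_pixels,
            "overlap_fraction": self.overlap_fraction,
            "z_planes": self.z_planes,
            "channels": [
                {"name": c.name, "kind": c.kind, "use_for_masking": c.use_for_masking}
                for c in self.channels
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionConfig":
        d = dict(d)
        if "channels" in d:
            d["channels"] = tuple(ChannelRole(**c) for c in d["channels"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "AcquisitionConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)

    def with_frame(self, frame_pixels: int, z_planes: int) -> "AcquisitionConfig":
        """Same optics on a smaller/larger frame (field width follows)."""
        return replace(
            self,
            frame_pixels=frame_pixels,
            field_width_um=frame_pixels * self.voxel_size_xy_um,
            z_planes=z_planes,
        )
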