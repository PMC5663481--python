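"""Domain containers and file I/O.

Stacks are exchanged as multi-page TIFF, one file per channel per field of
view, one page per Z-plane, 8- or 16-bit.  Arrays are held in ``(x, y, z)``
axis order with ``x`` fastest-varying within a file page.  Feature, label
and abundance tables are tab-separated text.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .config import AcquisitionConfig

PROVENANCE_COLUMNS = ("sample", "field_row", "field_col", "object_id")


@dataclass
class VoxelGrid:
    """A single-channel 3D intensity array I(x, y, z) with physical scaling."""

    values: np.ndarray  # shape (nx, ny, nz), non-negative integers
    config: AcquisitionConfig

    def __post_init__(self) -> None:
        if self.values.ndim != 3:
            raise ValueError("VoxelGrid values must be 3D (x, y, z)")
        if not np.issubdtype(self.values.dtype, np.number):
            raise ValueError("intensities must be numeric")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class Projection:
    """A 2D projection P(x, y) of one channel."""

    values: np.ndarray  # shape (nx, ny)
    channel: str


@dataclass
class FieldOfView:
    """Co-registered multi-channel stacks at one mosaic position."""

    channel_grids: dict[str, VoxelGrid]
    mosaic_row: int
    mosaic_col: int
    sample_id: str
    config: AcquisitionConfig

    def __post_init__(self) -> None:
        shapes = {n: g.shape for n, g in self.channel_grids.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channel grids differ in shape: {shapes}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channel_grids.values())).shape


@dataclass
class DetectedObject:
    """A labeled 2D region with its per-channel 3D crop and provenance.

    ``mask2d`` is the object's footprint restricted to its bounding box;
    ``crops`` are per-channel ``(x, y, z)`` sub-stacks over the same
    bounding box (full Z range), with voxels outside the footprint zeroed.
    Bounding box is a half-open pixel rectangle ``(x0, y0, x1, y1)``.
    """

    label: int
    mask2d: np.ndarray
    bbox: tuple[int, int, int, int]
    centroid_px: tuple[float, float]  # (x, y) within the field
    area_um2: float
    crops: dict[str, np.ndarray]
    config: AcquisitionConfig
    sample_id: str = ""
    mosaic_row: int = 0
    mosaic_col: int = 0


# ---------------------------------------------------------------------------
# stack I/O


def field_stack_name(sample: str, row: int, col: int, channel: str) -> str:
    """Canonical layout: one stack file per channel per field."""
    return f"{sample}_{row}_{col}_{channel}.tif"


def write_field(fov: FieldOfView, directory: str | Path) -> list[Path]:
    """Write one multi-page TIFF per channel; pages are Z-planes (y, x)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, grid in fov.channel_grids.items():
        path = directory / field_stack_name(
            fov.sample_id, fov.mosaic_row, fov.mosaic_col, name
        )
        # (x, y, z) -> pages (z, y, x): x fastest-varying within a page row
        pages = np.ascontiguousarray(grid.values.transpose(2, 1, 0))
        tifffile.imwrite(path, pages, photometric="minisblack")
        paths.append(path)
    return paths


def read_field(
    paths: Mapping[str, str | Path],
    config: AcquisitionConfig,
    sample_id: str = "",
    mosaic_row: int = 0,
    mosaic_col: int = 0,
) -> FieldOfView:
    """Read per-channel multi-page TIFF stacks into a FieldOfView.

    ``paths`` maps channel name to file location; channel order follows the
    configuration.  All channels must agree in XY size and Z-plane count.
    """
    missing = [c for c in config.channel_names if c not in paths]
    if missing:
        raise ValueError(f"missing stack paths for channels: {missing}")
    grids: dict[str, VoxelGrid] = {}
    ref_shape: tuple[int, int, int] | None = None
    ref_channel = ""
    for name in config.channel_names:
        pages = tifffile.imread(paths[name])
        if pages.ndim == 2:  # single page
            pages = pages[None]
        if pages.dtype not in (np.uint8, np.uint16):
            raise ValueError(
                f"channel {name!r}: expected 8- or 16-bit data, got {pages.dtype}"
            )
        values = pages.transpose(2, 1, 0)  # (z, y, x) -> (x, y, z)
        if ref_shape is None:
            ref_shape, ref_channel = values.shape, name
        elif values.shape != ref_shape:
            raise ValueError(
                f"channel {name!r} has shape {values.shape}, expected "
                f"{ref_shape} (as in channel {ref_channel!r})"
            )
        grids[name] = VoxelGrid(values=values, config=config)
    return FieldOfView(
        channel_grids=grids,
        mosaic_row=mosaic_row,
        mosaic_col=mosaic_col,
        sample_id=sample_id,
        config=config,
    )


# ---------------------------------------------------------------------------
# feature tables


def write_feature_table(records: Sequence, destination: str | Path) -> Path:
    """Write FeatureVector records as TSV: provenance columns + 480 names.

    All records must share a catalog version; values round-trip at 12
    significant digits.  An empty record list yields a header-only file
    using the default catalog.
    """
    from .features import default_catalog

    destination = Path(destination)
    if records:
        versions = {r.catalog_version for r in records}
        if len(versions) > 1:
            raise ValueError(f"mixed catalog versions: {sorted(versions)}")
        names = list(records[0].names)
    else:
        names = list(default_catalog().names)
    rows = []
    for r in records:
        rows.append(
            {
                "sample": r.sample_id,
                "field_row": r.mosaic_row,
                "field_col": r.mosaic_col,
                "object_id": r.object_id,
                **dict(zip(names, r.values)),
            }
        )
    df = pd.DataFrame(rows, columns=list(PROVENANCE_COLUMNS) + names)
    df.to_csv(destination, sep="\t", index=False, float_format="%.12g")
    return destination


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature TSV; feature columns are everything after provenance."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PROVENANCE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"feature table missing provenance columns: {missing}")
    return df


def feature_matrix(df: pd.DataFrame) -> np.ndarray:
    """The numeric feature block of a feature table, in catalog order."""
    cols = [c for c in df.columns if c not in PROVENANCE_COLUMNS]
    return df[cols].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# label tables


@dataclass
class LabelTable:
    """Curated object labels: object id -> 4-level category path."""

    frame: pd.DataFrame = dc_field(default_factory=pd.DataFrame)

    COLUMNS = ("object_id", "level1", "level2", "level3", "level4")

    def __post_init__(self) -> None:
        if self.frame.empty:
            self.frame = pd.DataFrame(columns=list(self.COLUMNS))
        missing = [c for c in self.COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"label table missing columns: {missing}")
        if self.frame["object_id"].duplicated().any():
            dups = self.frame.loc[self.frame["object_id"].duplicated(), "object_id"]
            raise ValueError(f"duplicate object ids in label table: {list(dups)[:5]}")

    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "LabelTable":
        return cls(pd.DataFrame(records, columns=list(cls.COLUMNS)))

    @classmethod
    def read(cls, path: str | Path) -> "LabelTable":
        return cls(pd.read_csv(path, sep="\t"))

    def write(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    def leaf_counts(self) -> pd.Series:
        return self.frame.groupby("level4").size()
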