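"""Mosaic geometry and duplicate removal across overlapping fields.

Fields tile the sample as a rectangular mosaic with a fixed fractional
overlap between neighbors, so a cell near a field edge is imaged (and
detected) in up to four fields.  Each object is assigned to exactly one
*canonical* field: the field whose *core* region contains its global
centroid.  A field's core is its rectangle shrunk by half the overlap
width on every edge shared with a neighbor (edges on the mosaic boundary
are not shrunk), so the cores tile the mosaic exactly.  Detections whose
detection field is not their canonical field are discarded; survivors are
renumbered sequentially per sample.

Coordinates: 2D points are ``(u, v)`` in µm, ``u`` along mosaic rows,
``v`` along columns; the origin of field (r, c) is
``(r * spacing, c * spacing)`` with ``spacing = field_extent * (1 -
overlap_fraction)``.  A centroid exactly on a core boundary belongs to
the field with the smaller (row, col) in row-major order; cores are
open-left/closed-right intervals (first field closed at the mosaic edge),
which realizes that tie-break deterministically in floating point.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .config import AcquisitionConfig
from .io import DetectedObject


@dataclass(frozen=True)
class MosaicLayout:
    """Rectangular mosaic of overlapping square fields."""

    rows: int
    cols: int
    field_extent_um: float
    overlap_fraction: float

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("mosaic must have at least one field")
        if not 0 <= self.overlap_fraction < 0.5:
            raise ValueError("overlap_fraction must be in [0, 0.5)")

    @classmethod
    def from_config(cls, config: AcquisitionConfig, rows: int, cols: int) -> "MosaicLayout":
        return cls(
            rows=rows,
            cols=cols,
            field_extent_um=config.field_width_um,
            overlap_fraction=config.overlap_fraction,
        )

    @property
    def spacing_um(self) -> float:
        return self.field_extent_um * (1.0 - self.overlap_fraction)

    @property
    def overlap_width_um(self) -> float:
        return self.field_extent_um - self.spacing_um

    def origin(self, row: int, col: int) -> tuple[float, float]:
        self._check_indices(row, col)
        return (row * self.spacing_um, col * self.spacing_um)

    @property
    def extent_um(self) -> tuple[float, float]:
        """Total mosaic extent (u, v) in µm."""
        return (
            (self.rows - 1) * self.spacing_um + self.field_extent_um,
            (self.cols - 1) * self.spacing_um + self.field_extent_um,
        )

    def core_interval(self, index: int, count: int) -> tuple[float, float]:
        """Core interval of field ``index`` along one axis of ``count`` fields.

        Half-open in the exclusive-left sense: a coordinate equal to the
        right endpoint belongs to this field (boundary -> smaller index).
        """
        half = self.overlap_width_um / 2.0
        lo = index * self.spacing_um
        hi = lo + self.field_extent_um
        if index > 0:
            lo += half
        if index < count - 1:
            hi -= half
        return lo, hi

    def canonical_index(self, coord: float, count: int) -> int:
        """Field index owning ``coord`` along one axis (cores tile the axis)."""
        for k in range(count):
            lo, hi = self.core_interval(k, count)
            if (coord >= lo if k == 0 else coord > lo) and coord <= hi:
                return k
        raise ValueError(f"coordinate {coord} µm outside the mosaic extent")

    def canonical_field(self, point_um: Sequence[float]) -> tuple[int, int]:
        u, v = float(point_um[0]), float(point_um[1])
        return (self.canonical_index(u, self.rows), self.canonical_index(v, self.cols))

    def _check_indices(self, row: int, col: int) -> None:
        if not (0 <= row < self.rows and 0 <= col < self.cols):
            raise ValueError(
                f"field ({row}, {col}) outside {self.rows}x{self.cols} mosaic"
            )


def to_global(
    field_pos: tuple[int, int],
    local_um: Sequence[float],
    layout: MosaicLayout,
) -> tuple[float, float]:
    """Field-local (u, v) µm -> global mosaic coordinates."""
    ou, ov = layout.origin(*field_pos)
    return (ou + float(local_um[0]), ov + float(local_um[1]))


def to_local(
    field_pos: tuple[int, int],
    global_um: Sequence[float],
    layout: MosaicLayout,
) -> tuple[float, float]:
    """Exact inverse of :func:`to_global`."""
    ou, ov = layout.origin(*field_pos)
    return (float(global_um[0]) - ou, float(global_um[1]) - ov)


@dataclass
class CanonicalAssignment:
    """One retained detection with its owning field and global centroid."""

    obj: DetectedObject
    canonical_field: tuple[int, int]
    global_centroid_um: tuple[float, float]
    object_id: int = 0  # sequential id, set by dedup_counts


def detection_global_centroid(
    obj: DetectedObject, layout: MosaicLayout
) -> tuple[float, float]:
    """Global (u, v) µm centroid of a detection.

    The detection centroid is (x, y) in field pixels; within a field the
    row axis u corresponds to y and the column axis v to x.
    """
    cx, cy = obj.centroid_px
    vxy = obj.config.voxel_size_xy_um
    return to_global((obj.mosaic_row, obj.mosaic_col), (cy * vxy, cx * vxy), layout)


def assign_canonical(
    objects: Sequence[DetectedObject], layout: MosaicLayout
) -> list[CanonicalAssignment]:
    """Keep each detection only in its canonical field.

    A detection made in a non-canonical field is a duplicate of (or a
    truncated view of) an object owned by a neighboring field and is
    discarded.
    """
    kept = []
    for obj in objects:
        g = detection_global_centroid(obj, layout)
        canon = layout.canonical_field(g)
        if canon == (obj.mosaic_row, obj.mosaic_col):
            kept.append(
                CanonicalAssignment(obj=obj, canonical_field=canon, global_centroid_um=g)
            )
    return kept


def dedup_counts(assignments: Sequence[CanonicalAssignment]) -> list[CanonicalAssignment]:
    """Sample registry: each physical object once, renumbered 1..K.

    Ordering is deterministic: sorted by (row, col, source label), so the
    result does not depend on the order fields were processed in.
    """
    ordered = sorted(
        assignments,
        key=lambda a: (a.canonical_field[0], a.canonical_field[1], a.obj.label),
    )
    for i, a in enumerate(ordered, start=1):
        a.object_id = i
    return ordered


def write_registry(
    assignments: Sequence[CanonicalAssignment], path: str | Path
) -> Path:
    """Registry TSV: sequential id, sample, canonical field, global centroid,
    source label."""
    rows = [
        {
            "object_id": a.object_id,
            "sample": a.obj.sample_id,
            "field_row": a.canonical_field[0],
            "field_col": a.canonical_field[1],
            "centroid_u_um": a.global_centroid_um[0],
            "centroid_v_um": a.global_centroid_um[1],
            "source_label": a.obj.label,
        }
        for a in assignments
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "object_id", "sample", "field_row", "field_col",
            "centroid_u_um", "centroid_v_um", "source_label",
        ],
    )
    df.to_csv(path, sep="\t", index=False)
    return Path(path)
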