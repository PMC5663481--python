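"""Object detection within one field of view.

The detection strategy is built for sparse fluorescence stacks:

1. *Background estimation* — per fluorescence channel, the mean and
   (population) standard deviation of all voxel intensities over all
   fields of a sample; the detection threshold is ``mean + 1.5 * std``
   with a floor of 1 intensity unit.  The mean-based rule is deliberately
   permissive: variance-partitioning thresholds such as Otsu's method
   under-detect when foreground occupies a tiny fraction of the image.
2. *Almost-max projection* — each Z-column is reduced to its
   second-highest value, a robust variant of max projection that
   suppresses single-voxel noise spikes (e.g. detector shot events).
3. *Masking* — the projection is median filtered (3x3, reflected edges)
   and thresholded; per-channel masks are OR-combined; binary opening and
   closing with the 4-connected cross structuring element, then hole
   filling; 4-connected labeling.
4. *Filtering* — objects smaller than 12.6 µm² in projected area and
   objects touching any of the four field borders are removed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage.filters import threshold_otsu

from .config import (
    AcquisitionConfig,
    MIN_OBJECT_AREA_UM2,
    THRESHOLD_FLOOR,
    THRESHOLD_SIGMA_MULTIPLIER,
)
from .io import DetectedObject, FieldOfView, Projection, VoxelGrid

#: 3x3 cross (4-connected) structuring element, also labeling connectivity
CROSS = ndimage.generate_binary_structure(2, 1)


@dataclass(frozen=True)
class BackgroundModel:
    """Per-channel background statistics and detection thresholds.

    Thresholds exist only for maskable (fluorescence) channels; the
    bright-field channel is never thresholded for mask construction.
    """

    mean: dict[str, float]
    std: dict[str, float]
    threshold: dict[str, float]

    def __post_init__(self) -> None:
        for ch, thr in self.threshold.items():
            expected = max(
                self.mean[ch] + THRESHOLD_SIGMA_MULTIPLIER * self.std[ch],
                THRESHOLD_FLOOR,
            )
            if not np.isclose(thr, expected):
                raise ValueError(f"threshold for {ch!r} violates the 1.5-sigma rule")


@dataclass
class ObjectMask2D:
    """One labeled 2D region within a field."""

    label: int
    pixels: np.ndarray  # (n, 2) array of (x, y) coordinates
    area_um2: float
    bbox: tuple[int, int, int, int]  # half-open (x0, y0, x1, y1)
    centroid: tuple[float, float]  # (x, y) pixel coordinates


def estimate_background(
    fields: Sequence[FieldOfView], config: AcquisitionConfig
) -> BackgroundModel:
    """Population mean/std of all voxels of all fields, per maskable channel.

    Statistics are pooled over every supplied field before any per-field
    processing, so downstream detection is embarrassingly parallel.
    """
    if len(fields) == 0:
        raise ValueError("background estimation requires at least one field")
    channels = config.maskable_channels
    n = dict.fromkeys(channels, 0)
    s = dict.fromkeys(channels, 0.0)
    ss = dict.fromkeys(channels, 0.0)
    for fov in fields:
        for ch in channels:
            v = fov.channel_grids[ch].values.astype(np.float64, copy=False)
            n[ch] += v.size
            s[ch] += float(v.sum())
            ss[ch] += float(np.square(v).sum())
    mean = {ch: s[ch] / n[ch] for ch in channels}
    std = {ch: float(np.sqrt(max(ss[ch] / n[ch] - mean[ch] ** 2, 0.0))) for ch in channels}
    threshold = {
        ch: max(mean[ch] + THRESHOLD_SIGMA_MULTIPLIER * std[ch], THRESHOLD_FLOOR)
        for ch in channels
    }
    return BackgroundModel(mean=mean, std=std, threshold=threshold)


def almost_max_project(grid: VoxelGrid | np.ndarray, channel: str = "") -> Projection:
    """Second-highest value of each Z-column: robust 'almost-max' projection."""
    values = grid.values if isinstance(grid, VoxelGrid) else np.asarray(grid)
    nz = values.shape[2]
    if nz < 2:
        raise ValueError("almost-max projection needs at least 2 Z-planes")
    # second-highest == order statistic at index nz-2 of ascending partition
    proj = np.partition(values, nz - 2, axis=2)[:, :, nz - 2]
    return Projection(values=proj, channel=channel)


def median_filter_2d(values: np.ndarray) -> np.ndarray:
    """3x3 median filter, edges by reflection."""
    return ndimage.median_filter(values, size=3, mode="reflect")


def make_channel_mask(projection: Projection, threshold: float) -> np.ndarray:
    """Median filter then threshold (strictly greater) one projection."""
    return median_filter_2d(projection.values) > threshold


def combined_mask(
    field: FieldOfView, thresholds: Mapping[str, float], config: AcquisitionConfig
) -> np.ndarray:
    """OR of per-channel masks, then open/close (4-connected cross) and
    hole filling."""
    mask = np.zeros(field.shape[:2], dtype=bool)
    for ch in config.maskable_channels:
        proj = almost_max_project(field.channel_grids[ch], channel=ch)
        mask |= make_channel_mask(proj, thresholds[ch])
    # erosions treat out-of-bounds as foreground so border-touching objects
    # are not shaved off the border (they must remain for the border filter)
    mask = ndimage.binary_erosion(mask, structure=CROSS, border_value=1)
    mask = ndimage.binary_dilation(mask, structure=CROSS)  # open
    mask = ndimage.binary_dilation(mask, structure=CROSS)
    mask = ndimage.binary_erosion(mask, structure=CROSS, border_value=1)  # close
    mask = ndimage.binary_fill_holes(mask, structure=CROSS)
    return mask


def identify_objects(
    field: FieldOfView,
    background: BackgroundModel | Mapping[str, float],
    config: AcquisitionConfig,
    min_area_um2: float = MIN_OBJECT_AREA_UM2,
) -> list[ObjectMask2D]:
    """Label the combined mask and apply size and border filters.

    ``background`` may be a BackgroundModel or a plain channel->threshold
    mapping (used by the Otsu comparison variant).  Objects with projected
    area strictly below ``min_area_um2`` and objects touching any of the
    four field borders are removed.  Remaining objects are relabeled
    1..K in raster order.
    """
    thresholds = (
        background.threshold if isinstance(background, BackgroundModel) else background
    )
    mask = combined_mask(field, thresholds, config)
    labels, n = ndimage.label(mask, structure=CROSS)
    if n == 0:
        return []
    nx, ny = mask.shape
    border = np.zeros_like(mask)
    border[0, :] = border[-1, :] = True
    border[:, 0] = border[:, -1] = True
    border_labels = set(np.unique(labels[border])) - {0}

    objects: list[ObjectMask2D] = []
    next_label = 1
    slices = ndimage.find_objects(labels)
    for lab, slc in enumerate(slices, start=1):
        if slc is None or lab in border_labels:
            continue
        region = labels[slc] == lab
        area = float(region.sum()) * config.pixel_area_um2
        if area < min_area_um2:
            continue
        xs, ys = np.nonzero(region)
        x0, y0 = slc[0].start, slc[1].start
        pixels = np.column_stack([xs + x0, ys + y0])
        centroid = (float(xs.mean() + x0), float(ys.mean() + y0))
        objects.append(
            ObjectMask2D(
                label=next_label,
                pixels=pixels,
                area_um2=area,
                bbox=(x0, y0, slc[0].stop, slc[1].stop),
                centroid=centroid,
            )
        )
        next_label += 1
    return objects


def otsu_thresholds(field: FieldOfView, config: AcquisitionConfig) -> dict[str, float]:
    """Per-channel Otsu thresholds on the median-filtered projections.

    Comparison variant only: partitions the projection histogram by
    maximizing between-class variance.
    """
    out = {}
    for ch in config.maskable_channels:
        proj = almost_max_project(field.channel_grids[ch], channel=ch)
        filtered = median_filter_2d(proj.values)
        out[ch] = float(threshold_otsu(filtered.ravel()))
    return out


def extract_objects(
    field: FieldOfView, masks: Sequence[ObjectMask2D]
) -> list[DetectedObject]:
    """Attach per-channel 3D crops (bounding box, footprint-masked) to
    detected regions."""
    out = []
    for m in masks:
        x0, y0, x1, y1 = m.bbox
        footprint = np.zeros((x1 - x0, y1 - y0), dtype=bool)
        footprint[m.pixels[:, 0] - x0, m.pixels[:, 1] - y0] = True
        crops = {}
        for ch, grid in field.channel_grids.items():
            crop = grid.values[x0:x1, y0:y1, :].copy()
            crop[~footprint, :] = 0
            crops[ch] = crop
        out.append(
            DetectedObject(
                label=m.label,
                mask2d=footprint,
                bbox=m.bbox,
                centroid_px=m.centroid,
                area_um2=m.area_um2,
                crops=crops,
                config=field.config,
                sample_id=field.sample_id,
                mosaic_row=field.mosaic_row,
                mosaic_col=field.mosaic_col,
            )
        )
    return out


def make_vignette(obj: DetectedObject) -> dict[str, np.ndarray]:
    """Per-channel almost-max projections of the object crop,
    contrast-stretched to the 1st-99th intensity percentiles."""
    out = {}
    for ch, crop in obj.crops.items():
        proj = almost_max_project(crop, channel=ch).values.astype(float)
        lo, hi = np.percentile(proj, [1.0, 99.0])
        if hi > lo:
            proj = np.clip((proj - lo) / (hi - lo), 0.0, 1.0)
        else:
            proj = np.zeros_like(proj)
        out[ch] = proj
    return out


def object_projections(obj: DetectedObject) -> dict[str, np.ndarray]:
    """Raw (unstretched) per-channel almost-max projections of the crop."""
    return {
        ch: almost_max_project(crop, channel=ch).values.astype(float)
        for ch, crop in obj.crops.items()
    }


# ---------------------------------------------------------------------------
# per-field outputs


def write_detections(
    field: FieldOfView,
    masks: Sequence[ObjectMask2D],
    directory: str | Path,
) -> tuple[Path, Path]:
    """Emit a 16-bit label image (TIFF) and an object index TSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = f"{field.sample_id}_{field.mosaic_row}_{field.mosaic_col}"
    nx, ny = field.shape[:2]
    label_img = np.zeros((nx, ny), dtype=np.uint16)
    rows = []
    for m in masks:
        label_img[m.pixels[:, 0], m.pixels[:, 1]] = m.label
        rows.append(
            {
                "label": m.label,
                "centroid_x_px": m.centroid[0],
                "centroid_y_px": m.centroid[1],
                "area_um2": m.area_um2,
                "bbox_x0": m.bbox[0],
                "bbox_y0": m.bbox[1],
                "bbox_x1": m.bbox[2],
                "bbox_y1": m.bbox[3],
            }
        )
    tif_path = directory / f"{stem}_labels.tif"
    tifffile.imwrite(tif_path, np.ascontiguousarray(label_img.T))
    tsv_path = directory / f"{stem}_objects.tsv"
    pd.DataFrame(
        rows,
        columns=[
            "label", "centroid_x_px", "centroid_y_px", "area_um2",
            "bbox_x0", "bbox_y0", "bbox_x1", "bbox_y1",
        ],
    ).to_csv(tsv_path, sep="\t", index=False)
    return tif_path, tsv_path
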