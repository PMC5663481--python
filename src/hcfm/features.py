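"""Per-object 3D sub-segmentation and the 480-descriptor feature catalog.

Each detected object is described by exactly 480 numeric descriptors,
organized in a versioned catalog:

* per channel (5 channels x 85): 13 Haralick direction-means + 13
  direction-ranges, uniform-LBP histograms (10 + 14 bins), 25 Zernike
  magnitudes to degree 8, and 10 intensity statistics — all on the
  almost-max projection within the object mask;
* 20 morphological descriptors of the combined 2D mask;
* per fluorescence channel (4 x 5): 3D biovolume and sub-object volume
  statistics;
* 12 pairwise fluorescence-channel 3D overlap descriptors (Jaccard and
  smaller-fraction overlap for the 6 channel pairs);
* 3 global 3D bounding-box extents in µm.

Sub-objects (nuclei, chloroplasts, ...) are 6-connected 3D components of
the 3x3x3-median-filtered crop thresholded at the channel's global
background threshold; components smaller than 0.5 µm³ are removed.

Degenerate descriptor values are 0 by convention — a feature vector
never contains NaN or infinity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import kurtosis, skew
from skimage.measure import label as sk_label
from skimage.measure import moments_hu, regionprops

from .config import (
    AcquisitionConfig,
    CHANNEL_KINDS,
    MIN_SUBOBJECT_VOLUME_UM3,
    N_FEATURES,
)
from .detect import BackgroundModel, object_projections
from .io import DetectedObject
from .texture import (
    HARALICK_NAMES,
    LBP_CONFIGS,
    feret_diameters,
    haralick_features,
    lbp_histograms,
    zernike_indices,
    zernike_magnitudes,
)

CATALOG_VERSION = "hcfm-480-v1"

FLUOR_KINDS = tuple(k for k in CHANNEL_KINDS if k != "bright_field")

INTENSITY_STATS = (
    "min", "max", "mean", "std", "median", "mad",
    "skewness", "kurtosis", "integrated", "frac_above_threshold",
)

MORPHOLOGY_NAMES = (
    "area_um2", "perimeter_um", "convex_area_um2", "solidity", "eccentricity",
    "major_axis_um", "minor_axis_um", "aspect_ratio", "equivalent_diameter_um",
    "circularity", "extent", "euler_number", "hole_count",
    "feret_max_um", "feret_min_um", "hu1", "hu2", "hu3", "hu4", "roundness",
)

SUBOBJECT_STATS = (
    "biovolume_um3", "subobject_count", "subobject_total_volume_um3",
    "subobject_max_volume_um3", "subobject_mean_volume_um3",
)

#: structuring element for 6-connected 3D labeling
CUBE6 = ndimage.generate_binary_structure(3, 1)

_LINEAR_INTENSITY = {"min", "max", "mean", "std", "median", "mad", "integrated"}


@dataclass(frozen=True)
class CatalogEntry:
    name: str
    group: str
    channel: str  # channel name, "combined", or "a+b" for overlap pairs
    scale_behavior: str  # response to positive intensity scaling


@dataclass(frozen=True)
class FeatureCatalog:
    """Frozen, versioned list of the 480 descriptor definitions."""

    version: str
    entries: tuple[CatalogEntry, ...]

    def __post_init__(self) -> None:
        if len(self.entries) != N_FEATURES:
            raise ValueError(f"catalog must have {N_FEATURES} entries, got {len(self.entries)}")
        if len({e.name for e in self.entries}) != len(self.entries):
            raise ValueError("catalog names must be unique")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(e.name for e in self.entries)

    def indices_for_channel(self, channel: str) -> np.ndarray:
        return np.array([i for i, e in enumerate(self.entries) if e.channel == channel])

    def group_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for e in self.entries:
            counts[e.group] = counts.get(e.group, 0) + 1
        return counts

    def write_manifest(self, path: str | Path) -> Path:
        df = pd.DataFrame(
            [(e.name, e.group, e.channel, e.scale_behavior) for e in self.entries],
            columns=["name", "group", "channel", "scale_behavior"],
        )
        df.insert(0, "version", self.version)
        df.to_csv(path, sep="\t", index=False)
        return Path(path)


@lru_cache(maxsize=None)
def default_catalog(channels: tuple[str, ...] = CHANNEL_KINDS) -> FeatureCatalog:
    """The canonical 480-entry catalog for the 5-channel acquisition."""
    entries: list[CatalogEntry] = []
    for ch in channels:
        for stat in HARALICK_NAMES:
            entries.append(CatalogEntry(f"{ch}.haralick_{stat}_mean", "haralick", ch, "invariant"))
        for stat in HARALICK_NAMES:
            entries.append(CatalogEntry(f"{ch}.haralick_{stat}_range", "haralick", ch, "invariant"))
        for radius, points in LBP_CONFIGS:
            for b in range(points + 2):
                entries.append(
                    CatalogEntry(f"{ch}.lbp_r{radius}p{points}_b{b}", "lbp", ch, "invariant")
                )
        for n, m in zernike_indices():
            entries.append(CatalogEntry(f"{ch}.zernike_n{n}m{m}", "zernike", ch, "invariant"))
        for stat in INTENSITY_STATS:
            behavior = (
                "linear" if stat in _LINEAR_INTENSITY
                else "threshold-dependent" if stat == "frac_above_threshold"
                else "invariant"
            )
            entries.append(CatalogEntry(f"{ch}.intensity_{stat}", "intensity", ch, behavior))
    for name in MORPHOLOGY_NAMES:
        entries.append(CatalogEntry(f"mask.{name}", "morphology2d", "combined", "invariant"))
    fluor = tuple(ch for ch in channels if ch != "bright_field")
    for ch in fluor:
        for stat in SUBOBJECT_STATS:
            entries.append(CatalogEntry(f"{ch}.{stat}", "biovolume3d", ch, "invariant"))
    for a, b in combinations(fluor, 2):
        entries.append(CatalogEntry(f"overlap.{a}_{b}.jaccard", "overlap3d", f"{a}+{b}", "invariant"))
        entries.append(
            CatalogEntry(f"overlap.{a}_{b}.min_fraction", "overlap3d", f"{a}+{b}", "invariant")
        )
    for axis in ("x", "y", "z"):
        entries.append(CatalogEntry(f"geom3d.extent_{axis}_um", "geometry3d", "combined", "invariant"))
    return FeatureCatalog(version=CATALOG_VERSION, entries=tuple(entries))


def feature_names(catalog: FeatureCatalog | None = None) -> tuple[str, ...]:
    return (catalog or default_catalog()).names


def brightfield_feature_indices(
    catalog: FeatureCatalog | None = None, channel: str = "bright_field"
) -> np.ndarray:
    """Indices of descriptors derived solely from the bright-field channel."""
    return (catalog or default_catalog()).indices_for_channel(channel)


# ---------------------------------------------------------------------------
# sub-segmentation


@dataclass
class SubObject:
    """A 6-connected 3D component of one channel inside one object."""

    channel: str
    voxels: np.ndarray  # (n, 3) crop-local (x, y, z) coordinates
    volume_um3: float


def thresholded_volumes(
    obj: DetectedObject, background: BackgroundModel
) -> dict[str, np.ndarray]:
    """Per fluorescence channel: 3x3x3-median-filtered crop > global
    threshold."""
    out = {}
    for ch, thr in background.threshold.items():
        med = ndimage.median_filter(obj.crops[ch], size=3, mode="reflect")
        out[ch] = med > thr
    return out


def subsegment_3d(
    obj: DetectedObject,
    background: BackgroundModel,
    config: AcquisitionConfig | None = None,
    min_volume_um3: float = MIN_SUBOBJECT_VOLUME_UM3,
    volumes: Mapping[str, np.ndarray] | None = None,
) -> list[SubObject]:
    """3D components per fluorescence channel; drop those below 0.5 µm³."""
    config = config or obj.config
    vox = config.voxel_volume_um3
    volumes = volumes if volumes is not None else thresholded_volumes(obj, background)
    subs: list[SubObject] = []
    for ch, mask in volumes.items():
        labels, n = ndimage.label(mask, structure=CUBE6)
        if n == 0:
            continue
        for lab, slc in enumerate(ndimage.find_objects(labels), start=1):
            if slc is None:
                continue
            component = labels[slc] == lab
            volume = float(component.sum()) * vox
            if volume < min_volume_um3:
                continue
            offset = np.array([s.start for s in slc])
            coords = np.column_stack(np.nonzero(component)) + offset
            subs.append(SubObject(channel=ch, voxels=coords, volume_um3=volume))
    return subs


# ---------------------------------------------------------------------------
# feature computation


@dataclass
class FeatureVector:
    """The ordered 480-descriptor record for one object."""

    values: np.ndarray
    names: tuple[str, ...]
    catalog_version: str
    sample_id: str = ""
    mosaic_row: int = 0
    mosaic_col: int = 0
    object_id: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.names),):
            raise ValueError("feature values must match catalog length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector contains non-finite values")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values))


def _intensity_stats(values: np.ndarray, threshold: float | None) -> list[float]:
    if values.size == 0:
        return [0.0] * len(INTENSITY_STATS)
    v = values.astype(float)
    med = float(np.median(v))
    constant = v.max() == v.min()
    return [
        float(v.min()),
        float(v.max()),
        float(v.mean()),
        float(v.std()),
        med,
        float(np.median(np.abs(v - med))),
        0.0 if constant else float(skew(v)),
        0.0 if constant else float(kurtosis(v)),
        float(v.sum()),
        float((v > threshold).mean()) if threshold is not None else 0.0,
    ]


def _morphology(mask: np.ndarray, pixel_um: float) -> list[float]:
    labeled = sk_label(mask, connectivity=1)
    props = regionprops(labeled)
    if not props:
        return [0.0] * len(MORPHOLOGY_NAMES)
    r = max(props, key=lambda p: p.area)
    area = float(r.area) * pixel_um**2
    perimeter = float(r.perimeter) * pixel_um
    convex_area = float(r.area_convex) * pixel_um**2
    major = float(r.axis_major_length) * pixel_um
    minor = float(r.axis_minor_length) * pixel_um
    euler = float(r.euler_number)
    fmax_px, fmin_px = feret_diameters(mask)
    hu = moments_hu(mask.astype(float))[:4]
    return [
        area,
        perimeter,
        convex_area,
        float(r.solidity),
        float(r.eccentricity),
        major,
        minor,
        major / minor if minor > 0 else 0.0,
        float(r.equivalent_diameter_area) * pixel_um,
        4.0 * np.pi * area / perimeter**2 if perimeter > 0 else 0.0,
        float(r.extent),
        euler,
        float(max(0, 1 - int(euler))),
        fmax_px * pixel_um,
        fmin_px * pixel_um,
        float(hu[0]), float(hu[1]), float(hu[2]), float(hu[3]),
        4.0 * area / (np.pi * major**2) if major > 0 else 0.0,
    ]


def compute_features(
    obj: DetectedObject,
    sub_objects: Sequence[SubObject],
    catalog: FeatureCatalog | None = None,
    background: BackgroundModel | None = None,
    volumes: Mapping[str, np.ndarray] | None = None,
) -> FeatureVector:
    """Compute the full catalog for one object, in catalog order.

    2D descriptors are computed on the per-channel almost-max projections
    of the object crop, within the object mask; 3D descriptors come from
    the thresholded channel volumes and the retained sub-objects.
    """
    catalog = catalog or default_catalog()
    if catalog.version != CATALOG_VERSION:
        raise ValueError(
            f"catalog version mismatch: {catalog.version!r} != {CATALOG_VERSION!r}"
        )
    config = obj.config
    mask = obj.mask2d
    projections = object_projections(obj)
    thresholds = background.threshold if background is not None else {}
    if volumes is None:
        if background is None:
            raise ValueError("either volumes or background must be supplied")
        volumes = thresholded_volumes(obj, background)

    values: list[float] = []
    for ch in config.channel_names:
        proj = projections[ch]
        means, ranges = haralick_features(proj, mask)
        values.extend(means)
        values.extend(ranges)
        values.extend(lbp_histograms(proj, mask))
        values.extend(zernike_magnitudes(proj * mask, mask))
        values.extend(_intensity_stats(proj[mask], thresholds.get(ch)))

    values.extend(_morphology(mask, config.voxel_size_xy_um))

    vox = config.voxel_volume_um3
    fluor = [c for c in config.channel_names if c != config.brightfield_channel]
    subs_by_channel: dict[str, list[SubObject]] = {ch: [] for ch in fluor}
    for s in sub_objects:
        subs_by_channel.setdefault(s.channel, []).append(s)
    for ch in fluor:
        vols = np.array([s.volume_um3 for s in subs_by_channel[ch]])
        biovolume = float(volumes[ch].sum()) * vox
        values.extend(
            [
                biovolume,
                float(len(vols)),
                float(vols.sum()) if len(vols) else 0.0,
                float(vols.max()) if len(vols) else 0.0,
                float(vols.mean()) if len(vols) else 0.0,
            ]
        )

    for a, b in combinations(fluor, 2):
        va, vb = volumes[a], volumes[b]
        inter = float(np.logical_and(va, vb).sum())
        union = float(np.logical_or(va, vb).sum())
        smaller = float(min(va.sum(), vb.sum()))
        values.append(inter / union if union > 0 else 0.0)
        values.append(inter / smaller if smaller > 0 else 0.0)

    any_fluor = np.zeros(obj.crops[fluor[0]].shape, dtype=bool)
    for ch in fluor:
        any_fluor |= volumes[ch]
    if any_fluor.any():
        xs, ys, zs = np.nonzero(any_fluor)
        values.extend(
            [
                float(xs.max() - xs.min() + 1) * config.voxel_size_xy_um,
                float(ys.max() - ys.min() + 1) * config.voxel_size_xy_um,
                float(zs.max() - zs.min() + 1) * config.voxel_size_z_um,
            ]
        )
    else:
        values.extend([0.0, 0.0, 0.0])

    arr = np.nan_to_num(np.asarray(values, dtype=float), nan=0.0, posinf=0.0, neginf=0.0)
    return FeatureVector(
        values=arr,
        names=catalog.names,
        catalog_version=catalog.version,
        sample_id=obj.sample_id,
        mosaic_row=obj.mosaic_row,
        mosaic_col=obj.mosaic_col,
        object_id=obj.label,
    )


def featurize(
    obj: DetectedObject,
    background: BackgroundModel,
    catalog: FeatureCatalog | None = None,
) -> FeatureVector:
    """Sub-segment then compute the full feature vector for one object."""
    volumes = thresholded_volumes(obj, background)
    subs = subsegment_3d(obj, background, volumes=volumes)
    return compute_features(
        obj, subs, catalog=catalog, background=background, volumes=volumes
    )
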