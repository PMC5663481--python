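"""Ground-truthed synthetic scene generation.

Renders mosaics of multi-channel Z-stacks that emulate the acquisition:
fluorescent cell-like objects over Gaussian (optionally spike-contaminated)
background noise, cut into overlapping fields of view so that objects
placed across field boundaries genuinely appear in several stacks.

Six object archetypes are rendered as parameterized solids sampled on the
anisotropic voxel grid (0.188 x 0.188 x 1.090 µm by default):

* ``coccolithophore`` — sphere with a bright surface shell;
* ``diatom_chain`` — a chain of touching ellipsoidal cells;
* ``spiky_star`` — a core with radiating rod-shaped spines;
* ``hollow_ring`` — a torus (annular projection with a hole);
* ``textured_blob`` — a sphere with speckled membrane texture, no
  surface signal (bright-field-identical to ``coccolithophore``);
* ``touching_pair`` — two touching spheres, one nucleus each.

Channel structure follows the staining scheme: one DNA sub-blob per cell,
a membrane fill, a surface rim, 0-4 chloroplast blobs, and a darker
bright-field shadow.  All per-object randomness (sizes, orientations,
organelle offsets, texture phases) is drawn once when the scene spec is
built, so an object straddling a field boundary renders consistently in
every field that images it.  No optical point-spread function is
simulated: the pipeline under test performs no deconvolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .config import AcquisitionConfig, default_channels
from .io import FieldOfView, VoxelGrid
from .mosaic import MosaicLayout

CLASS_NAMES = (
    "coccolithophore",
    "diatom_chain",
    "spiky_star",
    "hollow_ring",
    "textured_blob",
    "touching_pair",
)

#: default background (mean, std) per channel
DEFAULT_BACKGROUND = {
    "bright_field": (600.0, 10.0),
    "dna": (30.0, 8.0),
    "membranes": (30.0, 8.0),
    "surface": (30.0, 8.0),
    "chlorophyll": (30.0, 8.0),
}

FIXTURE_NAMES = ("dim_field", "six_classes", "mosaic_straddle")


@dataclass
class SceneObject:
    """One roster entry: archetype, global center, frozen parameters."""

    class_name: str
    center_um: tuple[float, float, float]  # (u, v, w)
    params: dict


@dataclass
class SceneSpec:
    """Full description of a renderable scene."""

    config: AcquisitionConfig
    rows: int
    cols: int
    objects: list[SceneObject]
    background: dict[str, tuple[float, float]]
    spike_prob: float = 0.0  # per-voxel hot-pixel probability (fluorescence)
    spike_amp: float = 400.0
    seed: int = 0
    sample_id: str = "synthetic"

    def layout(self) -> MosaicLayout:
        return MosaicLayout.from_config(self.config, self.rows, self.cols)

    def validate(self) -> None:
        extent_u, extent_v = self.layout().extent_um
        for i, obj in enumerate(self.objects):
            reach = obj.params["reach"]
            if 2 * reach > self.config.field_width_um:
                raise ValueError(
                    f"object {i} ({obj.class_name}) larger than the field extent"
                )
            u, v, _ = obj.center_um
            if not (0 <= u <= extent_u and 0 <= v <= extent_v):
                raise ValueError(f"object {i} center outside the mosaic extent")


@dataclass
class GroundTruth:
    """Per-object truth: class, global centroid, rendered voxel content."""

    frame: pd.DataFrame

    @property
    def centroids_um(self) -> np.ndarray:
        return self.frame[["center_u_um", "center_v_um"]].to_numpy(dtype=float)


@dataclass
class Scene:
    """A rendered fixture: fields, ground truth, and the generating spec."""

    fields: list[FieldOfView]
    truth: GroundTruth
    spec: SceneSpec

    @property
    def config(self) -> AcquisitionConfig:
        return self.spec.config

    @property
    def layout(self) -> MosaicLayout:
        return self.spec.layout()


# ---------------------------------------------------------------------------
# per-class parameter sampling


def sample_object(class_name: str, center_um, rng: np.random.Generator) -> SceneObject:
    """Draw an archetype's frozen parameters; sizes in µm."""
    p: dict = {}
    if class_name == "coccolithophore":
        r = rng.uniform(2.4, 3.0)
        p = {
            "r": r,
            "shell": 0.6,
            "nuclei": [(_interior_offset(rng, 0.3 * r), rng.uniform(0.9, 1.1))],
            "chloro": [(_interior_offset(rng, 0.4 * r), rng.uniform(0.7, 1.0))],
            "reach": r + 0.1,
            "i_membranes": 140.0,
            "i_surface": 320.0,
            "i_dna": 250.0,
            "i_chloro": 200.0,
        }
    elif class_name == "diatom_chain":
        n = 3
        theta = rng.uniform(0, np.pi)
        # cell thickness well beyond the 1.09 µm z-step: at least two planes
        # intersect each cell at any axial phase, so the almost-max
        # projection retains it and the chain clears the area cutoff
        a, b, c = 1.6, 1.5, 2.2
        # cells overlap by 20% of their long axis so the projected chain is
        # a single connected component
        step = 1.6 * a
        cell_offsets = [
            (
                (k - (n - 1) / 2) * step * np.cos(theta),
                (k - (n - 1) / 2) * step * np.sin(theta),
                0.0,
            )
            for k in range(n)
        ]
        p = {
            "n_cells": n,
            "theta": theta,
            "axes": (a, b, c),
            "step": step,
            "nuclei": [(off, 0.7) for off in cell_offsets],
            "chloro_r": 0.9,
            "reach": (n - 1) / 2 * step + a + 0.3,
            "i_membranes": 120.0,
            "i_surface": 90.0,
            "i_dna": 230.0,
            "i_chloro": 320.0,
        }
    elif class_name == "spiky_star":
        n_spikes = int(rng.integers(6, 9))
        phase = rng.uniform(0, 2 * np.pi)
        dirs = []
        for k in range(n_spikes):
            ang = phase + 2 * np.pi * k / n_spikes
            tilt = rng.uniform(-0.25, 0.25)
            d = np.array([np.cos(ang), np.sin(ang), tilt])
            dirs.append(tuple(d / np.linalg.norm(d)))
        p = {
            # the core alone clears the 12.6 um^2 projected-area cutoff;
            # thin spines are partly lost to the almost-max projection
            "r_core": rng.uniform(2.3, 2.6),
            "spikes": dirs,
            "spike_len": rng.uniform(2.2, 2.6),
            "spike_r": 0.45,
            "nuclei": [((0.0, 0.0, 0.0), rng.uniform(0.8, 1.0))],
            "reach": 2.6 + 2.6 + 0.1,
            "i_membranes": 150.0,
            "i_surface": 300.0,
            "i_dna": 230.0,
            "i_chloro": 0.0,
        }
    elif class_name == "hollow_ring":
        R = rng.uniform(2.3, 2.7)
        ang = rng.uniform(0, 2 * np.pi)
        p = {
            "R": R,
            "tube": rng.uniform(1.2, 1.4),
            "nuclei": [((R * np.cos(ang), R * np.sin(ang), 0.0), 0.6)],
            "reach": R + 1.5,
            "i_membranes": 280.0,
            "i_surface": 80.0,
            "i_dna": 210.0,
            "i_chloro": 0.0,
        }
    elif class_name == "textured_blob":
        r = rng.uniform(2.4, 3.0)
        n_chl = int(rng.integers(3, 5))
        p = {
            "r": r,
            "nuclei": [(_interior_offset(rng, 0.3 * r), rng.uniform(0.9, 1.1))],
            "chloro": [
                (_interior_offset(rng, 0.5 * r), rng.uniform(0.6, 0.9))
                for _ in range(n_chl)
            ],
            "speckle_amp": 0.45,
            "speckle_wavelength": (rng.uniform(1.3, 1.9), rng.uniform(1.3, 1.9)),
            "speckle_phase": (rng.uniform(0, 2 * np.pi), rng.uniform(0, 2 * np.pi)),
            "reach": r + 0.1,
            "i_membranes": 180.0,
            "i_surface": 0.0,
            "i_dna": 250.0,
            "i_chloro": 260.0,
        }
    elif class_name == "touching_pair":
        r1, r2 = rng.uniform(2.0, 2.4, size=2)
        theta = rng.uniform(0, np.pi)
        sep = 0.95 * (r1 + r2)
        axis = np.array([np.cos(theta), np.sin(theta), 0.0])
        c1, c2 = -axis * sep / 2, axis * sep / 2
        p = {
            "radii": (r1, r2),
            "centers": (tuple(c1), tuple(c2)),
            "shell": 0.5,
            "nuclei": [
                (tuple(c1), 0.75),
                (tuple(c2), 0.75),
            ],
            "chloro": [
                (tuple(c1 + np.array([0.6, 0.0, 0.0])), 0.6),
                (tuple(c2 + np.array([-0.6, 0.0, 0.0])), 0.6),
            ],
            "reach": sep / 2 + max(r1, r2) + 0.1,
            "i_membranes": 130.0,
            "i_surface": 300.0,
            "i_dna": 240.0,
            "i_chloro": 180.0,
        }
    else:
        raise ValueError(f"unknown object class {class_name!r}")
    return SceneObject(class_name=class_name, center_um=tuple(center_um), params=p)


def _interior_offset(rng: np.random.Generator, scale: float) -> tuple[float, float, float]:
    off = rng.uniform(-scale, scale, size=3)
    off[2] *= 0.5  # organelles stay near the equatorial plane
    return tuple(off)


# ---------------------------------------------------------------------------
# geometry primitives (displacement grids in µm)


def _sphere(du, dv, dw, r, center=(0.0, 0.0, 0.0)):
    return (du - center[0]) ** 2 + (dv - center[1]) ** 2 + (dw - center[2]) ** 2 <= r**2


def _body_mask(obj: SceneObject, du, dv, dw) -> np.ndarray:
    p = obj.params
    name = obj.class_name
    if name in ("coccolithophore", "textured_blob"):
        return _sphere(du, dv, dw, p["r"])
    if name == "diatom_chain":
        a, b, c = p["axes"]
        th = p["theta"]
        along = du * np.cos(th) + dv * np.sin(th)
        across = -du * np.sin(th) + dv * np.cos(th)
        n = p["n_cells"]
        mask = np.zeros(du.shape, dtype=bool)
        for k in range(n):
            pk = (k - (n - 1) / 2) * p["step"]
            mask |= ((along - pk) / a) ** 2 + (across / b) ** 2 + (dw / c) ** 2 <= 1.0
        return mask
    if name == "spiky_star":
        mask = _sphere(du, dv, dw, p["r_core"])
        pts = np.stack([du, dv, dw], axis=-1)
        for d in p["spikes"]:
            d = np.asarray(d)
            t = pts @ d
            perp2 = (pts**2).sum(axis=-1) - t**2
            mask |= (t >= 0) & (t <= p["spike_len"]) & (perp2 <= p["spike_r"] ** 2)
        return mask
    if name == "hollow_ring":
        return (np.hypot(du, dv) - p["R"]) ** 2 + dw**2 <= p["tube"] ** 2
    if name == "touching_pair":
        r1, r2 = p["radii"]
        c1, c2 = p["centers"]
        return _sphere(du, dv, dw, r1, c1) | _sphere(du, dv, dw, r2, c2)
    raise ValueError(name)


def _inner_mask(obj: SceneObject, du, dv, dw) -> np.ndarray:
    """Eroded body used to carve the surface shell."""
    p = obj.params
    name = obj.class_name
    if name == "coccolithophore":
        return _sphere(du, dv, dw, p["r"] - p["shell"])
    if name == "touching_pair":
        r1, r2 = p["radii"]
        c1, c2 = p["centers"]
        return _sphere(du, dv, dw, r1 - p["shell"], c1) | _sphere(
            du, dv, dw, r2 - p["shell"], c2
        )
    return np.zeros(du.shape, dtype=bool)


def _render_object(
    obj: SceneObject, U, V, W, channels: Sequence[str]
) -> tuple[dict[str, np.ndarray], dict[str, int]]:
    """Intensity contributions of one object on absolute µm grids.

    Returns (per-channel added intensity, per-channel true voxel counts).
    """
    cu, cv, cw = obj.center_um
    du, dv, dw = U - cu, V - cv, W - cw
    p = obj.params
    body = _body_mask(obj, du, dv, dw)
    out: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}

    if "membranes" in channels:
        fill = np.where(body, p["i_membranes"], 0.0)
        if "speckle_amp" in p:
            lu, lv = p["speckle_wavelength"]
            pu, pv = p["speckle_phase"]
            speckle = 1.0 + p["speckle_amp"] * np.sin(2 * np.pi * U / lu + pu) * np.sin(
                2 * np.pi * V / lv + pv
            )
            fill = fill * speckle
        out["membranes"] = fill
        counts["membranes"] = int(body.sum())

    if "surface" in channels and p.get("i_surface", 0) > 0:
        if obj.class_name in ("coccolithophore", "touching_pair"):
            shell = body & ~_inner_mask(obj, du, dv, dw)
        else:
            shell = body
        out["surface"] = np.where(shell, p["i_surface"], 0.0)
        counts["surface"] = int(shell.sum())

    if "dna" in channels:
        dna = np.zeros(du.shape, dtype=bool)
        for off, rn in p.get("nuclei", []):
            dna |= _sphere(du, dv, dw, rn, off)
        dna &= body
        out["dna"] = np.where(dna, p["i_dna"], 0.0)
        counts["dna"] = int(dna.sum())

    if "chlorophyll" in channels and p.get("i_chloro", 0) > 0:
        chl = np.zeros(du.shape, dtype=bool)
        if obj.class_name == "diatom_chain":
            # one chloroplast per cell, offset across the chain axis
            th = p["theta"]
            a = p["axes"][0]
            for k in range(p["n_cells"]):
                pk = (k - (p["n_cells"] - 1) / 2) * p["step"]
                off = (pk * np.cos(th), pk * np.sin(th), 0.0)
                chl |= _sphere(du, dv, dw, p["chloro_r"], off)
        else:
            for off, rc in p.get("chloro", []):
                chl |= _sphere(du, dv, dw, rc, off)
        chl &= body
        out["chlorophyll"] = np.where(chl, p["i_chloro"], 0.0)
        counts["chlorophyll"] = int(chl.sum())

    if "bright_field" in channels:
        out["bright_field"] = np.where(body, -210.0, 0.0)

    counts["body"] = int(body.sum())
    return out, counts


# ---------------------------------------------------------------------------
# scene rendering


def render_scene(spec: SceneSpec) -> tuple[list[FieldOfView], GroundTruth]:
    """Render all fields of a scene and collect ground truth.

    Background noise is drawn independently per (seed, field, channel);
    object structure is deterministic given the spec, so straddling
    objects render consistently in every field.  True voxel counts are
    recorded on the lattice of each object's canonical field.
    """
    spec.validate()
    config = spec.config
    layout = spec.layout()
    vxy, vz = config.voxel_size_xy_um, config.voxel_size_z_um
    n = config.frame_pixels
    nz = config.z_planes
    truth_rows = [
        {
            "object_index": i,
            "class_name": o.class_name,
            "center_u_um": o.center_um[0],
            "center_v_um": o.center_um[1],
        }
        for i, o in enumerate(spec.objects)
    ]
    canonical = [layout.canonical_field(o.center_um[:2]) for o in spec.objects]

    fields: list[FieldOfView] = []
    for r in range(spec.rows):
        for c in range(spec.cols):
            ou, ov = layout.origin(r, c)
            stacks: dict[str, np.ndarray] = {}
            for ch in config.channel_names:
                rng = np.random.default_rng(
                    [spec.seed, r, c, config.channel_names.index(ch)]
                )
                mean, std = spec.background[ch]
                arr = rng.normal(mean, std, size=(n, n, nz))
                if spec.spike_prob > 0 and ch != config.brightfield_channel:
                    spikes = rng.random(size=arr.shape) < spec.spike_prob
                    arr[spikes] += spec.spike_amp
                stacks[ch] = arr
            for i, obj in enumerate(spec.objects):
                reach = obj.params["reach"]
                cu, cv, cw = obj.center_um
                # field-local pixel ranges covering the object (u<->y, v<->x)
                y0 = max(int(np.floor((cu - reach - ou) / vxy)) - 1, 0)
                y1 = min(int(np.ceil((cu + reach - ou) / vxy)) + 1, n)
                x0 = max(int(np.floor((cv - reach - ov) / vxy)) - 1, 0)
                x1 = min(int(np.ceil((cv + reach - ov) / vxy)) + 1, n)
                if x0 >= x1 or y0 >= y1:
                    continue
                xs = ov + (np.arange(x0, x1) + 0.5) * vxy  # global v
                ys = ou + (np.arange(y0, y1) + 0.5) * vxy  # global u
                zs = (np.arange(nz) + 0.5) * vz
                V, U, W = np.meshgrid(xs, ys, zs, indexing="ij")
                contrib, counts = _render_object(obj, U, V, W, config.channel_names)
                for ch, add in contrib.items():
                    stacks[ch][x0:x1, y0:y1, :] += add
                if canonical[i] == (r, c):
                    for key, val in counts.items():
                        truth_rows[i][f"voxels_{key}"] = val
            grids = {
                ch: VoxelGrid(
                    values=np.clip(np.rint(a), 0, 65535).astype(np.uint16),
                    config=config,
                )
                for ch, a in stacks.items()
            }
            fields.append(
                FieldOfView(
                    channel_grids=grids,
                    mosaic_row=r,
                    mosaic_col=c,
                    sample_id=spec.sample_id,
                    config=config,
                )
            )
    frame = pd.DataFrame(truth_rows).fillna(0)
    return fields, GroundTruth(frame=frame)


# ---------------------------------------------------------------------------
# placement and fixtures


def _grid_centers(
    extent_u: float,
    extent_v: float,
    n_u: int,
    n_v: int,
    margin: float,
    jitter: float,
    rng: np.random.Generator,
) -> list[tuple[float, float]]:
    us = np.linspace(margin, extent_u - margin, n_u)
    vs = np.linspace(margin, extent_v - margin, n_v)
    out = []
    for u in us:
        for v in vs:
            out.append(
                (u + rng.uniform(-jitter, jitter), v + rng.uniform(-jitter, jitter))
            )
    return out


def _fixture_config(frame_pixels: int = 256, z_planes: int = 10) -> AcquisitionConfig:
    base = AcquisitionConfig()
    return base.with_frame(frame_pixels, z_planes)


def _w_center(config: AcquisitionConfig, rng: np.random.Generator) -> float:
    mid = config.z_planes * config.voxel_size_z_um / 2.0
    return mid + rng.uniform(-0.8, 0.8)


def make_fixture(name: str, seed: int = 0) -> Scene:
    """Build one of the packaged scenes.

    * ``dim_field`` — one 512-px field with 30 low-contrast particles
      visible only in the membrane channel, over spike-contaminated
      (heavy-tailed) background noise.
    * ``six_classes`` — 150 objects of each of the 6 archetypes spread
      over single-field scenes (100 fields of 9 objects).
    * ``mosaic_straddle`` — a 3x3 mosaic of 512-px fields with 10 objects
      placed across field boundaries plus 12 interior objects.
    """
    if name not in FIXTURE_NAMES:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    rng = np.random.default_rng([seed, FIXTURE_NAMES.index(name)])

    if name == "dim_field":
        config = _fixture_config(frame_pixels=512, z_planes=10)
        extent = config.field_width_um
        centers = _grid_centers(extent, extent, 5, 6, margin=10.0, jitter=3.0, rng=rng)
        objects = []
        for u, v in centers:
            r = rng.uniform(2.4, 2.8)
            objects.append(
                SceneObject(
                    class_name="coccolithophore",
                    center_um=(u, v, _w_center(config, rng)),
                    params={
                        "r": r,
                        "shell": r,  # degenerate shell: not used (no surface)
                        "nuclei": [],
                        "chloro": [],
                        "reach": r + 0.1,
                        "i_membranes": 70.0,
                        "i_surface": 0.0,
                        "i_dna": 0.0,
                        "i_chloro": 0.0,
                    },
                )
            )
        spec = SceneSpec(
            config=config,
            rows=1,
            cols=1,
            objects=objects,
            background=dict(DEFAULT_BACKGROUND),
            spike_prob=0.002,
            spike_amp=400.0,
            seed=seed,
            sample_id="dim_field",
        )
    elif name == "six_classes":
        config = _fixture_config(frame_pixels=256, z_planes=10)
        extent = config.field_width_um
        n_fields = 100
        labels = np.repeat(CLASS_NAMES, 150)
        rng.shuffle(labels)
        objects = []
        spec_fields = []
        idx = 0
        for f in range(n_fields):
            field_rng = np.random.default_rng([seed, 1, f])
            centers = _grid_centers(
                extent, extent, 3, 3, margin=10.0, jitter=1.0, rng=field_rng
            )
            field_objects = [
                sample_object(
                    labels[idx + k],
                    (u, v, _w_center(config, field_rng)),
                    field_rng,
                )
                for k, (u, v) in enumerate(centers)
            ]
            idx += len(centers)
            spec_fields.append(
                SceneSpec(
                    config=config,
                    rows=1,
                    cols=1,
                    objects=field_objects,
                    background=dict(DEFAULT_BACKGROUND),
                    seed=seed * 100003 + f,
                    sample_id=f"six_classes_f{f:03d}",
                )
            )
        # rendered lazily by the caller via render_scene on each sub-spec
        return _render_multi(spec_fields)
    else:  # mosaic_straddle
        config = _fixture_config(frame_pixels=512, z_planes=10)
        layout = MosaicLayout.from_config(config, 3, 3)
        spacing = layout.spacing_um
        overlap = layout.overlap_width_um
        extent_u, extent_v = layout.extent_um
        objects = []
        # 10 straddlers centered just off the core midline of a shared edge,
        # small enough to lie strictly inside the overlap slab of both fields
        straddle_positions = []
        for k, boundary_col in enumerate((1, 2, 1, 2, 1)):
            v = boundary_col * spacing + overlap / 2 + 0.7
            u = 20.0 + 50.0 * k
            straddle_positions.append((u, v))
        for k, boundary_row in enumerate((1, 2, 1, 2, 1)):
            u = boundary_row * spacing + overlap / 2 - 0.7
            v = 30.0 + 48.0 * k
            straddle_positions.append((u, v))
        for u, v in straddle_positions:
            obj = sample_object("coccolithophore", (u, v, _w_center(config, rng)), rng)
            obj.params["r"] = min(obj.params["r"], 2.8)
            obj.params["reach"] = obj.params["r"] + 0.1
            objects.append(obj)
        # 12 interior objects, away from every overlap slab
        interior = 0
        while interior < 12:
            u = rng.uniform(12.0, extent_u - 12.0)
            v = rng.uniform(12.0, extent_v - 12.0)
            if _near_boundary(u, spacing, overlap, 3) or _near_boundary(
                v, spacing, overlap, 3
            ):
                continue
            placed = np.array([o.center_um[:2] for o in objects])
            if np.linalg.norm(placed - np.array([u, v]), axis=1).min() < 14.0:
                continue
            objects.append(
                sample_object(
                    str(rng.choice(["coccolithophore", "touching_pair", "hollow_ring"])),
                    (u, v, _w_center(config, rng)),
                    rng,
                )
            )
            interior += 1
        spec = SceneSpec(
            config=config,
            rows=3,
            cols=3,
            objects=objects,
            background=dict(DEFAULT_BACKGROUND),
            seed=seed,
            sample_id="mosaic_straddle",
        )

    fields, truth = render_scene(spec)
    return Scene(fields=fields, truth=truth, spec=spec)


def _near_boundary(coord: float, spacing: float, overlap: float, count: int) -> bool:
    """Is a coordinate within (or near) any inter-field overlap slab?"""
    for k in range(1, count):
        lo = k * spacing - 6.0
        hi = k * spacing + overlap + 6.0
        if lo <= coord <= hi:
            return True
    return False


def _render_multi(specs: list[SceneSpec]) -> Scene:
    """Render a list of single-field specs into one Scene (fields tagged by
    their spec's sample id; truth concatenated with a field index)."""
    all_fields: list[FieldOfView] = []
    frames = []
    for f, spec in enumerate(specs):
        fields, truth = render_scene(spec)
        all_fields.extend(fields)
        df = truth.frame.copy()
        df.insert(0, "field_index", f)
        frames.append(df)
    frame = pd.concat(frames, ignore_index=True)
    frame["object_index"] = np.arange(len(frame))
    merged_spec = SceneSpec(
        config=specs[0].config,
        rows=1,
        cols=1,
        objects=[o for s in specs for o in s.objects],
        background=specs[0].background,
        seed=specs[0].seed,
        sample_id="six_classes",
    )
    return Scene(fields=all_fields, truth=GroundTruth(frame=frame), spec=merged_spec)


# ---------------------------------------------------------------------------
# ground-truth matching


def match_centroids(
    detected_um: np.ndarray, truth_um: np.ndarray, max_dist_um: float = 3.0
) -> np.ndarray:
    """Greedy nearest-neighbor match of detections to ground truth.

    Returns, per detection, the matched truth index or -1; each truth
    object is matched at most once.
    """
    detected_um = np.atleast_2d(np.asarray(detected_um, dtype=float))
    truth_um = np.atleast_2d(np.asarray(truth_um, dtype=float))
    out = np.full(len(detected_um), -1, dtype=int)
    if len(detected_um) == 0 or len(truth_um) == 0:
        return out
    d = np.linalg.norm(detected_um[:, None, :] - truth_um[None, :, :], axis=2)
    pairs = sorted(
        ((d[i, j], i, j) for i in range(d.shape[0]) for j in range(d.shape[1]))
    )
    used_t: set[int] = set()
    used_d: set[int] = set()
    for dist, i, j in pairs:
        if dist > max_dist_um or i in used_d or j in used_t:
            continue
        out[i] = j
        used_d.add(i)
        used_t.add(j)
    return out
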