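"""Shared fixtures: small configs and rendered scenes.

Heavy scenes (six_classes, mosaic_straddle, dim_field) are rendered once
per session and shared between the module tests and the acceptance tests.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from hcfm.config import AcquisitionConfig, ChannelRole
from hcfm.detect import estimate_background, extract_objects, identify_objects
from hcfm.features import featurize
from hcfm.synthetic import make_fixture, match_centroids

warnings.filterwarnings(
    "ignore", message="Applying `local_binary_pattern`", category=UserWarning
)


def two_channel_config(frame_pixels: int = 64, z_planes: int = 4) -> AcquisitionConfig:
    """Minimal config: one bright-field plus one fluorescence channel."""
    return AcquisitionConfig(
        frame_pixels=frame_pixels,
        field_width_um=frame_pixels * 0.188,
        z_planes=z_planes,
        channels=(
            ChannelRole("bright_field", "bright_field", False),
            ChannelRole("dna", "dna", True),
        ),
    )


@pytest.fixture(scope="session")
def small_config() -> AcquisitionConfig:
    return AcquisitionConfig().with_frame(256, 10)


@pytest.fixture(scope="session")
def dim_scene():
    return make_fixture("dim_field", seed=0)


@pytest.fixture(scope="session")
def straddle_scene():
    return make_fixture("mosaic_straddle", seed=0)


@pytest.fixture(scope="session")
def six_class_data():
    """six_classes scene processed to labeled feature vectors.

    Returns (X, y, recovery_stats) where recovery_stats carries the
    ground-truth match bookkeeping used by the recovery tests.
    """
    scene = make_fixture("six_classes", seed=0)
    cfg = scene.config
    background = estimate_background(scene.fields, cfg)
    X, y = [], []
    n_truth = len(scene.truth.frame)
    n_matched = 0
    centroid_errors = []
    for fi, fov in enumerate(scene.fields):
        masks = identify_objects(fov, background, cfg)
        objs = extract_objects(fov, masks)
        det = (
            np.array(
                [
                    [m.centroid[1] * cfg.voxel_size_xy_um,
                     m.centroid[0] * cfg.voxel_size_xy_um]
                    for m in masks
                ]
            )
            if masks
            else np.zeros((0, 2))
        )
        tf = scene.truth.frame[scene.truth.frame["field_index"] == fi]
        truth_um = tf[["center_u_um", "center_v_um"]].to_numpy(dtype=float)
        match = match_centroids(det, truth_um, max_dist_um=3.0)
        for obj, j in zip(objs, match):
            if j < 0:
                continue
            n_matched += 1
            centroid_errors.append(float(np.linalg.norm(det[obj.label - 1] - truth_um[j])))
            X.append(featurize(obj, background).values)
            y.append(tf.iloc[j]["class_name"])
    stats = {
        "n_truth": n_truth,
        "n_matched": n_matched,
        "centroid_errors_um": np.array(centroid_errors),
    }
    return np.array(X), np.array(y), stats
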