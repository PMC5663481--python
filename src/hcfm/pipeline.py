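"""End-to-end orchestration: background -> detect -> dedup -> features ->
(classify) -> (quantify).

Background statistics are estimated once over all fields of a sample;
after that, per-field processing is independent and may run in any order
— results are merged on the deterministic (row, col, label) sort key, so
the outputs do not depend on scheduling.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .classify import ForestModel, predict_with_confidence
from .config import AcquisitionConfig
from .detect import (
    BackgroundModel,
    estimate_background,
    extract_objects,
    identify_objects,
)
from .features import FeatureCatalog, FeatureVector, default_catalog, featurize
from .io import FieldOfView, write_feature_table
from .mosaic import (
    CanonicalAssignment,
    MosaicLayout,
    assign_canonical,
    dedup_counts,
    detection_global_centroid,
    write_registry,
)

log = logging.getLogger("hcfm")


@dataclass
class RunResult:
    """Everything a pipeline run produces for one sample."""

    background: BackgroundModel
    registry: list[CanonicalAssignment]
    features: list[FeatureVector]
    predictions: pd.DataFrame | None
    tallies: dict[str, int]
    catalog_version: str

    def registry_frame(self) -> pd.DataFrame:
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
            for a in self.registry
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "object_id", "sample", "field_row", "field_col",
                "centroid_u_um", "centroid_v_um", "source_label",
            ],
        )


def run_pipeline(
    fields: Sequence[FieldOfView],
    config: AcquisitionConfig,
    layout: MosaicLayout | None = None,
    catalog: FeatureCatalog | None = None,
    model: ForestModel | None = None,
    compute_features: bool = True,
) -> RunResult:
    """Process one sample's fields end to end.

    Stages: pooled background estimation; per-field detection; canonical
    assignment and sequential relabeling; per-object 3D sub-segmentation
    and feature extraction; optional classification when a trained model
    is supplied.  Per-field processing order does not affect any output.
    """
    if layout is None:
        rows = max((f.mosaic_row for f in fields), default=0) + 1
        cols = max((f.mosaic_col for f in fields), default=0) + 1
        layout = MosaicLayout.from_config(config, rows, cols)
    catalog = catalog or default_catalog()
    if not fields:
        return RunResult(
            background=BackgroundModel(mean={}, std={}, threshold={}),
            registry=[],
            features=[],
            predictions=None,
            tallies={"detections": 0, "non_canonical_removed": 0, "registry": 0},
            catalog_version=catalog.version,
        )

    t0 = time.perf_counter()
    background = estimate_background(fields, config)
    log.info("stage=background sample=%s n_fields=%d duration=%.2fs",
             fields[0].sample_id, len(fields), time.perf_counter() - t0)

    detections = []
    for fov in fields:
        t0 = time.perf_counter()
        masks = identify_objects(fov, background, config)
        objs = extract_objects(fov, masks)
        detections.extend(objs)
        log.info(
            "stage=detect sample=%s field=(%d,%d) objects=%d duration=%.2fs",
            fov.sample_id, fov.mosaic_row, fov.mosaic_col, len(masks),
            time.perf_counter() - t0,
        )

    assignments = assign_canonical(detections, layout)
    registry = dedup_counts(assignments)
    tallies = {
        "detections": len(detections),
        "non_canonical_removed": len(detections) - len(assignments),
        "registry": len(registry),
    }
    log.info("stage=dedup sample=%s %s", fields[0].sample_id, tallies)

    feature_vectors: list[FeatureVector] = []
    if compute_features:
        t0 = time.perf_counter()
        for a in registry:
            fv = featurize(a.obj, background, catalog)
            fv.object_id = a.object_id
            feature_vectors.append(fv)
        log.info("stage=features sample=%s objects=%d duration=%.2fs",
                 fields[0].sample_id, len(registry), time.perf_counter() - t0)

    predictions = None
    if model is not None and feature_vectors:
        X = np.stack([fv.values for fv in feature_vectors])
        preds = predict_with_confidence(
            model, X, object_ids=[fv.object_id for fv in feature_vectors]
        )
        predictions = pd.DataFrame(
            {
                "object_id": [p.object_id for p in preds],
                "predicted": [p.predicted for p in preds],
                "confidence": [p.confidence for p in preds],
            }
        )
    return RunResult(
        background=background,
        registry=registry,
        features=feature_vectors,
        predictions=predictions,
        tallies=tallies,
        catalog_version=catalog.version,
    )


def write_outputs(result: RunResult, directory: str | Path) -> dict[str, Path]:
    """Write registry, feature table, and predictions as TSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = {}
    out["registry"] = write_registry(result.registry, directory / "registry.tsv")
    out["features"] = write_feature_table(result.features, directory / "features.tsv")
    if result.predictions is not None:
        path = directory / "predictions.tsv"
        result.predictions.to_csv(path, sep="\t", index=False)
        out["predictions"] = path
    return out


def make_report(result: RunResult) -> dict:
    """Summary of one run: counts, per-category abundances, provenance."""
    report: dict = {
        "catalog_version": result.catalog_version,
        "n_objects": len(result.registry),
        "tallies": dict(result.tallies),
    }
    if result.predictions is not None:
        report["category_counts"] = (
            result.predictions["predicted"].value_counts().sort_index().to_dict()
        )
    report["vignette_index"] = [
        {
            "object_id": a.object_id,
            "field_row": a.canonical_field[0],
            "field_col": a.canonical_field[1],
            "source_label": a.obj.label,
        }
        for a in result.registry
    ]
    return report
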