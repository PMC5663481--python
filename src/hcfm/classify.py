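"""Hierarchical random-forest classification of detected objects.

Objects are classified at the finest level of a 4-level taxo-morphological
hierarchy by a random forest (500 trees by default) over the 480-descriptor
feature vectors.  Classes are not reweighted for abundance.  The forest
returns per-class probability estimates; an object is assigned to the
class with the highest probability and carries a *confidence score*, the
difference between the highest and second-highest probabilities.  Leaf
predictions are aggregated up the hierarchy to report accuracy at every
level.  Feature importances are impurity-based (Gini) importances
normalized by their mean, so values above 1 mark features more important
than average.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .config import MIN_SPECIMENS_PER_CATEGORY, N_TREES
from .features import CATALOG_VERSION, brightfield_feature_indices  # noqa: F401
from .io import LabelTable, PROVENANCE_COLUMNS
from .taxonomy import N_LEVELS, TaxonomyTree


@dataclass
class TrainingSet:
    """Curated feature matrix with leaf labels and the induced hierarchy."""

    X: np.ndarray
    y: np.ndarray  # level-4 (leaf) labels
    tree: TaxonomyTree
    catalog_version: str = CATALOG_VERSION
    feature_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.X) != len(self.y):
            raise ValueError("feature matrix and labels disagree in length")

    def leaf_counts(self) -> pd.Series:
        return pd.Series(self.y).value_counts().sort_index()


def curate_training_set(
    labels: LabelTable,
    features: pd.DataFrame,
    min_specimens: int = MIN_SPECIMENS_PER_CATEGORY,
) -> TrainingSet:
    """Join labels with features and keep categories with more than
    ``min_specimens`` specimens.

    Categories at or below the threshold are dropped together with their
    objects; classes are not reweighted.  Raises if nothing survives,
    reporting the offending counts.
    """
    feat_cols = [c for c in features.columns if c not in PROVENANCE_COLUMNS]
    merged = labels.frame.merge(features, on="object_id", how="inner")
    if len(merged) < len(labels.frame):
        missing = set(labels.frame["object_id"]) - set(merged["object_id"])
        raise ValueError(f"labels reference missing feature vectors: {sorted(missing)[:5]}")
    counts = merged.groupby("level4").size()
    kept_leaves = counts[counts > min_specimens].index
    kept = merged[merged["level4"].isin(kept_leaves)]
    if kept.empty:
        raise ValueError(
            f"no category exceeds {min_specimens} specimens; counts: "
            f"{counts.to_dict()}"
        )
    tree = TaxonomyTree.from_paths(
        kept[["level1", "level2", "level3", "level4"]].drop_duplicates().itertuples(
            index=False, name=None
        )
    )
    return TrainingSet(
        X=kept[feat_cols].to_numpy(dtype=float),
        y=kept["level4"].to_numpy(),
        tree=tree,
        feature_names=tuple(feat_cols),
    )


@dataclass
class ForestModel:
    """A trained forest plus the provenance needed to apply it safely."""

    estimator: RandomForestClassifier
    catalog_version: str
    seed: int
    feature_indices: np.ndarray | None = None  # None -> full catalog

    @property
    def classes_(self) -> np.ndarray:
        return self.estimator.classes_

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path: str | Path) -> "ForestModel":
        return joblib.load(path)


def train_classifier(
    train: TrainingSet,
    seed: int = 0,
    n_trees: int = N_TREES,
    feature_indices: Sequence[int] | None = None,
    oob_score: bool = False,
) -> ForestModel:
    """Fit a random forest on leaf labels.

    Defaults: 500 trees, sqrt(n_features) candidates per split, unlimited
    depth, bootstrap sampling; deterministic for a given seed.
    """
    if len(np.unique(train.y)) < 2:
        raise ValueError("training requires at least 2 leaf categories")
    X = train.X
    idx = None
    if feature_indices is not None:
        idx = np.sort(np.asarray(feature_indices, dtype=int))
        X = X[:, idx]
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        bootstrap=True,
        random_state=seed,
        oob_score=oob_score,
        n_jobs=1,
    )
    forest.fit(X, train.y)
    return ForestModel(
        estimator=forest,
        catalog_version=train.catalog_version,
        seed=seed,
        feature_indices=idx,
    )


@dataclass
class PredictionResult:
    """Per-object class probabilities with argmax label and confidence."""

    probabilities: np.ndarray
    classes: np.ndarray
    predicted: str
    confidence: float
    object_id: int = 0


def predict_with_confidence(
    model: ForestModel, X: np.ndarray, object_ids: Sequence[int] | None = None
) -> list[PredictionResult]:
    """Assign each object to its most probable class.

    Confidence is the gap between the two largest class probabilities
    (second-highest defined as 0 for a single-class model); probability
    ties break to the lower class index.
    """
    if model.feature_indices is not None:
        X = X[:, model.feature_indices]
    proba = model.estimator.predict_proba(np.asarray(X, dtype=float))
    classes = model.classes_
    out = []
    for i, p in enumerate(proba):
        order = np.argsort(-p, kind="stable")  # stable: ties -> lower index
        top = int(order[0])
        second = float(p[order[1]]) if len(p) > 1 else 0.0
        out.append(
            PredictionResult(
                probabilities=p,
                classes=classes,
                predicted=str(classes[top]),
                confidence=float(p[top]) - second,
                object_id=object_ids[i] if object_ids is not None else i,
            )
        )
    return out


def filter_by_confidence(
    predictions: Sequence[PredictionResult], cutoff: float
) -> list[PredictionResult]:
    """Retain predictions with confidence >= cutoff."""
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must be in [0, 1]")
    return [p for p in predictions if p.confidence >= cutoff]


def confidence_curve(
    predictions: Sequence[PredictionResult],
    truth: Sequence[str],
    cutoffs: Sequence[float],
) -> pd.DataFrame:
    """Retained fraction and accuracy among retained, per confidence cutoff."""
    truth = np.asarray(truth)
    pred = np.array([p.predicted for p in predictions])
    conf = np.array([p.confidence for p in predictions])
    rows = []
    for c in cutoffs:
        keep = conf >= c
        acc = float((pred[keep] == truth[keep]).mean()) if keep.any() else np.nan
        rows.append({"cutoff": c, "retained_fraction": float(keep.mean()), "accuracy": acc})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# hierarchical evaluation


@dataclass
class HierarchicalReport:
    """Per-level accuracy, per-category recall, and confusion matrices."""

    accuracy: dict[int, float]
    recall: dict[int, pd.Series]
    confusion: dict[int, pd.DataFrame]
    y_true: np.ndarray = field(default_factory=lambda: np.array([]))
    y_pred: np.ndarray = field(default_factory=lambda: np.array([]))

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for level in self.confusion:
            self.confusion[level].to_csv(
                directory / f"confusion_level{level}.tsv", sep="\t"
            )
            self.recall[level].rename("recall").to_csv(
                directory / f"recall_level{level}.tsv", sep="\t"
            )
        pd.Series(self.accuracy, name="accuracy").rename_axis("level").to_csv(
            directory / "accuracy_per_level.tsv", sep="\t"
        )


def aggregate_hierarchical(
    y_true: Sequence[str], y_pred: Sequence[str], tree: TaxonomyTree
) -> HierarchicalReport:
    """Map leaf truth/predictions to every ancestor level and score them.

    An object correct at the leaf is necessarily correct at all coarser
    levels, since each leaf has a single ancestor path.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    accuracy: dict[int, float] = {}
    recall: dict[int, pd.Series] = {}
    confusion: dict[int, pd.DataFrame] = {}
    for level in range(1, N_LEVELS + 1):
        t = np.array([tree.ancestor(leaf, level) for leaf in y_true])
        p = np.array([tree.ancestor(leaf, level) for leaf in y_pred])
        cats = sorted(tree.nodes_at_level(level))
        accuracy[level] = float((t == p).mean())
        cm = pd.crosstab(
            pd.Categorical(t, categories=cats),
            pd.Categorical(p, categories=cats),
            dropna=False,
        )
        cm.index.name, cm.columns.name = "true", "predicted"
        confusion[level] = cm
        support = cm.sum(axis=1)
        empty = support[support == 0].index.tolist()
        if empty:
            warnings.warn(
                f"level {level}: categories with no test instances excluded "
                f"from recall: {empty}",
                stacklevel=2,
            )
        with np.errstate(invalid="ignore"):
            rec = np.diag(cm.to_numpy()) / support.to_numpy()
        recall[level] = pd.Series(rec, index=cm.index, name="recall").dropna()
    return HierarchicalReport(
        accuracy=accuracy, recall=recall, confusion=confusion, y_true=y_true, y_pred=y_pred
    )


def cross_validated_predictions(
    train: TrainingSet,
    folds: int = 10,
    seed: int = 0,
    n_trees: int = N_TREES,
    feature_indices: Sequence[int] | None = None,
) -> np.ndarray:
    """Out-of-fold leaf predictions from stratified k-fold CV."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    y_pred = np.empty(len(train.y), dtype=object)
    for fold, (tr, te) in enumerate(skf.split(train.X, train.y)):
        sub = TrainingSet(
            X=train.X[tr], y=train.y[tr], tree=train.tree,
            catalog_version=train.catalog_version,
        )
        model = train_classifier(
            sub, seed=seed + fold, n_trees=n_trees, feature_indices=feature_indices
        )
        for i, p in zip(te, predict_with_confidence(model, train.X[te])):
            y_pred[i] = p.predicted
    return y_pred.astype(str)


def evaluate_hierarchical(
    train: TrainingSet,
    folds: int = 10,
    seed: int = 0,
    n_trees: int = N_TREES,
    feature_indices: Sequence[int] | None = None,
) -> HierarchicalReport:
    """Stratified k-fold CV, aggregated at all 4 hierarchy levels."""
    y_pred = cross_validated_predictions(
        train, folds=folds, seed=seed, n_trees=n_trees, feature_indices=feature_indices
    )
    return aggregate_hierarchical(train.y, y_pred, train.tree)


# ---------------------------------------------------------------------------
# feature importance and reduction


def feature_importance(model: ForestModel) -> np.ndarray:
    """Gini importances divided by their mean (reported mean is 1)."""
    imp = model.estimator.feature_importances_
    mean = imp.mean()
    return imp / mean if mean > 0 else np.ones_like(imp)


def feature_reduction_curve(
    train: TrainingSet,
    k_grid: Sequence[int],
    folds: int = 10,
    seed: int = 0,
    n_trees: int = N_TREES,
) -> pd.DataFrame:
    """Leaf accuracy of top-k-feature forests, k ranked per CV fold.

    Within each fold, features are ranked by importance computed on the
    training portion only; the forest is retrained on the top k and
    scored on the held-out portion.  Selected indices are sorted so the
    full-k entry reproduces the plain CV run exactly.
    """
    n_features = train.X.shape[1]
    k_grid = sorted(set(int(k) for k in k_grid))
    if any(k < 1 or k > n_features for k in k_grid):
        raise ValueError(f"k values must be in [1, {n_features}]")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores: dict[int, list[float]] = {k: [] for k in k_grid}
    for fold, (tr, te) in enumerate(skf.split(train.X, train.y)):
        sub = TrainingSet(
            X=train.X[tr], y=train.y[tr], tree=train.tree,
            catalog_version=train.catalog_version,
        )
        ranking_model = train_classifier(sub, seed=seed + fold, n_trees=n_trees)
        order = np.argsort(-feature_importance(ranking_model), kind="stable")
        for k in k_grid:
            idx = np.sort(order[:k])
            model = train_classifier(
                sub, seed=seed + fold, n_trees=n_trees, feature_indices=idx
            )
            preds = predict_with_confidence(model, train.X[te])
            y_hat = np.array([p.predicted for p in preds])
            scores[k].append(float((y_hat == train.y[te]).mean()))
    return pd.DataFrame(
        {"k": k_grid, "accuracy": [float(np.mean(scores[k])) for k in k_grid]}
    )
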