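"""Binary exceedance classification with a random forest.

The workflow mirrors standard practice for hazard mapping: a stratified
80/20 train/test split, tuning of ``mtry`` (the number of predictors made
available at each split) by out-of-bag accuracy over candidate values, a
final forest fit (default 10,001 trees), and probability prediction on
modeling tables or directly on a co-registered raster stack.

Categorical predictors are one-hot encoded with the category levels frozen
at fit time; the encoded schema travels with the fitted model so that
prediction inputs are validated column-by-column.  Predicted probabilities
are the fraction of trees voting for exceedance (scikit-learn's
``predict_proba`` mean-of-tree-probabilities; for fully grown trees this is
the tree-vote fraction).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .grids import RasterGrid, require_coregistered
from .prep import ModelingTable

__all__ = [
    "ForestSpec",
    "SplitResult",
    "FittedForest",
    "stratified_split",
    "tune_mtry",
    "fit_forest",
    "predict_prob_table",
    "predict_prob_raster",
    "save_forest",
    "load_forest",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ForestSpec:
    """Forest hyper-parameters.  ``mtry=None`` means tune before fitting."""

    n_trees: int = 10_001
    mtry: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.mtry is not None and self.mtry < 1:
            raise ValueError("mtry must be >= 1")


@dataclass
class SplitResult:
    train: ModelingTable
    test: ModelingTable
    seed: int


@dataclass
class FittedForest:
    """A fitted forest plus the encoded-column schema it expects."""

    estimator: RandomForestClassifier
    predictor_cols: list[str]
    categorical_levels: dict[str, list]  # raw categorical column -> levels seen at fit
    feature_columns: list[str]  # encoded design-matrix columns, in order
    oob_accuracy: float = field(default=float("nan"))


def _check_two_classes(labels: np.ndarray, what: str) -> None:
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError(f"{what} requires both classes present, got only {classes}")


def stratified_split(
    table: ModelingTable, train_fraction: float = 0.8, seed: int = 0
) -> SplitResult:
    """Per-class train/test partition preserving the class balance."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    _check_two_classes(table.labels, "stratified_split")
    idx = np.arange(len(table))
    train_idx, test_idx = train_test_split(
        idx,
        train_size=train_fraction,
        stratify=table.labels,
        random_state=seed,
    )
    frame = table.frame.reset_index(drop=True)
    base = ModelingTable(frame, list(table.predictor_cols), list(table.categorical_cols))
    return SplitResult(
        train=base.subset(np.sort(train_idx)),
        test=base.subset(np.sort(test_idx)),
        seed=seed,
    )


def _encode_fit(table: ModelingTable) -> tuple[np.ndarray, dict[str, list], list[str]]:
    """One-hot encode categoricals; freeze levels and column order."""
    levels = {
        c: list(table.frame[c].cat.categories) for c in table.categorical_cols
    }
    X = pd.get_dummies(table.X, columns=table.categorical_cols, dtype=float)
    return X.to_numpy(dtype=float), levels, list(X.columns)


def _encode_apply(
    frame: pd.DataFrame,
    predictor_cols: list[str],
    categorical_levels: dict[str, list],
    feature_columns: list[str],
) -> np.ndarray:
    missing = [c for c in predictor_cols if c not in frame.columns]
    if missing:
        raise ValueError(f"input is missing predictor columns: {missing}")
    X = frame[predictor_cols].copy()
    for col, levels in categorical_levels.items():
        vals = X[col]
        # raster layers carry category codes as floats; align dtype to levels
        if levels and isinstance(levels[0], (int, np.integer)):
            vals = pd.to_numeric(vals).astype("int64")
        X[col] = pd.Categorical(vals, categories=levels)
    X = pd.get_dummies(X, columns=list(categorical_levels), dtype=float)
    # categories absent from the input produce missing dummy columns: add zeros
    X = X.reindex(columns=feature_columns, fill_value=0.0)
    return X.to_numpy(dtype=float)


def tune_mtry(
    train: ModelingTable,
    candidates: list[int] | None = None,
    n_trees_tuning: int = 501,
    seed: int = 0,
) -> tuple[int, pd.DataFrame]:
    """Select mtry by out-of-bag accuracy over candidate values.

    ``candidates`` defaults to every value from 1 to the number of encoded
    predictor columns.  Returns the accuracy-maximizing candidate (ties go
    to the smallest, favouring parsimony) along with the full OOB trace.
    """
    _check_two_classes(train.labels, "tune_mtry")
    X, levels, feature_columns = _encode_fit(train)
    p = X.shape[1]
    if candidates is None:
        candidates = list(range(1, p + 1))
    candidates = sorted(set(int(c) for c in candidates))
    if any(c < 1 or c > p for c in candidates):
        raise ValueError(f"mtry candidates must lie in 1..{p}, got {candidates}")

    records = []
    for m in candidates:
        clf = RandomForestClassifier(
            n_estimators=n_trees_tuning,
            max_features=m,
            oob_score=True,
            random_state=seed,
            n_jobs=1,
        )
        clf.fit(X, train.labels)
        records.append({"mtry": m, "oob_accuracy": float(clf.oob_score_)})
        logger.info("tune_mtry: mtry=%d oob=%.4f", m, clf.oob_score_)
    trace = pd.DataFrame(records)
    best = int(trace.loc[trace["oob_accuracy"].idxmax(), "mtry"])  # first max = smallest
    return best, trace


def fit_forest(train: ModelingTable, spec: ForestSpec) -> FittedForest:
    """Fit the final forest and record its out-of-bag accuracy."""
    if len(train) == 0:
        raise ValueError("training table is empty")
    _check_two_classes(train.labels, "fit_forest")
    X, levels, feature_columns = _encode_fit(train)
    mtry = spec.mtry if spec.mtry is not None else max(1, int(np.sqrt(X.shape[1])))
    if mtry > X.shape[1]:
        raise ValueError(f"mtry={mtry} exceeds the {X.shape[1]} encoded predictors")
    clf = RandomForestClassifier(
        n_estimators=spec.n_trees,
        max_features=mtry,
        oob_score=True,
        random_state=spec.seed,
        n_jobs=1,
    )
    clf.fit(X, train.labels)
    return FittedForest(
        estimator=clf,
        predictor_cols=list(train.predictor_cols),
        categorical_levels=levels,
        feature_columns=feature_columns,
        oob_accuracy=float(clf.oob_score_),
    )


def predict_prob_table(model: FittedForest, data: ModelingTable | pd.DataFrame) -> np.ndarray:
    """Per-row exceedance probability (fraction of trees voting class 1)."""
    frame = data.frame if isinstance(data, ModelingTable) else data
    X = _encode_apply(
        frame, model.predictor_cols, model.categorical_levels, model.feature_columns
    )
    pos = list(model.estimator.classes_).index(1)
    return model.estimator.predict_proba(X)[:, pos]


def predict_class_table(
    model: FittedForest, data: ModelingTable | pd.DataFrame, cutoff: float = 0.5
) -> np.ndarray:
    """Hard class labels at a probability cutoff (1 iff prob > cutoff)."""
    return (predict_prob_table(model, data) > cutoff).astype(np.int64)


def predict_prob_raster(
    model: FittedForest, predictors: dict[str, RasterGrid]
) -> RasterGrid:
    """Exceedance-probability map over a co-registered predictor stack.

    Cells where any predictor is nodata get nodata in the output; every
    other cell receives a probability.
    """
    missing = [c for c in model.predictor_cols if c not in predictors]
    if missing:
        raise ValueError(f"raster stack is missing predictor layers: {missing}")
    rasters = {name: predictors[name] for name in model.predictor_cols}
    require_coregistered(**rasters)
    ref = next(iter(rasters.values()))
    stack = np.stack([rasters[name].data for name in model.predictor_cols], axis=-1)
    valid = ~np.isnan(stack).any(axis=-1)

    out = np.full(ref.spec.shape, np.nan)
    if valid.any():
        frame = pd.DataFrame(
            {name: stack[..., k][valid] for k, name in enumerate(model.predictor_cols)}
        )
        out[valid] = predict_prob_table(model, frame)
    return RasterGrid(ref.spec, out)


def save_forest(model: FittedForest, path: str | Path) -> None:
    """Persist the estimator (joblib) with a JSON schema sidecar."""
    path = Path(path)
    joblib.dump(model.estimator, path)
    sidecar = path.with_suffix(path.suffix + ".schema.json")
    sidecar.write_text(
        json.dumps(
            {
                "predictor_cols": model.predictor_cols,
                "categorical_levels": {
                    k: [int(v) for v in levels]
                    for k, levels in model.categorical_levels.items()
                },
                "feature_columns": model.feature_columns,
                "oob_accuracy": model.oob_accuracy,
            },
            indent=2,
        )
    )


def load_forest(path: str | Path) -> FittedForest:
    path = Path(path)
    estimator = joblib.load(path)
    sidecar = path.with_suffix(path.suffix + ".schema.json")
    meta = json.loads(sidecar.read_text())
    return FittedForest(
        estimator=estimator,
        predictor_cols=meta["predictor_cols"],
        categorical_levels=meta["categorical_levels"],
        feature_columns=meta["feature_columns"],
        oob_accuracy=meta["oob_accuracy"],
    )
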