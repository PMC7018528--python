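"""Random-forest age regression on ASV relative abundances.

The model regresses host chronological age on the feature table, selects
hyperparameters (mtry fraction and minimum leaf size) by k-fold
cross-validated mean absolute error, refits on all samples, and reports
impurity-based feature importances.  Out-of-fold predictions from the
winning configuration are kept so that downstream spline fitting can use
cross-validated rather than resubstitution microbiota ages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

from .exceptions import ConfigurationError, ConsistencyError
from .tables import FeatureTable, align_features

__all__ = [
    "ModelConfig",
    "TrainedAgeModel",
    "PredictionResult",
    "tune_and_train",
    "predict_microbiota_age",
    "mean_absolute_error",
    "feature_importance_ranking",
    "top_k_retrain_curve",
]


@dataclass(frozen=True)
class ModelConfig:
    """Forest size, tuning grid, and cross-validation layout.

    ``mtry_fractions`` are candidate fractions of the feature count tried at
    each split; ``min_node_sizes`` are candidate minimum samples per leaf.
    Ties in CV MAE are broken toward the smaller mtry fraction, then the
    smaller node size.
    """

    n_trees: int = 500
    mtry_fractions: tuple[float, ...] = (0.1, 0.25, 0.33, 0.5)
    min_node_sizes: tuple[int, ...] = (1, 5, 10)
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ConfigurationError("n_trees must be >= 1")
        if self.cv_folds < 2:
            raise ConfigurationError("cv_folds must be >= 2")
        if not self.mtry_fractions or not all(0 < f <= 1 for f in self.mtry_fractions):
            raise ConfigurationError("mtry fractions must lie in (0, 1]")
        if not self.min_node_sizes or not all(s >= 1 for s in self.min_node_sizes):
            raise ConfigurationError("min node sizes must be >= 1")


@dataclass
class TrainedAgeModel:
    forest: RandomForestRegressor
    feature_ids: list[str]
    hyperparameters: dict
    importances: np.ndarray
    cv_mae: float
    cv_predictions: np.ndarray  # out-of-fold microbiota ages, training order
    training_sample_ids: list[str]
    training_age_range: tuple[float, float]


@dataclass
class PredictionResult:
    sample_ids: list[str]
    microbiota_age: np.ndarray
    chronological_age: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        data = {"sample_id": self.sample_ids, "microbiota_age": self.microbiota_age}
        if self.chronological_age is not None:
            data["chronological_age"] = self.chronological_age
        return pd.DataFrame(data)


def mean_absolute_error(predicted: Sequence[float], observed: Sequence[float]) -> float:
    """Mean of |predicted - observed|, in years."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape:
        raise ConsistencyError(f"length mismatch: {p.shape} vs {o.shape}")
    if p.size == 0:
        raise ConsistencyError("MAE of empty vectors is undefined")
    return float(np.mean(np.abs(p - o)))


def _make_forest(n_trees: int, mtry: float, node_size: int, seed: int) -> RandomForestRegressor:
    return RandomForestRegressor(
        n_estimators=n_trees,
        max_features=mtry,
        min_samples_leaf=node_size,
        random_state=seed,
        n_jobs=1,
    )


def _cv_oof_predictions(
    X: np.ndarray,
    y: np.ndarray,
    folds: list[tuple[np.ndarray, np.ndarray]],
    n_trees: int,
    mtry: float,
    node_size: int,
    seed: int,
) -> np.ndarray:
    oof = np.empty_like(y)
    for train_idx, test_idx in folds:
        forest = _make_forest(n_trees, mtry, node_size, seed)
        forest.fit(X[train_idx], y[train_idx])
        oof[test_idx] = forest.predict(X[test_idx])
    return oof


def _check_training_inputs(table: FeatureTable, ages: Sequence[float], config: ModelConfig):
    y = np.asarray(ages, dtype=float)
    if y.shape != (table.n_samples,):
        raise ConsistencyError(
            f"{table.n_samples} samples but {y.size} ages"
        )
    if not np.all(np.isfinite(y)):
        raise ConfigurationError("ages must be finite")
    if table.n_samples < 2 * config.cv_folds:
        raise ConfigurationError(
            f"need at least {2 * config.cv_folds} samples for {config.cv_folds}-fold CV"
        )
    return y


def tune_and_train(
    table: FeatureTable, ages: Sequence[float], config: ModelConfig
) -> TrainedAgeModel:
    """Grid-search hyperparameters by CV MAE, then refit on all samples.

    Fold assignment is a seeded shuffle without age stratification.  The
    whole procedure is deterministic given the config (including its seed).
    """
    y = _check_training_inputs(table, ages, config)
    X = table.values
    folds = list(
        KFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed).split(X)
    )
    best = None  # (mae, mtry, node_size, oof)
    for mtry in sorted(config.mtry_fractions):
        for node_size in sorted(config.min_node_sizes):
            oof = _cv_oof_predictions(
                X, y, folds, config.n_trees, mtry, node_size, config.seed
            )
            mae = mean_absolute_error(oof, y)
            if best is None or mae < best[0]:
                best = (mae, mtry, node_size, oof)
    cv_mae, mtry, node_size, oof = best
    forest = _make_forest(config.n_trees, mtry, node_size, config.seed)
    forest.fit(X, y)
    return TrainedAgeModel(
        forest=forest,
        feature_ids=list(table.feature_ids),
        hyperparameters={
            "n_trees": config.n_trees,
            "mtry_fraction": mtry,
            "min_node_size": node_size,
            "cv_folds": config.cv_folds,
            "seed": config.seed,
        },
        importances=np.asarray(forest.feature_importances_),
        cv_mae=cv_mae,
        cv_predictions=oof,
        training_sample_ids=list(table.sample_ids),
        training_age_range=(float(y.min()), float(y.max())),
    )


def predict_microbiota_age(
    model: TrainedAgeModel,
    table: FeatureTable,
    chronological: Sequence[float] | None = None,
) -> PredictionResult:
    """Predict microbiota age for every sample of ``table``.

    The table is aligned to the model's feature list first (missing features
    zero-filled, extra features dropped).  A table sharing no feature with
    the model is rejected.
    """
    shared = set(model.feature_ids) & set(table.feature_ids)
    if not shared:
        raise ConsistencyError("table shares no features with the trained model")
    aligned = align_features(model.feature_ids, table)
    preds = model.forest.predict(aligned.values)
    chron = None if chronological is None else np.asarray(chronological, dtype=float)
    return PredictionResult(list(table.sample_ids), preds, chron)


def feature_importance_ranking(model: TrainedAgeModel) -> list[tuple[str, float]]:
    """Feature ids by descending importance; ties broken lexicographically."""
    pairs = list(zip(model.feature_ids, model.importances))
    return sorted(pairs, key=lambda p: (-p[1], p[0]))


def _rank_features(feature_ids: list[str], importances: np.ndarray) -> list[int]:
    """Column indices ordered by descending importance, ties by feature id."""
    order = sorted(
        range(len(feature_ids)), key=lambda j: (-importances[j], feature_ids[j])
    )
    return order


def top_k_retrain_curve(
    table: FeatureTable,
    ages: Sequence[float],
    ks: Sequence[int],
    config: ModelConfig,
) -> dict[int, float]:
    """CV MAE after restricting to the top-k most important features.

    The feature ranking is recomputed inside each CV training fold (the
    held-out fold never influences which features are kept), so the curve is
    free of selection leakage.  Hyperparameters are tuned once on the full
    table and reused for every k.  At k equal to the feature count the curve
    reproduces the full model's CV MAE exactly under the same seed.
    """
    ks = list(ks)
    if any(k <= 0 for k in ks):
        raise ConfigurationError("every k must be positive")
    if max(ks) > table.n_features:
        raise ConfigurationError(
            f"k={max(ks)} exceeds the {table.n_features} available features"
        )
    y = _check_training_inputs(table, ages, config)
    X = table.values
    tuned = tune_and_train(table, ages, config)
    mtry = tuned.hyperparameters["mtry_fraction"]
    node_size = tuned.hyperparameters["min_node_size"]
    folds = list(
        KFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed).split(X)
    )
    abs_errors: dict[int, list[np.ndarray]] = {k: [] for k in ks}
    for train_idx, test_idx in folds:
        ranker = _make_forest(config.n_trees, mtry, node_size, config.seed)
        ranker.fit(X[train_idx], y[train_idx])
        order = _rank_features(list(table.feature_ids), ranker.feature_importances_)
        for k in ks:
            keep = np.array(sorted(order[:k]))  # original column order
            forest = _make_forest(config.n_trees, mtry, node_size, config.seed)
            forest.fit(X[np.ix_(train_idx, keep)], y[train_idx])
            preds = forest.predict(X[np.ix_(test_idx, keep)])
            abs_errors[k].append(np.abs(preds - y[test_idx]))
    return {k: float(np.mean(np.concatenate(v))) for k, v in abs_errors.items()}
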