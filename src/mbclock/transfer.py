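"""Cross-stratum model transfer and permutation-null significance.

``stratified_cross_train`` trains an age model inside every level of a
stratifying variable (sex, cohort, body subsite, ...) and evaluates each
model on every other level, yielding a square MAE matrix whose diagonal is
cross-validated (so it is comparable to the off-diagonal transfer entries).

``permutation_null_mae`` asks whether an observed MAE beats chance by
recomputing it under random shuffles of the age labels, either of the test
set (cheap, no retraining) or of the training set (retrain per shuffle).
The empirical p-value uses the add-one estimator, so it is never exactly 0,
and ties with the observed MAE count against significance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ConsistencyError
from .regressor import (
    ModelConfig,
    TrainedAgeModel,
    mean_absolute_error,
    predict_microbiota_age,
    tune_and_train,
)
from .tables import FeatureTable

__all__ = [
    "CrossPredictionResult",
    "PermutationNull",
    "stratified_cross_train",
    "permutation_null_mae",
]


@dataclass
class CrossPredictionResult:
    """Train-stratum x test-stratum MAE matrix with per-entry sample counts."""

    strata: list[str]
    mae: np.ndarray  # (i, j): trained on stratum i, evaluated on stratum j
    n_test: np.ndarray
    models: dict[str, TrainedAgeModel]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.mae, index=self.strata, columns=self.strata)


@dataclass
class PermutationNull:
    observed_mae: float
    null_maes: np.ndarray
    mode: str
    n_perm: int
    p_value: float

    def summary(self) -> dict:
        q = np.quantile(self.null_maes, [0.05, 0.5, 0.95])
        return {
            "observed_mae": self.observed_mae,
            "mode": self.mode,
            "n_perm": self.n_perm,
            "p_value": self.p_value,
            "null_q05": float(q[0]),
            "null_median": float(q[1]),
            "null_q95": float(q[2]),
        }


def stratified_cross_train(
    table: FeatureTable,
    metadata: pd.DataFrame,
    stratify_by: str,
    config: ModelConfig,
) -> CrossPredictionResult:
    """Train within each stratum, evaluate on every stratum.

    Strata are the sorted unique levels of ``metadata[stratify_by]``; each
    level needs at least ``2 * cv_folds`` samples.  Entry (i, j) is
    independent of how many or which other strata are present, because each
    model is trained only on its own stratum with the shared config.
    """
    if stratify_by not in metadata.columns:
        raise ConfigurationError(f"metadata lacks stratification column {stratify_by!r}")
    meta = metadata.set_index("sample_id")
    levels = sorted(meta[stratify_by].astype(str).unique())
    if len(levels) < 2:
        raise ConfigurationError(
            f"stratification column {stratify_by!r} has fewer than 2 levels"
        )
    members: dict[str, list[str]] = {}
    for level in levels:
        ids = meta.index[meta[stratify_by].astype(str) == level].tolist()
        if len(ids) < 2 * config.cv_folds:
            raise ConfigurationError(
                f"stratum {level!r} has {len(ids)} samples; "
                f"needs at least {2 * config.cv_folds}"
            )
        members[level] = ids

    models: dict[str, TrainedAgeModel] = {}
    for level in levels:
        sub = table.select_samples(members[level])
        ages = meta.loc[members[level], "age"].to_numpy(dtype=float)
        models[level] = tune_and_train(sub, ages, config)

    k = len(levels)
    mae = np.zeros((k, k))
    n_test = np.zeros((k, k), dtype=int)
    for i, train_level in enumerate(levels):
        for j, test_level in enumerate(levels):
            if i == j:
                mae[i, j] = models[train_level].cv_mae
                n_test[i, j] = len(members[train_level])
                continue
            test_tab = table.select_samples(members[test_level])
            test_ages = meta.loc[members[test_level], "age"].to_numpy(dtype=float)
            preds = predict_microbiota_age(models[train_level], test_tab)
            mae[i, j] = mean_absolute_error(preds.microbiota_age, test_ages)
            n_test[i, j] = len(members[test_level])
    return CrossPredictionResult(strata=levels, mae=mae, n_test=n_test, models=models)


def permutation_null_mae(
    model_or_train: TrainedAgeModel | tuple[FeatureTable, Sequence[float], ModelConfig],
    test_table: FeatureTable,
    test_ages: Sequence[float],
    n_perm: int = 1000,
    mode: str = "permute_test",
    seed: int = 0,
) -> PermutationNull:
    """Permutation-null distribution of the test-set MAE.

    ``permute_test`` shuffles the test ages against fixed predictions (no
    retraining).  ``permute_train`` retrains on shuffled training ages for
    every permutation and evaluates each null model on the intact test set;
    it requires ``model_or_train`` to be a ``(table, ages, config)`` tuple.
    Empirical p = (1 + #{null MAE <= observed}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ConfigurationError("n_perm must be >= 1")
    if mode not in ("permute_test", "permute_train"):
        raise ConfigurationError(f"unknown permutation mode: {mode!r}")
    y_test = np.asarray(test_ages, dtype=float)
    if y_test.size != test_table.n_samples:
        raise ConsistencyError("test ages do not match test table samples")
    rng = np.random.default_rng(seed)

    if isinstance(model_or_train, TrainedAgeModel):
        model = model_or_train
        train_data = None
    else:
        train_table, train_ages, config = model_or_train
        model = tune_and_train(train_table, train_ages, config)
        train_data = (train_table, np.asarray(train_ages, dtype=float), config)

    preds = predict_microbiota_age(model, test_table).microbiota_age
    observed = mean_absolute_error(preds, y_test)

    null = np.empty(n_perm)
    if mode == "permute_test":
        for i in range(n_perm):
            null[i] = mean_absolute_error(preds, rng.permutation(y_test))
    else:
        if train_data is None:
            raise ConfigurationError(
                "permute_train mode needs (train_table, train_ages, config), "
                "not an already-trained model"
            )
        train_table, y_train, config = train_data
        for i in range(n_perm):
            shuffled = rng.permutation(y_train)
            null_model = tune_and_train(train_table, shuffled, config)
            null_preds = predict_microbiota_age(null_model, test_table).microbiota_age
            null[i] = mean_absolute_error(null_preds, y_test)

    p = (1 + int(np.sum(null <= observed))) / (n_perm + 1)
    return PermutationNull(
        observed_mae=observed, null_maes=null, mode=mode, n_perm=n_perm, p_value=p
    )
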