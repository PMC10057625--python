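"""Per-subject ensemble-tree regression of BGL from cycle features.

Day-wise train/test split (default days 1-7 train, 8-9 test), seeded
randomized hyperparameter search scored by 5-fold cross-validated RMSE
with folds grouped by recording (cycles from one recording never straddle
train/validation within a fold), over bagged trees and least-squares
gradient boosting. Predictions are per cycle, then aggregated per
recording (mean or median) for clinical evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor

from ppglucose.cycles import FEATURE_NAMES

#: glucometer measuring interval used to clip predictions, mg/dL
PREDICTION_MIN, PREDICTION_MAX = 10.0, 600.0


@dataclass(frozen=True)
class SplitSpec:
    """Day-wise train/test split plus CV fold count."""

    train_days: Tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7)
    test_days: Tuple[int, ...] = (8, 9)
    cv_folds: int = 5

    def __post_init__(self) -> None:
        if set(self.train_days) & set(self.test_days):
            raise ValueError("train and test days must be disjoint")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass(frozen=True)
class HyperparameterSpace:
    """Search ranges for the two ensemble methods (inclusive bounds)."""

    n_learners: Tuple[int, int] = (10, 500)
    min_leaf_size: Tuple[int, int] = (1, 18)
    n_predictors_to_sample: Tuple[int, int] = (1, 19)  # bag only
    learning_rate: Tuple[float, float] = (0.01, 1.0)  # lsboost only


@dataclass
class TrainedModel:
    """Fitted ensemble with the hyperparameters chosen by CV."""

    subject_id: str
    method: str  # "bag" or "lsboost"
    hyperparameters: Dict[str, float]
    cv_rmse: float
    estimator: object
    feature_names: Tuple[str, ...] = FEATURE_NAMES


def split_by_day(
    table: pd.DataFrame, spec: SplitSpec = SplitSpec()
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Route cycle rows into train/test sets by their recording day."""
    if "day" not in table.columns:
        raise ValueError("feature table must have a 'day' column")
    train = table[table["day"].isin(spec.train_days)]
    test = table[table["day"].isin(spec.test_days)]
    if len(train) == 0 or len(test) == 0:
        raise ValueError(
            f"empty split: {len(train)} train rows, {len(test)} test rows"
        )
    return train, test


def _make_estimator(method: str, params: Dict[str, float], seed: int):
    if method == "bag":
        return RandomForestRegressor(
            n_estimators=int(params["n_learners"]),
            min_samples_leaf=int(params["min_leaf_size"]),
            max_features=int(params["n_predictors_to_sample"]),
            bootstrap=True,
            random_state=seed,
            n_jobs=1,
        )
    if method == "lsboost":
        return GradientBoostingRegressor(
            n_estimators=int(params["n_learners"]),
            min_samples_leaf=int(params["min_leaf_size"]),
            learning_rate=float(params["learning_rate"]),
            loss="squared_error",
            random_state=seed,
        )
    raise ValueError(f"unknown method {method!r}")


def _draw_params(
    method: str, space: HyperparameterSpace, n_features: int, rng: np.random.Generator
) -> Dict[str, float]:
    params: Dict[str, float] = {
        "n_learners": int(rng.integers(space.n_learners[0], space.n_learners[1] + 1)),
        "min_leaf_size": int(
            rng.integers(space.min_leaf_size[0], space.min_leaf_size[1] + 1)
        ),
    }
    if method == "bag":
        hi = min(space.n_predictors_to_sample[1], n_features)
        lo = min(space.n_predictors_to_sample[0], hi)
        params["n_predictors_to_sample"] = int(rng.integers(lo, hi + 1))
    else:
        lo, hi = space.learning_rate
        params["learning_rate"] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    return params


def _group_folds(
    groups: np.ndarray, n_folds: int, rng: np.random.Generator
) -> List[np.ndarray]:
    """Row masks of CV folds; whole recordings are assigned to folds."""
    unique = np.unique(groups)
    if len(unique) >= n_folds:
        perm = rng.permutation(unique)
        chunks = np.array_split(perm, n_folds)
        return [np.isin(groups, chunk) for chunk in chunks]
    # fewer recordings than folds: fall back to row-level folds
    idx = rng.permutation(len(groups))
    return [np.isin(np.arange(len(groups)), part) for part in np.array_split(idx, n_folds)]


def tune_and_train(
    train: pd.DataFrame,
    subject_id: str = "",
    space: HyperparameterSpace = HyperparameterSpace(),
    methods: Sequence[str] = ("bag", "lsboost"),
    folds: int = 5,
    seed: int = 0,
    n_draws: int = 6,
    tuning_subsample: int | None = 1500,
    feature_names: Sequence[str] = FEATURE_NAMES,
    target_col: str = "bgl_label",
    group_col: str = "recording_id",
) -> TrainedModel:
    """Seeded randomized search over both ensemble methods; best CV RMSE wins.

    Each draw is scored by the mean RMSE over ``folds`` cross-validation
    folds grouped by recording; the winning configuration is refit on the
    full training set. For speed the CV scoring may run on a seeded row
    subsample (``tuning_subsample``); the final refit always uses all rows.
    """
    if len(train) < 2 * folds:
        raise ValueError("not enough training rows for cross-validation")
    y_all = train[target_col].to_numpy(dtype=float)
    if np.ptp(y_all) == 0:
        raise ValueError("degenerate single-valued training target")
    missing = [f for f in feature_names if f not in train.columns]
    if missing:
        raise ValueError(f"missing feature columns: {missing}")

    rng = np.random.default_rng(seed)
    X_all = train[list(feature_names)].to_numpy(dtype=float)
    groups_all = (
        train[group_col].to_numpy()
        if group_col in train.columns
        else np.arange(len(train))
    )

    if tuning_subsample is not None and len(train) > tuning_subsample:
        sub = rng.choice(len(train), size=tuning_subsample, replace=False)
        sub.sort()
    else:
        sub = np.arange(len(train))
    X, y, groups = X_all[sub], y_all[sub], groups_all[sub]
    fold_masks = _group_folds(groups, folds, rng)

    best: Tuple[float, str, Dict[str, float]] | None = None
    for method in methods:
        for _ in range(n_draws):
            params = _draw_params(method, space, len(feature_names), rng)
            errors = []
            for mask in fold_masks:
                if mask.all() or not mask.any():
                    continue
                est = _make_estimator(method, params, seed)
                est.fit(X[~mask], y[~mask])
                pred = est.predict(X[mask])
                errors.append(float(np.sqrt(np.mean((pred - y[mask]) ** 2))))
            score = float(np.mean(errors))
            if best is None or score < best[0]:
                best = (score, method, params)

    assert best is not None
    cv_rmse, method, params = best
    final = _make_estimator(method, params, seed)
    final.fit(X_all, y_all)
    return TrainedModel(
        subject_id=subject_id,
        method=method,
        hyperparameters=params,
        cv_rmse=cv_rmse,
        estimator=final,
        feature_names=tuple(feature_names),
    )


def predict(model: TrainedModel, rows: pd.DataFrame) -> np.ndarray:
    """Per-cycle BGL predictions, clipped to the glucometer interval."""
    missing = [f for f in model.feature_names if f not in rows.columns]
    if missing:
        raise ValueError(f"missing feature columns: {missing}")
    X = rows[list(model.feature_names)].to_numpy(dtype=float)
    pred = np.asarray(model.estimator.predict(X), dtype=float)
    if not np.all(np.isfinite(pred)):
        raise ValueError("non-finite predictions")
    return np.clip(pred, PREDICTION_MIN, PREDICTION_MAX)


def aggregate_predictions(
    rows: pd.DataFrame,
    predictions: np.ndarray,
    group_col: str = "recording_id",
    stat: str = "mean",
    reference_col: str = "bgl_label",
) -> pd.DataFrame:
    """One (reference, predicted) pair per recording (mean or median of cycles)."""
    if stat not in ("mean", "median"):
        raise ValueError("stat must be 'mean' or 'median'")
    work = rows[[group_col, reference_col]].copy()
    for extra in ("subject_id", "day", "timepoint_min"):
        if extra in rows.columns:
            work[extra] = rows[extra]
    work["predicted_bgl"] = np.asarray(predictions, dtype=float)
    agg = {reference_col: "first", "predicted_bgl": stat}
    for extra in ("subject_id", "day", "timepoint_min"):
        if extra in work.columns:
            agg[extra] = "first"
    out = work.groupby(group_col, sort=True).agg(agg).reset_index()
    return out.rename(columns={reference_col: "reference_bgl"})
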