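"""Machine-learning stack: preprocessing, RFE, baselines and GBM+RF stacking.

The pipeline z-scores descriptors (statistics learned on training data
only), reduces the descriptor table by recursive feature elimination under a
random-forest estimator, and compares baseline learners — linear (ridge),
decision tree, random forest, gradient boosting, optional neural network —
against a stacked hybrid in which a gradient-boosting machine produces a
score that a random forest consumes as an additional feature.

Two stacking modes are first-class and explicitly labeled:

* ``oof`` (default): the RF meta-learner trains on *out-of-fold* GBM scores,
  so the meta-feature for each training row comes from a model that never
  saw that row.  This is the leakage-safe construction.
* ``naive``: the RF trains on in-sample GBM scores.  This mirrors a literal
  two-stage reading of "GBM scores used as RF input" and demonstrates the
  optimistic bias such leakage produces; its training R^2 approaches 1.

All estimators use the published default hyperparameters (GBM: learning
rate 0.1, 100 stages, depth 3, subsample 1.0, squared error; RF: 100 trees,
squared error, unlimited depth, sqrt feature sampling, bootstrap).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.feature_selection import RFE
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold, cross_val_predict, cross_val_score
from sklearn.neural_network import MLPRegressor
from sklearn.tree import DecisionTreeRegressor

from .validation_stats import (DegenerateTargetError, ValidationReport,
                               q2_kfold, regression_metrics)


@dataclass
class MLConfig:
    """Hyperparameters for every learner plus CV/RFE settings."""

    gbm_learning_rate: float = 0.1
    gbm_n_stages: int = 100
    gbm_max_depth: int = 3
    gbm_subsample: float = 1.0
    rf_n_trees: int = 100
    rf_max_features: str = "sqrt"
    dt_max_depth: Optional[int] = None
    linear_alpha: float = 1.0          # L2 strength of the ridge baseline
    ann_hidden: int = 100
    ann_learning_rate: float = 0.001
    ann_max_iter: int = 200
    rfe_n_keep: int = 30
    rfe_step: int = 1
    rfe_cv_folds: int = 5
    cv_folds: int = 5
    cv_repeats: int = 1

    def validate(self) -> None:
        if not (0 < self.gbm_learning_rate and 0 < self.gbm_subsample <= 1):
            raise ValueError("rates must lie in (0, 1]")
        for count in (self.gbm_n_stages, self.rf_n_trees, self.rfe_n_keep,
                      self.rfe_step, self.cv_folds, self.cv_repeats):
            if count < 1:
                raise ValueError("counts must be >= 1")


DEFAULT_CONFIG = MLConfig()


def make_gbm(config: MLConfig = DEFAULT_CONFIG, seed: int = 0
             ) -> GradientBoostingRegressor:
    return GradientBoostingRegressor(
        loss="squared_error", learning_rate=config.gbm_learning_rate,
        n_estimators=config.gbm_n_stages, max_depth=config.gbm_max_depth,
        subsample=config.gbm_subsample, random_state=seed)


def make_rf(config: MLConfig = DEFAULT_CONFIG, seed: int = 0
            ) -> RandomForestRegressor:
    return RandomForestRegressor(
        n_estimators=config.rf_n_trees, criterion="squared_error",
        max_depth=None, min_samples_split=2, min_samples_leaf=1,
        bootstrap=True, max_features=config.rf_max_features, random_state=seed)


def make_baseline(name: str, config: MLConfig = DEFAULT_CONFIG, seed: int = 0):
    """Instantiate a named baseline with the default hyperparameters."""
    if name == "linear":
        return Ridge(alpha=config.linear_alpha)
    if name == "dt":
        return DecisionTreeRegressor(criterion="squared_error",
                                     max_depth=config.dt_max_depth,
                                     min_samples_split=2, min_samples_leaf=1,
                                     random_state=seed)
    if name == "rf":
        return make_rf(config, seed)
    if name == "gbm":
        return make_gbm(config, seed)
    if name == "ann":
        return MLPRegressor(hidden_layer_sizes=(config.ann_hidden,),
                            activation="relu", solver="adam",
                            learning_rate_init=config.ann_learning_rate,
                            max_iter=config.ann_max_iter, random_state=seed)
    raise ValueError(f"unknown model name {name!r}")


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

@dataclass
class ZScoreStats:
    mean: np.ndarray
    sd: np.ndarray
    constant_columns: np.ndarray   # boolean mask of zero-variance columns


def zscore(X_train: np.ndarray, X_apply: Optional[np.ndarray] = None
           ) -> tuple[np.ndarray, Optional[np.ndarray], ZScoreStats]:
    """Column-wise (x - mean)/sd with statistics learned on X_train only.

    The standard deviation uses the population convention (denominator n).
    Zero-variance columns are centered but not scaled, with a warning.
    """
    X_train = np.asarray(X_train, dtype=float)
    mean = X_train.mean(axis=0)
    sd = X_train.std(axis=0, ddof=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} zero-variance column(s) centered only: "
            f"{np.flatnonzero(constant).tolist()}", stacklevel=2)
    scale = np.where(constant, 1.0, sd)
    stats = ZScoreStats(mean=mean, sd=sd, constant_columns=constant)
    X_train_std = (X_train - mean) / scale
    X_apply_std = None
    if X_apply is not None:
        X_apply_std = (np.asarray(X_apply, dtype=float) - mean) / scale
    return X_train_std, X_apply_std, stats


# ---------------------------------------------------------------------------
# Recursive feature elimination
# ---------------------------------------------------------------------------

def rfe_select(X: np.ndarray, y: np.ndarray,
               config: MLConfig = DEFAULT_CONFIG, seed: int = 0,
               record_cv: bool = False
               ) -> tuple[np.ndarray, Optional[float]]:
    """Recursive feature elimination to ``config.rfe_n_keep`` descriptors.

    Iteratively fits the random-forest estimator and removes the
    lowest-importance feature (step = ``config.rfe_step``) until ``n_keep``
    remain.  Returns the sorted 0-based indices of the retained columns and,
    when ``record_cv`` is set, the k-fold CV score (R^2) of the estimator on
    the selected columns.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    p = X.shape[1]
    if p < config.rfe_n_keep:
        raise ValueError(f"p={p} < n_keep={config.rfe_n_keep}")
    if p == config.rfe_n_keep:
        selected = np.arange(p)
    else:
        selector = RFE(estimator=make_rf(config, seed),
                       n_features_to_select=config.rfe_n_keep,
                       step=config.rfe_step)
        selector.fit(X, y)
        selected = np.flatnonzero(selector.support_)
    score = None
    if record_cv:
        cv = KFold(n_splits=config.rfe_cv_folds, shuffle=True, random_state=seed)
        score = float(np.mean(cross_val_score(
            make_rf(config, seed), X[:, selected], y, cv=cv, scoring="r2")))
    return np.sort(selected), score


# ---------------------------------------------------------------------------
# Baselines
# ---------------------------------------------------------------------------

def train_baseline(name: str, X: np.ndarray, y: np.ndarray,
                   config: MLConfig = DEFAULT_CONFIG, seed: int = 0):
    """Fit a named baseline; returns (fitted model, ValidationReport)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.size < 10:
        raise ValueError(f"need at least 10 samples, got {y.size}")
    model = make_baseline(name, config, seed)
    model.fit(X, y)
    metrics = regression_metrics(y, model.predict(X))
    report = ValidationReport(
        r2=metrics["r2"], mse=metrics["mse"], mae=metrics["mae"],
        rmse=metrics["rmse"],
        q2_kfold=q2_kfold(make_baseline(name, config, seed), X, y,
                          folds=config.cv_folds, repeats=config.cv_repeats,
                          seed=seed),
        n_train=int(y.size), folds=config.cv_folds, seed=seed)
    return model, report


# ---------------------------------------------------------------------------
# GBM -> RF stacking
# ---------------------------------------------------------------------------

class StackedGBMRF(BaseEstimator, RegressorMixin):
    """Two-stage stack: GBM base learner, RF meta-learner.

    ``mode='oof'`` feeds the RF out-of-fold GBM scores during training;
    ``mode='naive'`` feeds in-sample scores (target leakage, retained
    deliberately for comparison).  ``feature_mode='append'`` gives the RF
    the descriptors plus the score column; ``'score-only'`` gives it the
    1-D score alone.  Prediction always computes the GBM score first and
    routes it through the RF.
    """

    def __init__(self, mode: str = "oof", feature_mode: str = "append",
                 folds: int = 5, seed: int = 0,
                 config: MLConfig = DEFAULT_CONFIG):
        self.mode = mode
        self.feature_mode = feature_mode
        self.folds = folds
        self.seed = seed
        self.config = config

    def _meta_features(self, X: np.ndarray, score: np.ndarray) -> np.ndarray:
        if self.feature_mode == "append":
            return np.column_stack([X, score])
        if self.feature_mode == "score-only":
            return score.reshape(-1, 1)
        raise ValueError(f"unknown feature_mode {self.feature_mode!r}")

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if np.std(y) == 0:
            raise DegenerateTargetError("constant target")
        if self.mode not in ("oof", "naive"):
            raise ValueError(f"unknown stacking mode {self.mode!r}")
        gbm = make_gbm(self.config, self.seed)
        if self.mode == "oof":
            cv = KFold(n_splits=self.folds, shuffle=True, random_state=self.seed)
            train_score = cross_val_predict(clone(gbm), X, y, cv=cv)
        self.base_ = gbm.fit(X, y)           # refit on all rows for inference
        if self.mode == "naive":
            train_score = self.base_.predict(X)
        self.meta_ = make_rf(self.config, self.seed).fit(
            self._meta_features(X, train_score), y)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        score = self.base_.predict(X)
        return self.meta_.predict(self._meta_features(X, score))


@dataclass
class StackedModel:
    """Fitted stack plus its training report and feature layout."""

    estimator: StackedGBMRF
    mode: str
    feature_mode: str
    selected_indices: Optional[np.ndarray]
    training_report: ValidationReport

    @property
    def meta_input_dim(self) -> int:
        return self.estimator.meta_.n_features_in_


def train_stack_gbm_rf(X: np.ndarray, y: np.ndarray, mode: str = "oof",
                       feature_mode: str = "append",
                       config: MLConfig = DEFAULT_CONFIG, seed: int = 0,
                       selected_indices: Optional[Sequence[int]] = None
                       ) -> StackedModel:
    """Train the GBM+RF stack and report training metrics plus k-fold Q^2."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    estimator = StackedGBMRF(mode=mode, feature_mode=feature_mode,
                             folds=config.cv_folds, seed=seed, config=config)
    estimator.fit(X, y)
    metrics = regression_metrics(y, estimator.predict(X))
    report = ValidationReport(
        r2=metrics["r2"], mse=metrics["mse"], mae=metrics["mae"],
        rmse=metrics["rmse"],
        q2_kfold=q2_kfold(StackedGBMRF(mode=mode, feature_mode=feature_mode,
                                       folds=config.cv_folds, seed=seed,
                                       config=config),
                          X, y, folds=config.cv_folds,
                          repeats=config.cv_repeats, seed=seed),
        n_train=int(y.size), folds=config.cv_folds, seed=seed)
    return StackedModel(estimator=estimator, mode=mode,
                        feature_mode=feature_mode,
                        selected_indices=(None if selected_indices is None
                                          else np.asarray(selected_indices)),
                        training_report=report)


def evaluate_models(X: np.ndarray, y: np.ndarray,
                    model_names: Sequence[str] = ("linear", "dt", "rf", "gbm"),
                    include_stack: bool = True,
                    config: MLConfig = DEFAULT_CONFIG, seed: int = 0
                    ) -> pd.DataFrame:
    """Fit every requested model and tabulate R2, MSE, MAE, RMSE, Q2.

    Metrics are computed identically across models: R2/MSE/MAE/RMSE on the
    training fit, Q2 from pooled out-of-fold residuals.
    """
    if len(model_names) + int(include_stack) < 2:
        raise ValueError("need at least 2 models to compare")
    rows = []
    for name in model_names:
        _, report = train_baseline(name, X, y, config=config, seed=seed)
        rows.append((name, report.r2, report.mse, report.mae, report.rmse,
                     report.q2_kfold))
    if include_stack:
        stack = train_stack_gbm_rf(X, y, config=config, seed=seed)
        r = stack.training_report
        rows.append((f"gbm+rf ({stack.mode})", r.r2, r.mse, r.mae, r.rmse,
                     r.q2_kfold))
    return pd.DataFrame(rows, columns=["Model", "R2", "MSE", "MAE", "RMSE", "Q2"])
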