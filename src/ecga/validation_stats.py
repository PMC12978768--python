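"""Scalar validation statistics for QSAR models.

PRESS is the predictive residual sum of squares over held-out predictions;
q2 = 1 - PRESS/SSY is the cross-validated coefficient of prediction, with
SSY the total sum of squares of the experimental values about their mean.
Two external-set variants differ only in the denominator: ext1 references
the training-set mean, ext2 the test-set mean.  R^2 is reported as the
squared Pearson correlation; the coefficient-of-determination reading is
available through the q2-style functions, so both conventions are exposed
without ambiguity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Callable, Optional, Sequence

import numpy as np
from sklearn.base import clone
from sklearn.model_selection import KFold


class DegenerateTargetError(ValueError):
    """The target has zero variance, so a variance-normalized statistic is
    undefined."""


def _pair(y, yhat) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.size == 0:
        raise ValueError("empty input")
    return y, yhat


def press(y_exp, y_calc) -> float:
    """Sum of squared residuals between experimental and predicted values."""
    y, yhat = _pair(y_exp, y_calc)
    return float(np.sum((y - yhat) ** 2))


def ssy(y_exp) -> float:
    """Total sum of squares of y about its mean."""
    y = np.asarray(y_exp, dtype=float)
    return float(np.sum((y - y.mean()) ** 2))


def q2_loo(y_exp, y_calc_loo) -> float:
    """q2 = 1 - PRESS/SSY over leave-one-out predictions."""
    y, yhat = _pair(y_exp, y_calc_loo)
    if y.size < 2:
        raise ValueError("q2 needs at least 2 observations")
    denom = ssy(y)
    if denom == 0:
        raise DegenerateTargetError("experimental values have zero variance")
    return 1.0 - press(y, yhat) / denom


def q2_external(y_test, y_calc, train_mean: Optional[float] = None,
                variant: str = "ext1") -> float:
    """External-set q2.

    ``ext1`` normalizes by sum((y_test - train_mean)^2) and requires
    ``train_mean``; ``ext2`` normalizes by the test-set total sum of squares.
    """
    y, yhat = _pair(y_test, y_calc)
    if variant == "ext1":
        if train_mean is None:
            raise ValueError("ext1 requires the training-set mean")
        denom = float(np.sum((y - float(train_mean)) ** 2))
    elif variant == "ext2":
        if y.size < 2:
            raise ValueError("ext2 needs at least 2 test observations")
        denom = ssy(y)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    if denom == 0:
        raise DegenerateTargetError(f"zero denominator for {variant}")
    return 1.0 - press(y, yhat) / denom


def regression_metrics(y, yhat) -> dict[str, float]:
    """R^2 (squared Pearson correlation), MSE, MAE and RMSE.

    R^2 is NaN when either vector is constant (correlation undefined).
    """
    y, yhat = _pair(y, yhat)
    if y.size < 2:
        raise ValueError("metrics need at least 2 observations")
    resid = y - yhat
    mse = float(np.mean(resid ** 2))
    if np.std(y) == 0 or np.std(yhat) == 0:
        r2 = math.nan
    else:
        r2 = float(np.corrcoef(y, yhat)[0, 1] ** 2)
    return {"r2": r2, "mse": mse, "mae": float(np.mean(np.abs(resid))),
            "rmse": math.sqrt(mse)}


def q2_kfold(model, X, y, folds: int = 5, repeats: int = 1,
             seed: int = 0) -> float:
    """Out-of-fold Q^2 = 1 - sum((y - yhat_oof)^2) / SSY over shuffled,
    seeded k-fold splits, averaged over ``repeats``.

    ``model`` is any scikit-learn style regressor (cloned per fold).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.size < folds or folds < 2:
        raise ValueError(f"need n >= folds >= 2, got n={y.size}, folds={folds}")
    denom = ssy(y)
    if denom == 0:
        raise DegenerateTargetError("target has zero variance")
    scores = []
    for r in range(repeats):
        kf = KFold(n_splits=folds, shuffle=True, random_state=seed + r)
        oof = np.empty_like(y)
        for train_idx, test_idx in kf.split(X):
            est = clone(model)
            est.fit(X[train_idx], y[train_idx])
            oof[test_idx] = est.predict(X[test_idx])
        scores.append(1.0 - float(np.sum((y - oof) ** 2)) / denom)
    return float(np.mean(scores))


@dataclass
class ValidationReport:
    """Bundle of the scalar statistics for one model/dataset pairing."""

    press: Optional[float] = None
    ssy: Optional[float] = None
    q2: Optional[float] = None
    q2_ext1: Optional[float] = None
    q2_ext2: Optional[float] = None
    r2: Optional[float] = None
    mse: Optional[float] = None
    mae: Optional[float] = None
    rmse: Optional[float] = None
    q2_kfold: Optional[float] = None
    n_train: Optional[int] = None
    n_test: Optional[int] = None
    folds: Optional[int] = None
    seed: Optional[int] = None

    def to_dict(self) -> dict:
        return {k: ("undefined" if v is None or
                    (isinstance(v, float) and math.isnan(v)) else v)
                for k, v in asdict(self).items()}


def internal_report(y_exp, y_calc_loo, seed: Optional[int] = None
                    ) -> ValidationReport:
    """PRESS/SSY/q2 plus pointwise metrics from LOO predictions."""
    y, yhat = _pair(y_exp, y_calc_loo)
    metrics = regression_metrics(y, yhat)
    return ValidationReport(
        press=press(y, yhat), ssy=ssy(y), q2=q2_loo(y, yhat),
        r2=metrics["r2"], mse=metrics["mse"], mae=metrics["mae"],
        rmse=metrics["rmse"], n_train=int(y.size), seed=seed)


def external_report(y_test, y_calc, train_mean: float,
                    seed: Optional[int] = None) -> ValidationReport:
    """External-set statistics under both q2 variants."""
    y, yhat = _pair(y_test, y_calc)
    metrics = regression_metrics(y, yhat) if y.size >= 2 else {
        "r2": math.nan, "mse": float(np.mean((y - yhat) ** 2)),
        "mae": float(np.mean(np.abs(y - yhat))),
        "rmse": float(np.sqrt(np.mean((y - yhat) ** 2)))}
    try:
        ext2 = q2_external(y, yhat, variant="ext2")
    except (ValueError, DegenerateTargetError):
        ext2 = math.nan
    return ValidationReport(
        press=press(y, yhat),
        q2_ext1=q2_external(y, yhat, train_mean=train_mean, variant="ext1"),
        q2_ext2=ext2, r2=metrics["r2"], mse=metrics["mse"], mae=metrics["mae"],
        rmse=metrics["rmse"], n_test=int(y.size), seed=seed)
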