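"""Performance measures for the surrogate: R², aRRMSE, aRelErr, MAE,
min/last-RSA extraction, and cross-validation aggregation.

R² is pooled over every (sample, day) pair.  The average relative
root-mean-squared error (aRRMSE) averages, over the 365 output days, the
per-day RMSE normalized by the day's deviation from its mean — values
below 0.1 are conventionally read as excellent multi-target regression.
The average relative error (aRelErr) is the flat mean of |error|/|target|
over all entries (well defined because RSA > 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .errors import ConfigurationError

__all__ = ["r_squared", "arrmse", "arelerr", "mae", "min_last_rsa",
           "characteristic_block", "MetricsReport", "evaluate"]


def _as_arrays(targets, predictions) -> Tuple[np.ndarray, np.ndarray]:
    y = np.asarray(targets, dtype=float)
    yh = np.asarray(predictions, dtype=float)
    if y.shape != yh.shape:
        raise ConfigurationError(
            f"targets {y.shape} and predictions {yh.shape} differ in shape")
    return y, yh


def r_squared(targets, predictions) -> float:
    """Goodness of fit 1 - sum(e²)/sum((y - ȳ)²), pooled over all entries.

    May be negative when the residuals exceed the targets' own spread.
    Constant targets leave the denominator zero and are rejected.
    """
    y, yh = _as_arrays(targets, predictions)
    if y.size < 2:
        raise ConfigurationError("R² needs at least two values")
    denom = np.sum((y - y.mean()) ** 2)
    if denom <= 0:
        raise ConfigurationError("R² undefined for constant targets")
    return float(1.0 - np.sum((y - yh) ** 2) / denom)


def arrmse(targets, predictions) -> float:
    """Average relative RMSE over target columns.

    For each output dimension j: sqrt(sum_i e_ij² / sum_i (y_ij - ȳ_j)²),
    then the flat mean over j.  The column-mean predictor scores exactly 1.
    """
    y, yh = _as_arrays(targets, predictions)
    y = np.atleast_2d(y)
    yh = np.atleast_2d(yh)
    denom = np.sum((y - y.mean(axis=0)) ** 2, axis=0)
    bad = np.flatnonzero(denom <= 0)
    if bad.size:
        raise ConfigurationError(
            f"aRRMSE undefined: constant target column(s) {bad[:5].tolist()}")
    ratios = np.sqrt(np.sum((y - yh) ** 2, axis=0) / denom)
    return float(ratios.mean())


def arelerr(targets, predictions) -> float:
    """Mean of |error| / |target| over all entries (targets must be nonzero)."""
    y, yh = _as_arrays(targets, predictions)
    if np.any(y == 0):
        raise ConfigurationError("aRelErr undefined for zero targets")
    return float(np.mean(np.abs(y - yh) / np.abs(y)))


def mae(targets, predictions) -> float:
    """Mean absolute error over all entries."""
    y, yh = _as_arrays(targets, predictions)
    return float(np.mean(np.abs(y - yh)))


def min_last_rsa(rsa_course) -> Tuple[float, float]:
    """(minimum RSA, last RSA) of one course.

    The minimum marks maximum contraction during healing; the last value is
    the 'asymptotic' permanent contraction after remodeling.
    """
    course = np.asarray(rsa_course, dtype=float)
    if course.size == 0:
        raise ConfigurationError("empty RSA course")
    return float(course.min()), float(course[-1])


def characteristic_block(targets: np.ndarray, predictions: np.ndarray) -> Dict:
    """Per-characteristic metrics for the minimum and last RSA values:
    R², MAE, plus min/max/range/average of the target distribution."""
    y = np.atleast_2d(np.asarray(targets, float))
    yh = np.atleast_2d(np.asarray(predictions, float))
    out = {}
    for name, ty, py in (
        ("min_rsa", y.min(axis=1), yh.min(axis=1)),
        ("last_rsa", y[:, -1], yh[:, -1]),
    ):
        lo, hi = float(ty.min()), float(ty.max())
        out[name] = {
            "r2": r_squared(ty, py),
            "mae": mae(ty, py),
            "min": lo,
            "max": hi,
            "range": hi - lo,
            "average": float(ty.mean()),
        }
    return out


@dataclass
class MetricsReport:
    """Cross-validation (mean ± sd over folds) and held-out test metrics."""

    cv_mean: Dict[str, float]
    cv_sd: Dict[str, float]
    test: Dict[str, float]
    characteristics: Dict[str, Dict[str, float]]
    fold_scores: Dict[str, List[float]] = field(default_factory=dict)

    def to_dict(self) -> Dict:
        return {
            "cv_mean": self.cv_mean,
            "cv_sd": self.cv_sd,
            "test": self.test,
            "characteristics": self.characteristics,
            "fold_scores": self.fold_scores,
        }

    def format_table(self) -> str:
        """Human-readable summary mirroring the performance tables."""
        lines = ["Performance measure   Cross-validation value   Test value"]
        for key, label in (("r2", "R^2"), ("arrmse", "aRRMSE"),
                           ("arelerr", "aRelErr")):
            lines.append(
                f"{label:<21} {self.cv_mean[key]:.4f} +/- "
                f"{self.cv_sd[key]:.4f}        {self.test[key]:.4f}")
        lines.append("")
        lines.append("Characteristic   R^2     MAE     Min     Max     "
                     "Range   Average")
        for name, row in self.characteristics.items():
            lines.append(
                f"{name:<16} {row['r2']:.4f}  {row['mae']:.4f}  "
                f"{row['min']:.4f}  {row['max']:.4f}  {row['range']:.4f}  "
                f"{row['average']:.4f}")
        return "\n".join(lines)


def _metric_dict(y: np.ndarray, yh: np.ndarray) -> Dict[str, float]:
    return {"r2": r_squared(y, yh), "arrmse": arrmse(y, yh),
            "arelerr": arelerr(y, yh)}


def evaluate(fold_models: Sequence, final_model, split,
             predict_fn=None) -> MetricsReport:
    """Score fold models on their validation folds and the final model on
    the held-out test set.

    ``split`` is a :class:`scarnet.dataset.SplitData`; fold k's model is
    evaluated on the fold's validation indices (data it never fitted).
    Fold scores are aggregated as mean ± sample standard deviation (ddof=1).
    """
    if len(fold_models) != len(split.folds):
        raise ConfigurationError(
            f"{len(split.folds)} folds but {len(fold_models)} fold models")
    if predict_fn is None:
        predict_fn = lambda m, X: m.forward(X)  # noqa: E731 - scaled inputs

    fold_scores: Dict[str, List[float]] = {"r2": [], "arrmse": [], "arelerr": []}
    for model, (_, val_idx) in zip(fold_models, split.folds):
        yh = predict_fn(model, split.X_train[val_idx])
        scores = _metric_dict(split.Y_train[val_idx], yh)
        for k, v in scores.items():
            fold_scores[k].append(v)

    cv_mean = {k: float(np.mean(v)) for k, v in fold_scores.items()}
    cv_sd = {k: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
             for k, v in fold_scores.items()}

    yh_test = predict_fn(final_model, split.X_test)
    test = _metric_dict(split.Y_test, yh_test)
    characteristics = characteristic_block(split.Y_test, yh_test)

    return MetricsReport(cv_mean=cv_mean, cv_sd=cv_sd, test=test,
                         characteristics=characteristics,
                         fold_scores=fold_scores)
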