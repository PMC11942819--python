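"""Support-vector-regression benchmark on (deviation, MH) pairs.

Six fixed presets — linear, quadratic, cubic, and fine/medium/coarse
Gaussian — are cross-validated with k-fold CV and compared on RMSE, R²,
and the Pearson correlation of pooled held-out predictions with the
observations.  Preset hyperparameters follow the conventions of the
point-and-click regression tools these names come from: for P predictors
the Gaussian kernel scales are √P/4, √P and 4√P (ratio 1:4:16), the box
constraint is IQR(y)/1.349, the epsilon tube IQR(y)/13.49, and predictors
are standardized on each training fold.  A kernel scale s corresponds to
the RBF coefficient gamma = 1/s².
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.stats import iqr
from sklearn.model_selection import KFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .exceptions import ValidationError

__all__ = [
    "SVRPreset",
    "BenchmarkResult",
    "PRESET_NAMES",
    "make_preset",
    "default_presets",
    "cv_benchmark",
    "run_full_benchmark",
]

PRESET_NAMES = (
    "linear",
    "quadratic",
    "cubic",
    "fine_gaussian",
    "medium_gaussian",
    "coarse_gaussian",
)

_GAUSSIAN_SCALE_FACTOR = {"fine_gaussian": 0.25, "medium_gaussian": 1.0, "coarse_gaussian": 4.0}
_POLY_DEGREE = {"linear": 1, "quadratic": 2, "cubic": 3}


@dataclass(frozen=True)
class SVRPreset:
    """One named SVR configuration.

    ``kernel`` is "poly" (degree 1-3, kernel (1 + x'z)^degree) or
    "gaussian"; ``kernel_scale`` divides the (standardized) predictors
    inside the Gaussian kernel.
    """

    name: str
    kernel: str
    degree: int = 1
    kernel_scale: float = 1.0
    box_constraint: float = 1.0
    epsilon: float = 0.1
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.kernel not in ("poly", "gaussian"):
            raise ValidationError(f"kernel must be 'poly' or 'gaussian', got {self.kernel!r}")
        if self.kernel_scale <= 0 or self.box_constraint <= 0 or self.epsilon <= 0:
            raise ValidationError("kernel_scale, box_constraint and epsilon must be positive")
        if self.kernel == "poly" and self.degree not in (1, 2, 3):
            raise ValidationError(f"polynomial degree must be 1, 2 or 3, got {self.degree}")

    def estimator(self) -> SVR:
        if self.kernel == "gaussian":
            return SVR(
                kernel="rbf",
                gamma=1.0 / self.kernel_scale**2,
                C=self.box_constraint,
                epsilon=self.epsilon,
            )
        if self.degree == 1:
            return SVR(kernel="linear", C=self.box_constraint, epsilon=self.epsilon)
        return SVR(
            kernel="poly",
            degree=self.degree,
            gamma=1.0,
            coef0=1.0,
            C=self.box_constraint,
            epsilon=self.epsilon,
        )


def make_preset(name: str, y, n_predictors: int = 1) -> SVRPreset:
    """Build a named preset with data-driven box constraint and epsilon."""
    if name not in PRESET_NAMES:
        raise ValidationError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    y = np.asarray(y, dtype=float)
    spread = float(iqr(y))
    if spread == 0:  # degenerate target: fall back to a unit box
        spread = 1.349
    box = spread / 1.349
    eps = spread / 13.49
    if name in _POLY_DEGREE:
        return SVRPreset(
            name=name, kernel="poly", degree=_POLY_DEGREE[name],
            box_constraint=box, epsilon=eps,
        )
    scale = _GAUSSIAN_SCALE_FACTOR[name] * np.sqrt(n_predictors)
    return SVRPreset(
        name=name, kernel="gaussian", kernel_scale=scale,
        box_constraint=box, epsilon=eps,
    )


def default_presets(y, n_predictors: int = 1) -> list[SVRPreset]:
    return [make_preset(n, y, n_predictors) for n in PRESET_NAMES]


@dataclass(frozen=True)
class BenchmarkResult:
    """Pooled cross-validated performance of one preset."""

    preset: str
    rmse: float
    r2: float
    pearson_r: float
    fold_assignments: np.ndarray
    seed: int
    predictions: np.ndarray

    def __post_init__(self) -> None:
        if self.rmse < 0:
            raise ValidationError("rmse must be nonnegative")


def _fold_indices(n: int, k: int, seed: int) -> np.ndarray:
    folds = np.empty(n, dtype=int)
    for f, (_, test) in enumerate(KFold(n_splits=k, shuffle=True, random_state=seed).split(np.zeros(n))):
        folds[test] = f
    return folds


def _degenerate(v: np.ndarray) -> bool:
    return bool(np.ptp(v) <= 1e-12 * max(1.0, float(np.abs(v).max())))


def _pooled_metrics(y: np.ndarray, pred: np.ndarray) -> tuple[float, float, float]:
    resid = y - pred
    rmse = float(np.sqrt(np.mean(resid**2)))
    if _degenerate(y):  # constant target: R² and r are undefined
        return rmse, float("nan"), float("nan")
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / sst
    r = float(np.corrcoef(y, pred)[0, 1]) if not _degenerate(pred) else float("nan")
    return rmse, r2, r


def cv_benchmark(
    x,
    y,
    preset: SVRPreset | str,
    k: int = 5,
    seed: int = 0,
    fold_assignments: np.ndarray | None = None,
) -> BenchmarkResult:
    """k-fold cross-validated RMSE / R² / Pearson r for one preset.

    Points are randomly partitioned into ``k`` folds by ``seed`` (or an
    explicit assignment vector); each fold is predicted by a model trained
    on the remaining folds, and the metrics are computed on the pooled
    held-out predictions.  A constant target makes R² and r undefined
    (returned as NaN).
    """
    x = np.asarray(x, dtype=float).reshape(-1, 1) if np.ndim(x) == 1 else np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if len(x) != n:
        raise ValidationError("x and y must have equal length")
    if k < 2 or k > n:
        raise ValidationError(f"need 2 <= k <= n folds; got k={k}, n={n}")
    if isinstance(preset, str):
        preset = make_preset(preset, y, x.shape[1])
    folds = _fold_indices(n, k, seed) if fold_assignments is None else np.asarray(fold_assignments)
    if len(folds) != n or set(np.unique(folds)) != set(range(k)):
        raise ValidationError("fold_assignments must place every point in one of k folds")
    pred = np.empty(n, dtype=float)
    for f in range(k):
        test = folds == f
        train = ~test
        xt, yt = x[train], y[train]
        if preset.standardize:
            scaler = StandardScaler().fit(xt)
            # constant training column: leave it unscaled rather than divide by 0
            scaler.scale_[scaler.scale_ == 0] = 1.0
            model = preset.estimator().fit(scaler.transform(xt), yt)
            pred[test] = model.predict(scaler.transform(x[test]))
        else:
            model = preset.estimator().fit(xt, yt)
            pred[test] = model.predict(x[test])
    rmse, r2, r = _pooled_metrics(y, pred)
    return BenchmarkResult(
        preset=preset.name, rmse=rmse, r2=r2, pearson_r=r,
        fold_assignments=folds, seed=seed, predictions=pred,
    )


def run_full_benchmark(
    x, y, seed: int = 0, k: int = 5, presets: Sequence[SVRPreset | str] | None = None
) -> list[BenchmarkResult]:
    """Benchmark all six presets on identical fold assignments."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    folds = _fold_indices(n, k, seed)
    if presets is None:
        presets = list(PRESET_NAMES)
    return [
        cv_benchmark(x, y, p, k=k, seed=seed, fold_assignments=folds) for p in presets
    ]
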