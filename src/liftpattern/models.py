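"""Model/Results facades over the deviation-similarity analyses.

Three estimators share a statsmodels-like shape: construct the model from
data (arrays or a DataFrame via ``from_dataframe``), call :meth:`fit`, and
read estimates, diagnostics and a ``summary()`` table off the returned
results object.

* :class:`QuadraticTrend` — OLS quadratic of MH similarity on deviation.
* :class:`FuzzyScoringModel` — 18-rule zero-order Sugeno system whose rule
  constants are calibrated to observed (deviation, MH) pairs by linear
  least squares.
* :class:`SVRBenchmark` — the six-preset cross-validated SVR comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import fuzzy as fz
from . import stats as st
from . import svm as sv
from .exceptions import ValidationError

__all__ = [
    "QuadraticTrend",
    "QuadraticTrendResults",
    "FuzzyScoringModel",
    "FuzzyScoringResults",
    "SVRBenchmark",
    "SVRBenchmarkResults",
]


def _as_xy(deviation, mh) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(deviation, dtype=float)
    y = np.asarray(mh, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("deviation and mh must be 1-D arrays of equal length")
    return x, y


class _PairsModel:
    """Shared constructor logic for models fitted on (deviation, MH) pairs."""

    def __init__(self, deviation, mh):
        self.deviation, self.mh = _as_xy(deviation, mh)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, deviation: str = "deviation_cm", mh: str = "mh", **kw
    ):
        return cls(df[deviation].to_numpy(), df[mh].to_numpy(), **kw)


# --------------------------------------------------------------------------
# quadratic trend


class QuadraticTrend(_PairsModel):
    """OLS quadratic trend  mh = a·dev² + b·dev + c."""

    def fit(self) -> "QuadraticTrendResults":
        return QuadraticTrendResults(self, st.quadratic_fit(self.deviation, self.mh))


@dataclass(frozen=True)
class QuadraticTrendResults:
    model: QuadraticTrend
    fit_: st.QuadraticFit

    @property
    def params(self) -> np.ndarray:
        return self.fit_.params

    @property
    def bse(self) -> np.ndarray:
        return np.asarray(self.fit_.bse)

    @property
    def rsquared(self) -> float:
        return self.fit_.r2

    @property
    def pearson_r(self) -> float:
        return self.fit_.r

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict(self.model.deviation)

    @property
    def resid(self) -> np.ndarray:
        return self.model.mh - self.fittedvalues

    def predict(self, deviation) -> np.ndarray:
        return self.fit_.predict(deviation)

    def summary(self) -> str:
        f = self.fit_
        lines = [
            "Quadratic deviation-similarity trend (OLS)",
            "=" * 46,
            f"  n observations      {f.nobs}",
            f"  a (dev², cm⁻²)      {f.a: .6e}   se {f.bse[0]:.2e}",
            f"  b (dev, cm⁻¹)       {f.b: .6e}   se {f.bse[1]:.2e}",
            f"  c (intercept)       {f.c: .6f}   se {f.bse[2]:.2e}",
            f"  R²                  {f.r2: .4f}",
            f"  Pearson r (obs,fit) {f.r: .4f}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Scatter of the pairs with the fitted trend curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x, y = self.model.deviation, self.model.mh
        ax.scatter(x, y, s=18, label="observed")
        grid = np.linspace(0, max(x.max(), 25.0), 200)
        ax.plot(grid, self.predict(grid), color="C1", label="quadratic trend")
        ax.set_xlabel("absolute vertical deviation (cm)")
        ax.set_ylabel("Morisita-Horn index")
        ax.legend()
        return ax


# --------------------------------------------------------------------------
# fuzzy scoring


class FuzzyScoringModel(_PairsModel):
    """Sugeno fuzzy scorer calibrated to observed (deviation, MH) pairs.

    The observations are taken at a single load level (default 50 % body
    weight); fitting re-estimates the rule constants by linear least
    squares while keeping the membership functions fixed.
    """

    def __init__(self, deviation, mh, load: float = 50.0, config: fz.FISConfig | None = None):
        super().__init__(deviation, mh)
        self.load = float(load)
        self.config = config or fz.build_default_fis()

    def fit(self) -> "FuzzyScoringResults":
        pairs = np.column_stack([self.deviation, self.mh])
        calibrated = fz.calibrate_output_constants(self.config, pairs, load=self.load)
        r2, r = fz.fis_fit_metrics(calibrated, pairs, load=self.load)
        return FuzzyScoringResults(self, calibrated, r2, r)


@dataclass(frozen=True)
class FuzzyScoringResults:
    model: FuzzyScoringModel
    config: fz.FISConfig
    rsquared: float
    pearson_r: float

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict(self.model.deviation)

    @property
    def resid(self) -> np.ndarray:
        return self.model.mh - self.fittedvalues

    def predict(self, deviation, load: float | None = None) -> np.ndarray:
        load = self.model.load if load is None else load
        return np.array(
            [fz.evaluate_fis(self.config, d, load).similarity for d in np.atleast_1d(deviation)]
        )

    def score(self, deviation: float, load: float | None = None) -> fz.FuzzyScore:
        """Full fuzzy score (similarity, category, rule activations)."""
        return fz.evaluate_fis(self.config, deviation, self.model.load if load is None else load)

    def summary(self) -> str:
        lines = [
            "Sugeno fuzzy scoring system (calibrated constants)",
            "=" * 50,
            f"  rules               {self.config.n_rules}",
            f"  calibration load    {self.model.load:g} % body weight",
            f"  n observations      {len(self.model.mh)}",
            f"  R²                  {self.rsquared: .4f}",
            f"  Pearson r           {self.pearson_r: .4f}",
            "  constants (dev level x load level):",
        ]
        for j, mf in enumerate(self.config.dev_mfs):
            row = "  ".join(f"{c:.5f}" for c in self.config.constants[j])
            lines.append(f"    {mf.name:<12s} {row}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Observed MH vs the fuzzy system's output over the deviation range."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x, y = self.model.deviation, self.model.mh
        ax.scatter(x, y, s=18, label="observed MH")
        grid = np.linspace(*self.config.dev_domain, 200)
        ax.plot(grid, self.predict(grid), color="C2", label="fuzzy output")
        ax.set_xlabel("absolute vertical deviation (cm)")
        ax.set_ylabel("similarity")
        ax.legend()
        return ax


# --------------------------------------------------------------------------
# SVR benchmark


class SVRBenchmark(_PairsModel):
    """Cross-validated comparison of the six SVR presets."""

    def fit(
        self, folds: int = 5, seed: int = 0, repeats: int = 1, presets=None
    ) -> "SVRBenchmarkResults":
        """Run the benchmark; ``repeats`` > 1 averages over consecutive seeds
        (seed, seed+1, ...), each repeat using one fold partition shared by
        all presets."""
        rows = []
        for rep in range(repeats):
            for res in sv.run_full_benchmark(
                self.deviation, self.mh, seed=seed + rep, k=folds, presets=presets
            ):
                rows.append(
                    {
                        "preset": res.preset,
                        "seed": res.seed,
                        "rmse": res.rmse,
                        "r2": res.r2,
                        "pearson_r": res.pearson_r,
                    }
                )
        return SVRBenchmarkResults(self, pd.DataFrame(rows), folds=folds)


@dataclass(frozen=True)
class SVRBenchmarkResults:
    model: SVRBenchmark
    runs: pd.DataFrame  # one row per preset x seed
    folds: int

    @property
    def table(self) -> pd.DataFrame:
        """Seed-averaged rmse / r2 / pearson_r per preset, in preset order."""
        agg = self.runs.groupby("preset")[["rmse", "r2", "pearson_r"]].mean()
        return agg.reindex([p for p in sv.PRESET_NAMES if p in agg.index])

    @property
    def best_preset(self) -> str:
        """Preset with the lowest seed-averaged RMSE."""
        return str(self.table["rmse"].idxmin())

    def win_fraction(self, preset: str) -> float:
        """Fraction of seeds in which ``preset`` has the lowest RMSE."""
        wins = self.runs.loc[self.runs.groupby("seed")["rmse"].idxmin(), "preset"]
        return float((wins == preset).mean())

    def summary(self) -> str:
        lines = [
            f"SVR benchmark ({self.folds}-fold CV, "
            f"{self.runs['seed'].nunique()} seed(s))",
            "=" * 52,
            self.table.to_string(float_format=lambda v: f"{v:.5f}"),
            f"best preset by RMSE: {self.best_preset}",
        ]
        return "\n".join(lines)
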