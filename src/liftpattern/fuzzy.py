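"""Zero-order Sugeno fuzzy scoring of execution quality.

A Takagi-Sugeno system with constant consequents maps the pair (maximum
absolute vertical deviation in cm, load in % body weight) to a similarity
score on the Morisita-Horn scale.  The deviation universe [0, 25] cm is
partitioned by six Gaussian membership functions (very low ... high), the
load universe by three (L0, L25, L50); the full 6 x 3 rule grid therefore
has 18 rules.  Rule strength is the product t-norm of the two memberships
and the crisp output is the weighted average of the rule constants
(weighted-average defuzzification).  Scores are mapped onto five
performance categories over the output range [0.97, 1.0].

Rule constants default to the quadratic deviation-similarity trend and can
be re-estimated from observed (deviation, MH) pairs by linear least
squares: the Sugeno output is linear in its constants, so calibration is a
projection, not an iterative fit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .exceptions import CalibrationError, ValidationError

__all__ = [
    "GaussianMF",
    "FISConfig",
    "FuzzyScore",
    "DEFAULT_CATEGORIES",
    "build_default_fis",
    "evaluate_fis",
    "classify",
    "calibrate_output_constants",
    "fis_fit_metrics",
]

DEV_LEVEL_NAMES = ("very low", "low", "low medium", "medium", "medium high", "high")
LOAD_LEVEL_NAMES = ("L0", "L25", "L50")
DEFAULT_CATEGORIES = (
    "Total Error",
    "Medium Error",
    "Average Execution",
    "Medium Accuracy",
    "Total Accuracy",
)
DEV_DOMAIN = (0.0, 25.0)
OUTPUT_RANGE = (0.97, 1.0)

# half-overlap spacing: adjacent MFs cross at membership 0.5 when
# sigma = spacing / (2 * sqrt(2 ln 2))
HALF_OVERLAP_SIGMA = 5.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

# quadratic deviation->similarity trend used to seed the rule constants
TREND_COEF = (-3.1026e-5, -4.1535e-4, 1.0013)  # a, b, c


def _trend(x):
    a, b, c = TREND_COEF
    return a * np.asarray(x, dtype=float) ** 2 + b * np.asarray(x, dtype=float) + c


@dataclass(frozen=True)
class GaussianMF:
    """Gaussian membership function exp(-(v-center)²/(2 sigma²))."""

    center: float
    sigma: float
    name: str = ""

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValidationError(f"sigma must be positive, got {self.sigma}")

    def __call__(self, v) -> np.ndarray | float:
        v = np.asarray(v, dtype=float)
        out = np.exp(-((v - self.center) ** 2) / (2.0 * self.sigma**2))
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class FISConfig:
    """A zero-order Sugeno system over (deviation, load).

    ``constants`` is the 6 x 3 grid of rule consequents, row j the
    deviation level, column l the load level; the rule IF dev is level j
    AND load is level l THEN similarity = constants[j, l].
    """

    dev_mfs: tuple[GaussianMF, ...]
    load_mfs: tuple[GaussianMF, ...]
    constants: np.ndarray  # shape (n_dev, n_load)
    output_range: tuple[float, float] = OUTPUT_RANGE
    category_thresholds: tuple[float, ...] = ()
    categories: tuple[str, ...] = DEFAULT_CATEGORIES
    dev_domain: tuple[float, float] = DEV_DOMAIN

    def __post_init__(self) -> None:
        object.__setattr__(self, "constants", np.asarray(self.constants, dtype=float))
        nd, nl = len(self.dev_mfs), len(self.load_mfs)
        if self.constants.shape != (nd, nl):
            raise ValidationError(
                f"constants must be shaped ({nd}, {nl}), got {self.constants.shape}"
            )
        if not self.category_thresholds:
            lo, hi = self.output_range
            width = (hi - lo) / len(self.categories)
            object.__setattr__(
                self,
                "category_thresholds",
                tuple(lo + width * k for k in range(1, len(self.categories))),
            )
        if len(self.category_thresholds) != len(self.categories) - 1:
            raise ValidationError("need one threshold fewer than categories")
        if np.any(np.diff(self.category_thresholds) <= 0):
            raise ValidationError("category thresholds must be strictly increasing")
        lo = min(self.output_range) - 0.01
        hi = max(TREND_COEF[2], max(self.output_range))
        if self.constants.min() < lo - 1e-12 or self.constants.max() > hi + 1e-12:
            raise ValidationError(
                f"rule constants must lie within [{lo:.4f}, {hi:.4f}]; "
                f"got [{self.constants.min():.4f}, {self.constants.max():.4f}]"
            )

    @property
    def n_rules(self) -> int:
        return self.constants.size

    def rules(self) -> list[tuple[str, str, float]]:
        """The 18 rules as (deviation level, load level, constant)."""
        return [
            (d.name, l.name, float(self.constants[j, k]))
            for j, d in enumerate(self.dev_mfs)
            for k, l in enumerate(self.load_mfs)
        ]

    def rule_weights(self, dev: float, load: float) -> np.ndarray:
        """Product-t-norm firing strengths, shaped like ``constants``."""
        dev = float(np.clip(dev, *self.dev_domain))
        wd = np.array([mf(dev) for mf in self.dev_mfs])
        wl = np.array([mf(load) for mf in self.load_mfs])
        return wd[:, None] * wl[None, :]

    # -- JSON round-trip ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "dev_mfs": [{"center": m.center, "sigma": m.sigma, "name": m.name} for m in self.dev_mfs],
            "load_mfs": [{"center": m.center, "sigma": m.sigma, "name": m.name} for m in self.load_mfs],
            "constants": self.constants.tolist(),
            "output_range": list(self.output_range),
            "category_thresholds": list(self.category_thresholds),
            "categories": list(self.categories),
            "dev_domain": list(self.dev_domain),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "FISConfig":
        return cls(
            dev_mfs=tuple(GaussianMF(**m) for m in d["dev_mfs"]),
            load_mfs=tuple(GaussianMF(**m) for m in d["load_mfs"]),
            constants=np.asarray(d["constants"], dtype=float),
            output_range=tuple(d.get("output_range", OUTPUT_RANGE)),
            category_thresholds=tuple(d.get("category_thresholds", ())),
            categories=tuple(d.get("categories", DEFAULT_CATEGORIES)),
            dev_domain=tuple(d.get("dev_domain", DEV_DOMAIN)),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "FISConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class FuzzyScore:
    similarity: float
    category: str
    rule_activations: np.ndarray  # (n_dev, n_load) firing strengths


def build_default_fis(
    dev_sigma: float = HALF_OVERLAP_SIGMA, load_sigma: float = 10.6
) -> FISConfig:
    """The default 18-rule system.

    Deviation MF centers sit at 0, 5, ..., 25 cm with a common sigma such
    that adjacent functions cross at membership 0.5; load MF centers at
    0, 25, 50 % body weight.  Each rule constant is seeded from the
    quadratic trend evaluated at the deviation center scaled by load/50
    (so the no-load column scores ~1 and the load-50 column follows the
    trend), clamped to at most 1.
    """
    dev_centers = np.linspace(*DEV_DOMAIN, len(DEV_LEVEL_NAMES))
    load_centers = np.array([0.0, 25.0, 50.0])
    dev_mfs = tuple(
        GaussianMF(center=c, sigma=dev_sigma, name=n)
        for c, n in zip(dev_centers, DEV_LEVEL_NAMES)
    )
    load_mfs = tuple(
        GaussianMF(center=c, sigma=load_sigma, name=n)
        for c, n in zip(load_centers, LOAD_LEVEL_NAMES)
    )
    constants = np.minimum(1.0, _trend(dev_centers[:, None] * load_centers[None, :] / 50.0))
    return FISConfig(dev_mfs=dev_mfs, load_mfs=load_mfs, constants=constants)


def evaluate_fis(config: FISConfig, deviation: float, load: float) -> FuzzyScore:
    """Weighted-average (Sugeno) inference for one input pair.

    Deviations above the domain ceiling clamp to it; the output is the
    activation-weighted mean of the rule constants, hence always a convex
    combination of them.
    """
    if not np.isfinite(deviation) or not np.isfinite(load):
        raise ValidationError("deviation and load must be finite numbers")
    if deviation < 0:
        raise ValidationError(f"deviation must be nonnegative, got {deviation}")
    if load < 0:
        raise ValidationError(f"load must be nonnegative, got {load}")
    w = config.rule_weights(deviation, load)
    similarity = float((w * config.constants).sum() / w.sum())
    return FuzzyScore(
        similarity=similarity,
        category=classify(similarity, config),
        rule_activations=w,
    )


def classify(similarity: float, config: FISConfig | None = None) -> str:
    """Map a similarity score to one of the five performance categories.

    The output range is split at the config's thresholds (default: five
    equal-width bins over [0.97, 1.0]); scores below the range fall in the
    lowest category.
    """
    # scores may exceed 1 by up to the trend intercept's overshoot (1.0013)
    if not (0.0 <= similarity <= TREND_COEF[2] + 1e-12):
        raise ValidationError(
            f"similarity must lie in [0, {TREND_COEF[2]}], got {similarity}"
        )
    cfg = config or build_default_fis()
    idx = int(np.searchsorted(cfg.category_thresholds, similarity, side="right"))
    return cfg.categories[idx]


def calibrate_output_constants(
    config: FISConfig, pairs: Sequence[tuple[float, float]], load: float = 50.0
) -> FISConfig:
    """Re-estimate the rule constants from observed (deviation, MH) pairs.

    The observations live at one load level (default 50 %).  Because the
    Sugeno output is linear in the constants, the load-50 column is the
    least-squares solution of observed MH on the normalized rule-activation
    basis; the other load columns keep their default proportion to the
    load-50 constant of the same deviation level (the proportions are
    folded into the design matrix, so the calibrated system reproduces the
    least-squares fit at the calibration load exactly).
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValidationError("pairs must be an (n, 2) array of (deviation, mh)")
    n_dev = len(config.dev_mfs)
    if len(pairs) < n_dev + 1:
        raise ValidationError(
            f"need more pairs ({len(pairs)}) than free constants ({n_dev}) to calibrate"
        )
    load_idx = int(np.argmin([abs(m.center - load) for m in config.load_mfs]))
    base = config.constants[:, load_idx]
    if np.any(base == 0):
        raise CalibrationError("zero constant at the calibration load; cannot form ratios")
    ratios = config.constants / base[:, None]  # (n_dev, n_load), calibration column == 1

    design = np.empty((len(pairs), n_dev))
    for i, (dev, _) in enumerate(pairs):
        w = config.rule_weights(dev, load)
        design[i] = (ratios * w).sum(axis=1) / w.sum()
    if np.linalg.matrix_rank(design) < n_dev:
        raise CalibrationError(
            "singular activation basis: deviations do not excite all membership "
            "functions; widen the MF sigmas or supply more spread-out pairs"
        )
    c_cal, *_ = np.linalg.lstsq(design, pairs[:, 1], rcond=None)
    constants = ratios * c_cal[:, None]
    # guard against pathological targets pushing constants out of the valid band
    lo = min(config.output_range) - 0.01
    hi = max(TREND_COEF[2], max(config.output_range))
    constants = np.clip(constants, lo, hi)
    return replace(config, constants=constants)


def fis_fit_metrics(
    config: FISConfig, pairs: Sequence[tuple[float, float]], load: float = 50.0
) -> tuple[float, float]:
    """(R², Pearson r) of the system's outputs against observed MH values.

    Returns NaN for r when the observed values have zero variance.
    """
    pairs = np.asarray(pairs, dtype=float)
    if len(pairs) < 2:
        raise ValidationError("need at least 2 pairs")
    pred = np.array([evaluate_fis(config, d, load).similarity for d in pairs[:, 0]])
    obs = pairs[:, 1]
    if np.ptp(obs) <= 1e-12:
        return float("nan"), float("nan")
    sst = ((obs - obs.mean()) ** 2).sum()
    r2 = 1.0 - ((obs - pred) ** 2).sum() / sst
    r = float(np.corrcoef(obs, pred)[0, 1]) if np.ptp(pred) > 1e-12 else float("nan")
    return float(r2), r
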