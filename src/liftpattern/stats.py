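"""Quadratic deviation-similarity trend, one-way ANOVA, and Tukey HSD.

The deviation-to-similarity relation is summarised by an ordinary
least-squares quadratic y = a x² + b x + c (statsmodels OLS under the
hood), reported with R² and the Pearson correlation between observed and
fitted values.  Group comparisons of maximum displacements use a classical
one-way ANOVA with Tukey's HSD post hoc, available both from raw samples
and from published (mean, SD, n) summaries — the latter reconstructs the
identical F from the sufficient statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

from .exceptions import ValidationError

__all__ = [
    "QuadraticFit",
    "AnovaResult",
    "TukeyComparison",
    "quadratic_fit",
    "one_way_anova",
    "anova_from_summary",
]


@dataclass(frozen=True)
class QuadraticFit:
    """OLS fit of y = a x² + b x + c with goodness-of-fit measures."""

    a: float
    b: float
    c: float
    r2: float
    r: float  # Pearson correlation between observed and fitted
    nobs: int
    bse: tuple[float, float, float] = (np.nan, np.nan, np.nan)  # SEs of (a, b, c)

    @property
    def params(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c])

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.a * x**2 + self.b * x + self.c


@dataclass(frozen=True)
class TukeyComparison:
    pair: tuple[int, int]
    mean_diff: float
    q_stat: float
    p_adj: float


@dataclass(frozen=True)
class AnovaResult:
    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    tukey: tuple[TukeyComparison, ...] = ()
    group_means: tuple[float, ...] = ()

    def significant_pairs(self, alpha: float = 0.05) -> list[tuple[int, int]]:
        return [c.pair for c in self.tukey if c.p_adj < alpha]


def quadratic_fit(x, y) -> QuadraticFit:
    """Least-squares quadratic trend of similarity on deviation.

    Requires at least four points and a non-constant predictor.  R² is
    1 − SS_res/SS_tot; ``r`` is the Pearson correlation between observed
    and fitted values (equal to +√R² for a fit with intercept).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValidationError("x and y must be 1-D arrays of equal length")
    if len(x) < 4:
        raise ValidationError(f"need at least 4 points, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValidationError("all x values identical: quadratic design is rank-deficient")
    design = np.column_stack([x**2, x, np.ones_like(x)])
    res = sm.OLS(y, design).fit()
    fitted = res.fittedvalues
    r = float(np.corrcoef(y, fitted)[0, 1]) if np.ptp(fitted) > 0 else float("nan")
    return QuadraticFit(
        a=float(res.params[0]),
        b=float(res.params[1]),
        c=float(res.params[2]),
        r2=float(res.rsquared),
        r=r,
        nobs=int(res.nobs),
        bse=tuple(float(v) for v in res.bse),
    )


def _tukey_from_moments(
    means: np.ndarray, ns: np.ndarray, msw: float, df_within: int
) -> tuple[TukeyComparison, ...]:
    """Tukey HSD from group means, sizes and the pooled within-group MS.

    Unequal group sizes use the Tukey-Kramer harmonic-mean correction; the
    adjusted p comes from the studentized-range distribution.
    """
    k = len(means)
    comps = []
    for i, j in combinations(range(k), 2):
        diff = means[i] - means[j]
        se = np.sqrt(msw / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
        q = abs(diff) / se if se > 0 else np.inf
        p = float(sps.studentized_range.sf(q, k, df_within)) if np.isfinite(q) else 0.0
        comps.append(TukeyComparison(pair=(i, j), mean_diff=float(diff), q_stat=float(q), p_adj=min(1.0, p)))
    return tuple(comps)


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Classical one-way ANOVA with Tukey HSD on raw samples."""
    if len(groups) < 2:
        raise ValidationError(f"need at least 2 groups, got {len(groups)}")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for idx, g in enumerate(arrays):
        if len(g) < 2:
            raise ValidationError(f"group {idx} has n={len(g)} < 2")
    f_stat, p_value = sps.f_oneway(*arrays)
    k = len(arrays)
    n_total = sum(len(g) for g in arrays)
    dfb, dfw = k - 1, n_total - k
    means = np.array([g.mean() for g in arrays])
    ns = np.array([len(g) for g in arrays])
    ssw = sum(((g - g.mean()) ** 2).sum() for g in arrays)
    msw = ssw / dfw
    if not np.isfinite(f_stat):  # zero within-group variance edge case
        grand = np.concatenate(arrays).mean()
        ssb = float((ns * (means - grand) ** 2).sum())
        f_stat = np.inf if ssb > 0 else 0.0
        p_value = 0.0 if ssb > 0 else 1.0
    return AnovaResult(
        f_stat=float(f_stat),
        df_between=dfb,
        df_within=dfw,
        p_value=float(p_value),
        tukey=_tukey_from_moments(means, ns, msw, dfw),
        group_means=tuple(float(m) for m in means),
    )


def anova_from_summary(means, sds, ns) -> AnovaResult:
    """One-way ANOVA reconstructed from per-group (mean, SD, n).

    SSB is rebuilt from the group means and sizes, SSW from (n−1)·SD², so
    the F statistic is identical to :func:`one_way_anova` applied to any
    raw data having these summaries.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    ns = np.asarray(ns, dtype=float)
    if not (means.shape == sds.shape == ns.shape) or means.ndim != 1:
        raise ValidationError("means, sds, ns must be 1-D and of equal length")
    if len(means) < 2:
        raise ValidationError("need at least 2 groups")
    if np.any(ns < 2):
        raise ValidationError("every group needs n >= 2")
    k = len(means)
    n_total = ns.sum()
    dfb, dfw = k - 1, int(n_total - k)
    grand = float((ns * means).sum() / n_total)
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(((ns - 1) * sds**2).sum())
    msb = ssb / dfb
    msw = ssw / dfw
    if msw == 0:
        f_stat = np.inf if ssb > 0 else 0.0
        p_value = 0.0 if ssb > 0 else 1.0
    else:
        f_stat = msb / msw
        p_value = float(sps.f.sf(f_stat, dfb, dfw))
    return AnovaResult(
        f_stat=float(f_stat),
        df_between=dfb,
        df_within=dfw,
        p_value=p_value,
        tukey=_tukey_from_moments(means, ns, msw, dfw) if msw > 0 else (),
        group_means=tuple(float(m) for m in means),
    )
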