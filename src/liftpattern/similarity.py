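"""No-load reference profiles, deviations, and the Morisita-Horn index.

The analysis compares every loaded execution of an exercise against the
subject's own unloaded technique: the three bar-only executions define
MMD0 (the mean of their maximum displacements) and a time-normalized mean
reference trajectory.  An execution is then summarised by (i) the absolute
and relative deviation of its maximum displacement from MMD0 and (ii) a
Morisita-Horn overlap index between its displacement sequence and the
reference's, treating the resampled displacement magnitudes as abundance
vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError
from .trajectory import DisplacementSummary, MarkerTrajectory, max_displacement, RepetitionSegment

__all__ = [
    "ReferenceProfile",
    "SimilarityRecord",
    "resample",
    "reference_profile",
    "deviation",
    "morisita_horn",
    "execution_similarity",
]

DEFAULT_N_POINTS = 101

_AXES = ("horizontal", "vertical")


def _check_axis(axis: str) -> None:
    if axis not in _AXES:
        raise ValidationError(f"axis must be one of {_AXES}, got {axis!r}")


def resample(traj: MarkerTrajectory, n_points: int) -> tuple[np.ndarray, np.ndarray]:
    """Linearly resample (x, y) onto ``n_points`` points of normalized time.

    Time is mapped to [0, 1] using the trajectory's own span, so executions
    of different durations become comparable point-by-point.
    """
    if n_points < 2:
        raise ValidationError(f"n_points must be >= 2, got {n_points}")
    t = traj.t
    span = t[-1] - t[0]
    if span <= 0:
        raise ValidationError("trajectory has zero time span; cannot resample")
    u = (t - t[0]) / span
    grid = np.linspace(0.0, 1.0, n_points)
    return np.interp(grid, u, traj.x), np.interp(grid, u, traj.y)


@dataclass(frozen=True)
class ReferenceProfile:
    """Subject-specific no-load reference.

    ``mmd0_dx`` / ``mmd0_dy`` are the means of the no-load maximum
    displacements (MMD0); ``mean_x`` / ``mean_y`` the pointwise mean of the
    time-normalized no-load trajectories (cm, first point at the origin).
    """

    mmd0_dx: float
    mmd0_dy: float
    mean_x: np.ndarray
    mean_y: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean_x", np.asarray(self.mean_x, dtype=float))
        object.__setattr__(self, "mean_y", np.asarray(self.mean_y, dtype=float))
        if self.mmd0_dx < 0 or self.mmd0_dy < 0:
            raise ValidationError("MMD0 values must be nonnegative")
        n = len(self.mean_x)
        if n != len(self.mean_y) or n < 2:
            raise ValidationError("mean trajectory needs >= 2 points of equal length")

    @property
    def n_points(self) -> int:
        return len(self.mean_x)

    def mmd0(self, axis: str) -> float:
        _check_axis(axis)
        return self.mmd0_dy if axis == "vertical" else self.mmd0_dx

    def mean_axis(self, axis: str) -> np.ndarray:
        _check_axis(axis)
        return self.mean_y if axis == "vertical" else self.mean_x


@dataclass(frozen=True)
class SimilarityRecord:
    """Similarity of one execution to the no-load reference along one axis."""

    execution_id: str
    dev_abs: float  # cm, |execution maximum - MMD0|
    dev_rel: float  # dev_abs / MMD0; NaN when MMD0 == 0
    mh: float  # Morisita-Horn index in [0, 1]
    axis: str
    load_pct: int

    def __post_init__(self) -> None:
        _check_axis(self.axis)
        if self.dev_abs < 0:
            raise ValidationError("dev_abs must be nonnegative")
        if not (0.0 <= self.mh <= 1.0):
            raise ValidationError(f"MH index must lie in [0, 1], got {self.mh}")


def reference_profile(
    trajectories: list[MarkerTrajectory],
    summaries: list[DisplacementSummary] | None = None,
    n_points: int = DEFAULT_N_POINTS,
    min_executions: int = 3,
) -> ReferenceProfile:
    """Build the no-load reference from one subject's bar-only executions.

    ``trajectories`` are the (rebased) ascending-phase trajectories of the
    no-load executions.  ``summaries`` may carry their maximum
    displacements; when omitted they are measured from the trajectories
    directly.  MMD0 is the arithmetic mean of the three maxima per axis;
    the mean trajectory is the pointwise mean after time-normalized
    resampling to ``n_points``.
    """
    if len(trajectories) < min_executions:
        raise ValidationError(
            f"need at least {min_executions} no-load executions, got {len(trajectories)}"
        )
    if summaries is None:
        summaries = [
            max_displacement(
                RepetitionSegment(0, len(tr), "ascending", tr.rebase())
            )
            for tr in trajectories
        ]
    if len(summaries) != len(trajectories):
        raise ValidationError("summaries and trajectories must align one-to-one")
    xs, ys = zip(*(resample(tr.rebase(), n_points) for tr in trajectories))
    return ReferenceProfile(
        mmd0_dx=float(np.mean([s.dx_max for s in summaries])),
        mmd0_dy=float(np.mean([s.dy_max for s in summaries])),
        mean_x=np.mean(xs, axis=0),
        mean_y=np.mean(ys, axis=0),
    )


def deviation(
    exec_summary: DisplacementSummary, ref: ReferenceProfile, axis: str = "vertical"
) -> tuple[float, float]:
    """Absolute and relative deviation of an execution maximum from MMD0.

    Returns ``(dev_abs, dev_rel)`` with ``dev_rel = dev_abs / MMD0``; when
    MMD0 is zero the relative deviation is undefined and returned as NaN.
    """
    _check_axis(axis)
    mmd0 = ref.mmd0(axis)
    dev_abs = abs(exec_summary.for_axis(axis) - mmd0)
    dev_rel = dev_abs / mmd0 if mmd0 > 0 else float("nan")
    return dev_abs, dev_rel


def morisita_horn(xs, ys) -> float:
    """Morisita-Horn overlap index between two abundance vectors.

    I_MH = 2 Σ x_i y_i / [ (Σx_i²/X² + Σy_i²/Y²) · X · Y ]  with the
    sample totals X = Σ x_i, Y = Σ y_i.  The index is 1 for proportional
    vectors and 0 for disjoint support; floating-point overshoot beyond
    [0, 1] of at most 1e-12 is clamped.
    """
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or len(x) != len(y):
        raise ValidationError(
            f"sequences must be 1-D with equal length; got {x.shape} and {y.shape}"
        )
    if len(x) < 1:
        raise ValidationError("sequences must have at least one entry")
    if np.any(x < 0) or np.any(y < 0):
        raise ValidationError("Morisita-Horn requires nonnegative entries")
    X = x.sum()
    Y = y.sum()
    if X == 0 or Y == 0:
        raise ValidationError("Morisita-Horn is undefined for an all-zero sequence")
    num = 2.0 * float(x @ y)
    # algebraically (Σx²/X² + Σy²/Y²)·X·Y, written to avoid under/overflow
    # in X², and exact (== num) for identical inputs
    den = (x @ x) * (Y / X) + (y @ y) * (X / Y)
    val = num / den
    if -1e-12 <= val < 0.0:
        val = 0.0
    elif 1.0 < val <= 1.0 + 1e-12:
        val = 1.0
    return float(val)


def _nonneg_shift(v: np.ndarray) -> np.ndarray:
    return v - v.min()


def execution_similarity(
    exec_traj: MarkerTrajectory,
    ref: ReferenceProfile,
    axis: str = "vertical",
    load_pct: int = 50,
    execution_id: str = "",
    exec_summary: DisplacementSummary | None = None,
) -> SimilarityRecord:
    """Score one execution against the reference along one axis.

    The execution is resampled to the reference's grid; the MH index is
    computed between the reference's and the execution's displacement
    sequences along ``axis``, each shifted to be nonnegative by
    subtracting its minimum.  Deviations come from :func:`deviation`.
    """
    _check_axis(axis)
    rx, ry = resample(exec_traj.rebase(), ref.n_points)
    exec_seq = _nonneg_shift(ry if axis == "vertical" else rx)
    ref_seq = _nonneg_shift(ref.mean_axis(axis))
    mh = morisita_horn(ref_seq, exec_seq)
    if exec_summary is None:
        tr = exec_traj.rebase()
        exec_summary = max_displacement(
            RepetitionSegment(0, len(tr), "ascending", tr), load_pct=load_pct
        )
    dev_abs, dev_rel = deviation(exec_summary, ref, axis)
    return SimilarityRecord(
        execution_id=execution_id or exec_traj.label,
        dev_abs=dev_abs,
        dev_rel=dev_rel,
        mh=mh,
        axis=axis,
        load_pct=load_pct,
    )
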