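"""Synthetic biceps-curl bar trajectories with known ground truth.

The generator emulates what a 30 Hz sagittal-plane recording of a standing
barbell curl looks like after marker tracking: per repetition the bar
sweeps up and back down a circular arc (fixed elbow, forearm as radius),
with the arc parameter following a raised cosine in time so velocity
vanishes at the turning points.  Load inflates the vertical amplitude
multiplicatively (defaults 1.00 / 1.05 / 1.13 for 0 / 25 / 50 % body
weight, matching the ~13 % vertical increase observed between unloaded and
half-body-weight curls); white positional jitter models tracking noise and
a slow horizontal sinusoid models postural sway.  Amplitudes default to a
56.8 cm vertical rise and 23.7 cm peak horizontal excursion with no load.

Every simulated execution returns the exact programmed per-repetition
maxima, so pipeline estimates can be checked against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import ValidationError
from .trajectory import MarkerTrajectory

__all__ = ["CurlSimConfig", "GroundTruth", "StudyExecution", "simulate_curl", "make_study"]

# no-load amplitude calibration: dy_max and peak dx at the default forearm
_NO_LOAD_DY_CM = 56.8
_NO_LOAD_DX_CM = 23.7
_DEFAULT_FOREARM_CM = 30.0

DY_GAIN_DEFAULT = {0: 1.0, 25: 1.05, 50: 1.13}
DX_GAIN_DEFAULT = {0: 1.0, 25: 1.0, 50: 1.05}


@dataclass(frozen=True)
class CurlSimConfig:
    """Parameters of one simulated execution (a set of repetitions)."""

    forearm_cm: float = _DEFAULT_FOREARM_CM
    reps: int = 3
    cadence_s: float = 4.0  # seconds per repetition (up + down)
    fs: float = 30.0
    load_pct: int = 0
    dy_gain: dict[int, float] = field(default_factory=lambda: dict(DY_GAIN_DEFAULT))
    dx_gain: dict[int, float] = field(default_factory=lambda: dict(DX_GAIN_DEFAULT))
    sway_sd_cm: float = 0.5
    jitter_sd_cm: float = 0.2
    seed: int = 0
    # per-cm-of-forearm amplitude factors; defaults reproduce the no-load
    # calibration amplitudes at the default forearm length
    dy_amp_factor: float = _NO_LOAD_DY_CM / _DEFAULT_FOREARM_CM
    dx_amp_factor: float = _NO_LOAD_DX_CM / _DEFAULT_FOREARM_CM

    def __post_init__(self) -> None:
        if min(self.forearm_cm, self.cadence_s, self.fs) <= 0 or self.reps < 1:
            raise ValidationError("physical parameters must be positive")
        if self.fs * self.cadence_s < 10:
            raise ValidationError("need at least 10 samples per repetition")
        if self.load_pct not in self.dy_gain:
            raise ValidationError(f"no dy_gain entry for load {self.load_pct}")
        if self.dy_gain.get(0) != 1.0:
            raise ValidationError("dy_gain at no load must be 1.0 (it is the reference)")
        if self.sway_sd_cm < 0 or self.jitter_sd_cm < 0:
            raise ValidationError("noise SDs must be nonnegative")

    @property
    def dy_amplitude(self) -> float:
        return self.forearm_cm * self.dy_amp_factor * self.dy_gain[self.load_pct]

    @property
    def dx_amplitude(self) -> float:
        return self.forearm_cm * self.dx_amp_factor * self.dx_gain.get(self.load_pct, 1.0)


@dataclass(frozen=True)
class GroundTruth:
    """Programmed per-repetition maxima and repetition boundaries."""

    dx_max: np.ndarray  # cm, one entry per repetition
    dy_max: np.ndarray
    rep_bounds: np.ndarray  # start index of each repetition, plus final end

    def __post_init__(self) -> None:
        if len(self.dx_max) != len(self.dy_max):
            raise ValidationError("ground-truth maxima must have one entry per repetition")


def simulate_curl(
    config: CurlSimConfig, rng: np.random.Generator | None = None
) -> tuple[MarkerTrajectory, GroundTruth]:
    """Simulate one execution; returns the trajectory and its ground truth.

    Within a repetition of phase u ∈ [0, 1] the arc parameter is
    s(u) = (1 − cos 2πu)/2 (a raised-cosine sweep up and back down), and
    the bar sits at x = A_x sin(πs), y = A_y (1 − cos πs)/2 — the circular
    arc from hanging to flexed.  The vertical maximum A_y is reached at
    mid-repetition, the horizontal maximum A_x a quarter of the way up.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_per_rep = int(round(config.fs * config.cadence_s))
    n = config.reps * n_per_rep + 1  # include the final return-to-start sample
    t = np.arange(n) / config.fs
    u = (t * config.fs % n_per_rep) / n_per_rep  # phase within repetition
    u[-1] = 1.0
    s = 0.5 * (1.0 - np.cos(2.0 * np.pi * u))
    ax, ay = config.dx_amplitude, config.dy_amplitude
    x = ax * np.sin(np.pi * s)
    y = ay * 0.5 * (1.0 - np.cos(np.pi * s))
    if config.sway_sd_cm > 0:
        amp = rng.normal(0.0, config.sway_sd_cm)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        x = x + amp * np.sin(2.0 * np.pi * t / t[-1] + phase) - amp * np.sin(phase)
    if config.jitter_sd_cm > 0:
        x = x + rng.normal(0.0, config.jitter_sd_cm, size=n)
        y = y + rng.normal(0.0, config.jitter_sd_cm, size=n)
        x[0] = 0.0  # origin convention: marker centre at movement start
        y[0] = 0.0
    traj = MarkerTrajectory(
        t=t, x=x, y=y, fs=config.fs,
        label=f"sim_load{config.load_pct}",
    )
    bounds = np.append(np.arange(config.reps) * n_per_rep, n - 1)
    gt = GroundTruth(
        dx_max=np.full(config.reps, ax),
        dy_max=np.full(config.reps, ay),
        rep_bounds=bounds,
    )
    return traj, gt


@dataclass(frozen=True)
class StudyExecution:
    """One execution of one subject at one load, with its ground truth."""

    subject: int
    load_pct: int
    execution: int  # 1-based within load
    trajectory: MarkerTrajectory
    truth: GroundTruth
    config: CurlSimConfig

    @property
    def execution_id(self) -> str:
        return f"S{self.subject:02d}_Ex{self.execution}_{self.load_pct}"


def make_study(
    n_subjects: int = 10,
    seed: int = 0,
    loads: tuple[int, ...] = (0, 25, 50),
    executions_per_load: int = 3,
    base_config: CurlSimConfig | None = None,
    forearm_sd_cm: float = 2.0,
    gain_sd: float = 0.02,
) -> list[StudyExecution]:
    """Simulate a full study: per subject, three executions at each load.

    An execution is one full repetition (ascending + descending), matching
    the protocol in which each of the three repetitions at a load is
    analysed as a separate execution.  Each subject draws a forearm length
    (N(30, forearm_sd) cm, floored at 15 cm) and subject-specific load
    gains (default gains perturbed by N(0, gain_sd) at the loaded levels;
    the no-load gain stays 1 so the subject's own reference is exact).
    Noise settings come from ``base_config``; with both noise SDs at zero
    the three executions at a load are identical, so no-load deviations
    are exactly zero.
    """
    if n_subjects < 1:
        raise ValidationError("n_subjects must be >= 1")
    base = base_config or CurlSimConfig()
    rng = np.random.default_rng(seed)
    out: list[StudyExecution] = []
    for subj in range(1, n_subjects + 1):
        forearm = max(15.0, rng.normal(_DEFAULT_FOREARM_CM, forearm_sd_cm))
        gains = dict(base.dy_gain)
        for load in gains:
            if load != 0 and gain_sd > 0:
                gains[load] = max(1.0, gains[load] + rng.normal(0.0, gain_sd))
        for load in loads:
            for ex in range(1, executions_per_load + 1):
                cfg = replace(base, forearm_cm=forearm, load_pct=load, dy_gain=gains, reps=1)
                traj, gt = simulate_curl(cfg, rng=rng)
                traj = replace(traj, label=f"S{subj:02d}_Ex{ex}_{load}")
                out.append(
                    StudyExecution(
                        subject=subj, load_pct=load, execution=ex,
                        trajectory=traj, truth=gt, config=cfg,
                    )
                )
    return out
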