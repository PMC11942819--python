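"""Marker-trajectory ingestion, repetition segmentation, and displacements.

A barbell exercise filmed in the sagittal plane reduces, after marker
tracking, to a 2-D time series of the bar-marker position.  This module
owns that representation (:class:`MarkerTrajectory`, in centimetres, y up,
x anterior), readers for the two export dialects we accept (plain CSV and
Kinovea-style XML), the signed displacement of Eq. Δx = x_f − x_i /
Δy = y_f − y_i, extraction of ascending (lifting) repetition segments, and
the per-repetition maximum displacements that every downstream similarity
computation consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from lxml import etree

from .exceptions import SegmentationError, TrajectoryParseError, ValidationError

__all__ = [
    "MarkerTrajectory",
    "RepetitionSegment",
    "DisplacementSummary",
    "XmlFormatProfile",
    "load_trajectory",
    "displacement",
    "segment_repetitions",
    "max_displacement",
]

DEFAULT_FS = 30.0  # Hz; consumer video frame rate used for capture
VALID_LOADS = (0, 25, 50)  # % body weight


@dataclass(frozen=True)
class MarkerTrajectory:
    """Time-stamped 2-D bar-marker coordinates in centimetres.

    Parameters
    ----------
    t : array of seconds, monotone nondecreasing.
    x : horizontal (anterior) position, cm.
    y : vertical position, cm, increasing upward.
    fs : sampling rate in Hz; used to derive ``t`` when a file has no
        time column.
    label : free-text identifier (subject/execution).
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    fs: float = DEFAULT_FS
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float))
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        n = len(self.t)
        if not (n == len(self.x) == len(self.y)):
            raise ValidationError(
                f"t, x, y must have equal length; got {n}, {len(self.x)}, {len(self.y)}"
            )
        if n < 2:
            raise ValidationError(f"trajectory needs at least 2 samples, got {n}")
        if self.fs <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if np.any(np.diff(self.t) < 0):
            raise ValidationError("time stamps must be monotone nondecreasing")

    def __len__(self) -> int:
        return len(self.t)

    def rebase(self) -> "MarkerTrajectory":
        """Shift coordinates so the first sample is the origin (idempotent).

        Mirrors the capture convention of placing the coordinate origin at
        the marker centre at the start of the upward movement.
        """
        return replace(self, x=self.x - self.x[0], y=self.y - self.y[0])

    def scaled(self, k: float) -> "MarkerTrajectory":
        """Multiply coordinates by ``k`` (unit conversion)."""
        if k <= 0:
            raise ValidationError(f"scale must be positive, got {k}")
        return replace(self, x=self.x * k, y=self.y * k)


@dataclass(frozen=True)
class RepetitionSegment:
    """Half-open sample range [start_idx, end_idx) of one movement phase."""

    start_idx: int
    end_idx: int
    phase: str  # "ascending" | "descending"
    parent: MarkerTrajectory

    def __post_init__(self) -> None:
        if self.phase not in ("ascending", "descending"):
            raise ValidationError(f"unknown phase {self.phase!r}")
        if not (0 <= self.start_idx < self.end_idx <= len(self.parent)):
            raise ValidationError(
                f"segment [{self.start_idx}, {self.end_idx}) out of range "
                f"for trajectory of length {len(self.parent)}"
            )

    def __len__(self) -> int:
        return self.end_idx - self.start_idx

    @property
    def t(self) -> np.ndarray:
        return self.parent.t[self.start_idx : self.end_idx]

    @property
    def x(self) -> np.ndarray:
        return self.parent.x[self.start_idx : self.end_idx]

    @property
    def y(self) -> np.ndarray:
        return self.parent.y[self.start_idx : self.end_idx]

    def as_trajectory(self, label: str = "") -> MarkerTrajectory:
        """The segment as a stand-alone (rebased) trajectory."""
        return MarkerTrajectory(
            t=self.t - self.t[0],
            x=self.x - self.x[0],
            y=self.y - self.y[0],
            fs=self.parent.fs,
            label=label or self.parent.label,
        )


@dataclass(frozen=True)
class DisplacementSummary:
    """Maximum absolute displacements over one ascending phase, in cm."""

    dx_max: float
    dy_max: float
    load_pct: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if self.dx_max < 0 or self.dy_max < 0:
            raise ValidationError("maximum displacements must be nonnegative")
        if self.load_pct not in VALID_LOADS:
            raise ValidationError(
                f"load_pct must be one of {VALID_LOADS}, got {self.load_pct}"
            )

    def for_axis(self, axis: str) -> float:
        if axis == "vertical":
            return self.dy_max
        if axis == "horizontal":
            return self.dx_max
        raise ValidationError(f"axis must be 'vertical' or 'horizontal', got {axis!r}")


@dataclass(frozen=True)
class XmlFormatProfile:
    """Element/attribute names of a Kinovea-style XML coordinate export.

    Tracker versions differ in tag spelling, so every name is
    configurable; matching is case-insensitive.  With the default profile
    any element carrying both an x and a y attribute is taken as a point.
    """

    point_tag: str | None = None  # None: accept any element with x+y attrs
    x_attr: str = "x"
    y_attr: str = "y"
    time_attr: str = "t"
    time_attr_alt: str = "time"


def _read_csv(path: Path, fs: float) -> tuple[np.ndarray | None, np.ndarray, np.ndarray]:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pandas raises several parser error types
        raise TrajectoryParseError(f"{path}: could not parse CSV ({exc})") from exc
    cols = {c.strip().lower(): c for c in df.columns}
    if "x" not in cols or "y" not in cols:
        raise TrajectoryParseError(
            f"{path}: CSV must have 'x' and 'y' columns (optionally 't'); "
            f"found {list(df.columns)}"
        )
    for key in ("x", "y"):
        col = df[cols[key]]
        bad = pd.to_numeric(col, errors="coerce").isna() & col.notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise TrajectoryParseError(
                f"{path}: non-numeric value in column '{key}' at line {line}"
            )
    x = df[cols["x"]].astype(float).to_numpy()
    y = df[cols["y"]].astype(float).to_numpy()
    t = df[cols["t"]].astype(float).to_numpy() if "t" in cols else None
    return t, x, y


def _attr_lookup(elem, name: str) -> str | None:
    for key, val in elem.attrib.items():
        if key.lower() == name.lower():
            return val
    return None


def _read_kinovea_xml(
    path: Path, profile: XmlFormatProfile
) -> tuple[np.ndarray | None, np.ndarray, np.ndarray]:
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise TrajectoryParseError(f"{path}: malformed XML ({exc})") from exc
    root = tree.getroot()
    if profile.point_tag is not None:
        points = [
            e for e in root.iter() if etree.QName(e).localname.lower() == profile.point_tag.lower()
        ]
    else:
        points = [
            e
            for e in root.iter()
            if _attr_lookup(e, profile.x_attr) is not None
            and _attr_lookup(e, profile.y_attr) is not None
        ]
    if not points:
        raise TrajectoryParseError(
            f"{path}: no point elements found "
            f"(tag={profile.point_tag!r}, attrs={profile.x_attr}/{profile.y_attr})"
        )
    ts, xs, ys = [], [], []
    for elem in points:
        sx = _attr_lookup(elem, profile.x_attr)
        sy = _attr_lookup(elem, profile.y_attr)
        st = _attr_lookup(elem, profile.time_attr)
        if st is None and profile.time_attr_alt:
            st = _attr_lookup(elem, profile.time_attr_alt)
        try:
            xs.append(float(sx))
            ys.append(float(sy))
        except (TypeError, ValueError) as exc:
            raise TrajectoryParseError(
                f"{path}: non-numeric coordinate in element "
                f"<{etree.QName(elem).localname}> at line {elem.sourceline}"
            ) from exc
        if st is not None:
            try:
                ts.append(float(st))
            except ValueError as exc:
                raise TrajectoryParseError(
                    f"{path}: non-numeric time in element at line {elem.sourceline}"
                ) from exc
    t = np.asarray(ts, dtype=float) if len(ts) == len(xs) else None
    return t, np.asarray(xs, dtype=float), np.asarray(ys, dtype=float)


def load_trajectory(
    path: str | Path,
    format: str = "csv",
    scale: float = 1.0,
    fs: float = DEFAULT_FS,
    label: str = "",
    xml_profile: XmlFormatProfile | None = None,
) -> MarkerTrajectory:
    """Read a marker trajectory and return it in cm, rebased to the origin.

    Parameters
    ----------
    path : file to read.
    format : ``"csv"`` (header ``t,x,y``; ``t`` optional) or
        ``"kinovea_xml"`` (point elements with x/y/time attributes).
    scale : cm per file unit (e.g. cm per pixel from the background
        calibration); coordinates are multiplied by it.
    fs : sampling rate used to derive ``t`` when the file has none.
    xml_profile : element/attribute names for the XML dialect.

    The returned trajectory has ``x[0] == y[0] == 0`` exactly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trajectory file not found: {path}")
    if scale <= 0:
        raise ValidationError(f"scale must be positive, got {scale}")
    if format == "csv":
        t, x, y = _read_csv(path, fs)
    elif format in ("kinovea_xml", "kinovea"):
        t, x, y = _read_kinovea_xml(path, xml_profile or XmlFormatProfile())
    else:
        raise ValidationError(f"unknown format {format!r}; use 'csv' or 'kinovea_xml'")
    if t is None:
        t = np.arange(len(x), dtype=float) / fs
    traj = MarkerTrajectory(t=t, x=x * scale, y=y * scale, fs=fs, label=label or path.stem)
    return traj.rebase()


def displacement(traj: MarkerTrajectory, i: int, f: int) -> tuple[float, float]:
    """Signed displacement (Δx, Δy) = (x_f − x_i, y_f − y_i) in cm."""
    n = len(traj)
    for idx in (i, f):
        if not (0 <= idx < n):
            raise ValidationError(f"index {idx} out of range for trajectory of length {n}")
    return float(traj.x[f] - traj.x[i]), float(traj.y[f] - traj.y[i])


def _moving_average(v: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return v.astype(float)
    # centered window; edges use a shrinking window so the length is preserved
    kernel = np.ones(window) / window
    padded = np.pad(v.astype(float), window // 2, mode="edge")
    out = np.convolve(padded, kernel, mode="same")[window // 2 : window // 2 + len(v)]
    return out


def segment_repetitions(
    traj: MarkerTrajectory,
    n_reps: int,
    smooth_window: int = 5,
    min_rise_frac: float = 0.2,
) -> list[RepetitionSegment]:
    """Locate the first ``n_reps`` ascending (lifting) phases.

    The vertical coordinate is smoothed with a centered moving average;
    a repetition's ascending phase runs from a local minimum of the
    smoothed signal to the following local maximum, extrema being strict
    sign changes of the first difference.  The recording's first sample
    counts as a minimum when the movement starts upward, and the last
    sample as a maximum when it ends upward.  Candidate ascents whose rise
    is below ``min_rise_frac`` of the largest detected rise are discarded
    as tracking-noise wiggles.
    """
    if n_reps < 1:
        raise ValidationError(f"n_reps must be >= 1, got {n_reps}")
    ys = _moving_average(traj.y, smooth_window)
    d = np.diff(ys)
    sign = np.sign(d)
    # carry the last nonzero sign through flat stretches
    for k in range(1, len(sign)):
        if sign[k] == 0:
            sign[k] = sign[k - 1]
    minima: list[int] = []
    maxima: list[int] = []
    if len(sign) and sign[np.argmax(sign != 0)] > 0:
        minima.append(0)
    flips = np.nonzero(sign[1:] * sign[:-1] < 0)[0] + 1
    for k in flips:
        (maxima if sign[k] < 0 else minima).append(int(k))
    if len(sign) and sign[-1] > 0:
        maxima.append(len(traj) - 1)

    candidates: list[tuple[int, int, float]] = []  # (lo, hi, rise)
    maxs = sorted(maxima)
    last_end = -1
    for lo in sorted(minima):
        nxt = [m for m in maxs if m > lo]
        if not nxt:
            break
        hi = nxt[0]
        if lo <= last_end:
            continue
        candidates.append((lo, hi, float(ys[hi] - ys[lo])))
        last_end = hi
    if candidates:
        threshold = min_rise_frac * max(c[2] for c in candidates)
        candidates = [c for c in candidates if c[2] >= threshold]
    segments = [
        RepetitionSegment(start_idx=lo, end_idx=hi + 1, phase="ascending", parent=traj)
        for lo, hi, _ in candidates
    ]
    if len(segments) < n_reps:
        raise SegmentationError(
            f"requested {n_reps} repetitions but detected only {len(segments)} "
            f"ascending cycles"
        )
    return segments[:n_reps]


def max_displacement(
    segment: RepetitionSegment, load_pct: int = 0, label: str = ""
) -> DisplacementSummary:
    """Maximum |Δx| and |Δy| over an ascending segment, from its start sample."""
    if segment.phase != "ascending":
        raise ValidationError("max_displacement expects an ascending segment")
    if len(segment) == 0:
        raise ValidationError("empty segment")
    dx = np.abs(segment.x - segment.x[0])
    dy = np.abs(segment.y - segment.y[0])
    return DisplacementSummary(
        dx_max=float(dx.max()),
        dy_max=float(dy.max()),
        load_pct=load_pct,
        label=label or segment.parent.label,
    )
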