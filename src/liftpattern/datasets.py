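"""Bundled reference dataset of a ten-volunteer barbell-curl study.

The package ships, as plain CSV transcriptions, the published measurement
grids of a study in which ten volunteers performed three barbell-curl
executions at each of three loads (bar only, 25 % and 50 % of body
weight): maximum absolute horizontal and vertical deviations (cm) of each
loaded execution from the subject's no-load reference MMD0, and the
Morisita-Horn indices of the vertical comparisons at 50 % load.  These
grids are measured data — inputs to the modelling stages, not quantities
the package recomputes.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = ["ReferenceTables", "load_reference_tables", "paired_vertical_50"]

EXECUTIONS_25 = ("Ex1_25", "Ex2_25", "Ex3_25")
EXECUTIONS_50 = ("Ex1_50", "Ex2_50", "Ex3_50")
VOLUNTEERS = tuple(f"V{i:02d}" for i in range(1, 11))


@dataclass(frozen=True)
class ReferenceTables:
    """The three measurement grids, indexed by execution x volunteer."""

    horizontal: pd.DataFrame  # absolute horizontal deviations, cm (6 x 10)
    vertical: pd.DataFrame  # absolute vertical deviations, cm (6 x 10)
    mh: pd.DataFrame  # Morisita-Horn indices, vertical, 50 % load (3 x 10)


def _read(name: str) -> pd.DataFrame:
    with resources.files("liftpattern.data").joinpath(name).open("r") as fh:
        df = pd.read_csv(fh, index_col="execution")
    return df.astype(float)


def load_reference_tables() -> ReferenceTables:
    """Load the bundled deviation and MH grids."""
    return ReferenceTables(
        horizontal=_read("horizontal_deviations_cm.csv"),
        vertical=_read("vertical_deviations_cm.csv"),
        mh=_read("mh_indices_vertical.csv"),
    )


def paired_vertical_50(tables: ReferenceTables | None = None) -> pd.DataFrame:
    """The 30 (deviation, MH) pairs of the 50 %-load vertical analysis.

    One row per volunteer x execution at 50 % load, with columns
    ``volunteer``, ``execution``, ``deviation_cm``, ``mh`` — the dataset
    every regression and scoring model in this package is fitted on.
    """
    t = tables or load_reference_tables()
    rows = []
    for ex in EXECUTIONS_50:
        for vol in VOLUNTEERS:
            rows.append(
                {
                    "volunteer": vol,
                    "execution": ex,
                    "deviation_cm": float(t.vertical.loc[ex, vol]),
                    "mh": float(t.mh.loc[ex, vol]),
                }
            )
    return pd.DataFrame(rows)
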