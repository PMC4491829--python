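"""Track-table input/output.

A *track table* is the tabular interchange format produced by upstream
adhesion segmentation/tracking: one row per (adhesion, timepoint), with the
segmented adhesion area and the per-adhesion mean intensities of the two
FRET sensor channels (mTFP1 donor, Venus/FRET acceptor).  Everything
downstream of segmentation starts from this table.

Columns (fixed order)::

    cell_id, track_id, timepoint, area, mtfp1_mean, venus_mean

``timepoint`` is a 0-based integer index at a fixed sampling interval
(default 30 s); wall-clock time is ``timepoint * sampling_interval``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TRACK_COLUMNS = ["cell_id", "track_id", "timepoint", "area", "mtfp1_mean", "venus_mean"]


class SchemaError(ValueError):
    """The file/table does not have the required track-table columns."""


class ValidationError(ValueError):
    """The table has the right columns but violates a track-table invariant."""


@dataclass
class TrackTable:
    """Validated per-adhesion time-series table.

    Wraps a :class:`pandas.DataFrame` with the six required columns, sorted
    by ``(cell_id, track_id, timepoint)``.  Invariants enforced on
    construction: unique (cell, track, timepoint) keys, consecutive integer
    timepoints within each track, strictly positive areas and non-negative
    intensities.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.df = validate_track_table(self.df)

    @property
    def n_tracks(self) -> int:
        if len(self.df) == 0:
            return 0
        return self.df.groupby(["cell_id", "track_id"], sort=False).ngroups

    def __len__(self) -> int:
        return len(self.df)

    def tracks(self):
        """Yield ``((cell_id, track_id), per-track DataFrame)`` pairs."""
        if len(self.df) == 0:
            return
        yield from self.df.groupby(["cell_id", "track_id"], sort=True)


def validate_track_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"track table is missing column(s): {', '.join(missing)}")
    df = df.loc[:, TRACK_COLUMNS].copy()
    df["timepoint"] = df["timepoint"].astype(np.int64)
    for col in ("area", "mtfp1_mean", "venus_mean"):
        df[col] = df[col].astype(np.float64)
    df = df.sort_values(["cell_id", "track_id", "timepoint"], kind="mergesort")
    df = df.reset_index(drop=True)

    if len(df):
        if df.duplicated(subset=["cell_id", "track_id", "timepoint"]).any():
            raise ValidationError("duplicate (cell_id, track_id, timepoint) rows")
        if not (df["area"] > 0).all():
            raise ValidationError("area must be strictly positive for every row")
        if not (df[["mtfp1_mean", "venus_mean"]] >= 0).all().all():
            raise ValidationError("channel intensities must be non-negative")
        for (cell, track), sub in df.groupby(["cell_id", "track_id"], sort=False):
            tp = sub["timepoint"].to_numpy()
            if len(tp) > 1 and not np.array_equal(np.diff(tp), np.ones(len(tp) - 1)):
                raise ValidationError(
                    f"track (cell_id={cell!r}, track_id={track!r}) has "
                    "non-consecutive timepoints"
                )
    return df


def read_track_table(path) -> TrackTable:
    """Read a track-table CSV and validate it.

    Raises :class:`SchemaError` if a required column is absent and
    :class:`ValidationError` (naming the offending track) if timepoints are
    not consecutive or values are out of range.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    return TrackTable(df)


def write_track_table(table: TrackTable, path) -> None:
    """Write a track table as CSV with the fixed column order.

    Floats use repr-roundtrip precision so that write → read → write is
    byte-identical.
    """
    table.df.to_csv(path, index=False, columns=TRACK_COLUMNS, float_format="%.17g")
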