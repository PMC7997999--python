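"""Reading and writing tracked-trajectory tables.

Targets the delimited-text exports of manual-tracking tools (ImageJ Manual
Tracking and kin): one row per (track, frame) with x/y coordinates in either
pixels or μm. The dialect object names the columns and units; internally
everything is μm with 0-based frames.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .core import AcquisitionSettings, Trajectory
from .errors import DuplicateRecordError, GapError, ParseError, TrackFormatError


@dataclass(frozen=True)
class TrackTableDialect:
    """Column layout and units of a track table file."""

    delimiter: str = ","
    track_col: str = "track"
    frame_col: str = "frame"
    x_col: str = "x"
    y_col: str = "y"
    coordinate_unit: str = "micron"  # "micron" | "pixel"
    frame_base: int = 0

    def __post_init__(self):
        cols = [self.track_col, self.frame_col, self.x_col, self.y_col]
        if len(set(cols)) != 4:
            raise TrackFormatError("dialect column names must be distinct")
        if self.coordinate_unit not in ("micron", "pixel"):
            raise TrackFormatError("coordinate_unit must be 'micron' or 'pixel'")
        if self.frame_base not in (0, 1):
            raise TrackFormatError("frame_base must be 0 or 1")


DEFAULT_DIALECT = TrackTableDialect()


def read_tracks(
    path,
    dialect: TrackTableDialect = DEFAULT_DIALECT,
    settings: Optional[AcquisitionSettings] = None,
    allow_gaps: bool = False,
) -> List[Trajectory]:
    """Read a delimited track table into a list of trajectories.

    Pixel coordinates are converted to μm with ``settings.pixel_size``; times
    are reconstructed as frame × frame_interval relative to each track's first
    frame. Frames with gaps raise :class:`GapError` unless ``allow_gaps``;
    duplicate (track, frame) rows and non-numeric coordinates are always
    rejected. No row is ever silently dropped.
    """
    settings = settings or AcquisitionSettings()
    d = dialect
    try:
        df = pd.read_csv(path, sep=d.delimiter, dtype=str, skipinitialspace=True)
    except pd.errors.EmptyDataError:
        raise TrackFormatError(f"{path}: empty file without header")
    missing = [c for c in (d.track_col, d.frame_col, d.x_col, d.y_col) if c not in df.columns]
    if missing:
        raise TrackFormatError(f"{path}: missing column(s) {missing}")
    if df.empty:
        return []

    def numeric(col):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.index[vals.isna() & df[col].notna()]
        if len(bad):
            row = int(bad[0]) + 2  # 1-based, counting the header line
            raise ParseError(f"{path}: non-numeric value in column {col!r} at row {row}", row=row)
        if vals.isna().any():
            row = int(vals.index[vals.isna()][0]) + 2
            raise ParseError(f"{path}: missing value in column {col!r} at row {row}", row=row)
        return vals.to_numpy()

    frames = numeric(d.frame_col)
    if np.any(frames != np.round(frames)):
        raise ParseError(f"{path}: non-integer frame index")
    frames = frames.astype(np.int64) - d.frame_base
    x = numeric(d.x_col)
    y = numeric(d.y_col)
    if d.coordinate_unit == "pixel":
        x = x * settings.pixel_size
        y = y * settings.pixel_size

    out: List[Trajectory] = []
    table = pd.DataFrame({"track": df[d.track_col].to_numpy(), "frame": frames, "x": x, "y": y})
    for track_id, grp in table.groupby("track", sort=True):
        grp = grp.sort_values("frame")
        fr = grp["frame"].to_numpy()
        if len(np.unique(fr)) != len(fr):
            dup = fr[np.diff(fr, prepend=fr[0] - 1) == 0][0]
            raise DuplicateRecordError(f"{path}: duplicate (track={track_id}, frame={dup})")
        if not allow_gaps and np.any(np.diff(fr) != 1):
            raise GapError(
                f"{path}: track {track_id} has frame gaps; pass allow_gaps=True to accept"
            )
        out.append(
            Trajectory(
                track_id=str(track_id),
                frames=fr,
                positions=grp[["x", "y"]].to_numpy(),
                settings=settings,
            )
        )
    return out


def write_tracks(
    trajs: Sequence[Trajectory],
    path,
    dialect: TrackTableDialect = DEFAULT_DIALECT,
) -> None:
    """Write trajectories as a delimited table, rows ordered (track, frame).

    Inverse of :func:`read_tracks` for the same dialect: μm round-trips
    exactly, pixel units to representation precision.
    """
    d = dialect
    rows = []
    for traj in sorted(trajs, key=lambda t: t.track_id):
        x, y = traj.positions[:, 0], traj.positions[:, 1]
        if d.coordinate_unit == "pixel":
            px = traj.settings.pixel_size
            x, y = x / px, y / px
        for i in range(traj.n_frames):
            rows.append((traj.track_id, int(traj.frames[i]) + d.frame_base, x[i], y[i]))
    df = pd.DataFrame(rows, columns=[d.track_col, d.frame_col, d.x_col, d.y_col])
    df.to_csv(path, sep=d.delimiter, index=False, float_format="%.10g")


def validate_tracks(path, dialect: TrackTableDialect = DEFAULT_DIALECT,
                    settings: Optional[AcquisitionSettings] = None) -> dict:
    """Validate a track file; returns a small summary dict or raises."""
    trajs = read_tracks(path, dialect=dialect, settings=settings)
    return {
        "n_tracks": len(trajs),
        "n_rows": int(sum(t.n_frames for t in trajs)),
        "frame_counts": {t.track_id: t.n_frames for t in trajs},
    }
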