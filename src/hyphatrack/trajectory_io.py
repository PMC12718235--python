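"""Reading, validating and writing frame-wise bacterial tracking tables.

Two CSV dialects are supported:

``trackmate_spots``
    The spot table exported by TrackMate (columns ``TRACK_ID``, ``FRAME``,
    ``POSITION_X``, ``POSITION_Y`` and optionally ``POSITION_T``).  Spots
    that were never linked into a track carry an empty ``TRACK_ID`` and are
    dropped (their count is reported).

``minimal``
    A compact internal exchange format with columns
    ``track_id,frame,x,y[,t]`` used for fixtures and simulator output.

Positions are planar and expressed in µm after applying the calibration
factor; a ``z`` column, if present, is ignored with a warning.  When the
file carries no per-row timestamp, time is reconstructed as
``frame * frame_interval``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Detection",
    "Trajectory",
    "TrackSet",
    "TrackFormatError",
    "TrackParseError",
    "ValidationReport",
    "read_tracks",
    "write_tracks",
    "validate_trackset",
]

#: Inter-frame time of the study's high-speed recordings, seconds.
DEFAULT_FRAME_INTERVAL = 0.024

_TRACKMATE_COLUMNS = {
    "track_id": "TRACK_ID",
    "frame": "FRAME",
    "x": "POSITION_X",
    "y": "POSITION_Y",
    "t": "POSITION_T",
}
_MINIMAL_COLUMNS = {"track_id": "track_id", "frame": "frame", "x": "x", "y": "y", "t": "t"}


class TrackFormatError(ValueError):
    """A required column is missing or the dialect is unknown."""


class TrackParseError(ValueError):
    """A cell that should be numeric could not be parsed."""


@dataclass(frozen=True)
class Detection:
    """One localized cell position: frame index, x/y in µm, time in s."""

    frame: int
    x: float
    y: float
    t: float


@dataclass
class Trajectory:
    """An ordered (by frame) sequence of detections sharing one track id."""

    track_id: str
    detections: list[Detection]

    def __len__(self) -> int:
        return len(self.detections)


@dataclass
class TrackSet:
    """A collection of trajectories plus acquisition metadata."""

    trajectories: list[Trajectory]
    frame_interval: float = DEFAULT_FRAME_INTERVAL
    source: str = ""
    n_unlinked_dropped: int = 0

    def __len__(self) -> int:
        return len(self.trajectories)

    @property
    def n_detections(self) -> int:
        return sum(len(tr) for tr in self.trajectories)


@dataclass
class ValidationReport:
    n_tracks: int = 0
    n_detections: int = 0
    duplicate_frame_violations: list[str] = field(default_factory=list)
    non_monotone_time_violations: list[str] = field(default_factory=list)

    @property
    def n_violations(self) -> int:
        return len(self.duplicate_frame_violations) + len(self.non_monotone_time_violations)

    @property
    def is_valid(self) -> bool:
        return self.n_violations == 0


def _resolve_columns(df: pd.DataFrame, dialect: str) -> dict[str, str]:
    """Map canonical field names to actual dataframe columns, case-insensitively."""
    if dialect == "trackmate_spots":
        wanted = _TRACKMATE_COLUMNS
    elif dialect == "minimal":
        wanted = _MINIMAL_COLUMNS
    else:
        raise TrackFormatError(f"unknown dialect {dialect!r}")
    lower = {c.lower(): c for c in df.columns}
    mapping: dict[str, str] = {}
    for key, col in wanted.items():
        actual = lower.get(col.lower())
        if actual is None:
            if key == "t":  # timestamps are reconstructable
                continue
            raise TrackFormatError(f"missing required column {col!r} for dialect {dialect!r}")
        mapping[key] = actual
    return mapping


def _to_numeric(df: pd.DataFrame, column: str) -> pd.Series:
    converted = pd.to_numeric(df[column], errors="coerce")
    bad = converted.isna() & df[column].notna()
    if bad.any():
        # +2: one for the header line, one for 0-based indexing
        row = int(bad.idxmax()) + 2
        raise TrackParseError(
            f"non-numeric value {df[column][bad.idxmax()]!r} in column {column!r} at file row {row}"
        )
    return converted


def read_tracks(
    path: str | Path,
    dialect: str = "minimal",
    calibration: float = 1.0,
    frame_interval: float = DEFAULT_FRAME_INTERVAL,
) -> TrackSet:
    """Read a tracking table into a :class:`TrackSet`.

    Parameters
    ----------
    path
        CSV file to read.
    dialect
        ``"trackmate_spots"`` or ``"minimal"``.
    calibration
        Multiplicative factor converting file position units to µm.
    frame_interval
        Seconds between consecutive frames, used to reconstruct time when
        the file carries no timestamp column.  This is a mandatory, logged
        choice rather than a constant: deposited file names and acquisition
        metadata may disagree, so runs against real exports should verify
        the interval from the timestamp column when one is present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    cols = _resolve_columns(df, dialect)
    logger.info("read_tracks(%s): dialect=%s calibration=%g frame_interval=%g",
                path.name, dialect, calibration, frame_interval)

    zcols = [c for c in df.columns if c.lower() in ("z", "position_z")]
    if zcols:
        logger.warning("ignoring z column(s) %s: positions are treated as planar", zcols)

    track_ids = df[cols["track_id"]]
    unlinked = track_ids.isna() | (track_ids.str.strip() == "")
    n_unlinked = int(unlinked.sum())
    if n_unlinked:
        logger.info("dropped %d unlinked spots (missing track id)", n_unlinked)
        df = df.loc[~unlinked]

    if df.empty:
        return TrackSet([], frame_interval=frame_interval, source=str(path),
                        n_unlinked_dropped=n_unlinked)

    frame = _to_numeric(df, cols["frame"]).astype(int)
    x = _to_numeric(df, cols["x"]) * calibration
    y = _to_numeric(df, cols["y"]) * calibration
    if "t" in cols:
        t = _to_numeric(df, cols["t"])
    else:
        t = frame * frame_interval

    table = pd.DataFrame({
        "track_id": df[cols["track_id"]].str.strip().to_numpy(),
        "frame": frame.to_numpy(),
        "x": x.to_numpy(),
        "y": y.to_numpy(),
        "t": t.to_numpy(dtype=float),
    })

    trajectories = []
    for tid, grp in table.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        detections = [
            Detection(int(f), float(xx), float(yy), float(tt))
            for f, xx, yy, tt in zip(grp["frame"], grp["x"], grp["y"], grp["t"])
        ]
        trajectories.append(Trajectory(str(tid), detections))
    return TrackSet(trajectories, frame_interval=frame_interval, source=str(path),
                    n_unlinked_dropped=n_unlinked)


def write_tracks(tracks: TrackSet, path: str | Path, dialect: str = "minimal") -> None:
    """Write a TrackSet as CSV such that ``read_tracks`` round-trips it."""
    rows = [
        (tr.track_id, d.frame, d.x, d.y, d.t)
        for tr in tracks.trajectories
        for d in tr.detections
    ]
    if dialect == "minimal":
        columns = ["track_id", "frame", "x", "y", "t"]
    elif dialect == "trackmate_spots":
        columns = ["TRACK_ID", "FRAME", "POSITION_X", "POSITION_Y", "POSITION_T"]
    else:
        raise TrackFormatError(f"unknown dialect {dialect!r}")
    df = pd.DataFrame(rows, columns=columns)
    df.to_csv(path, index=False, float_format="%.12g")


def validate_trackset(tracks: TrackSet) -> ValidationReport:
    """Report structural violations without raising.

    Checks per track: frame indices unique, time nondecreasing with frame.
    """
    report = ValidationReport(n_tracks=len(tracks), n_detections=tracks.n_detections)
    seen: set[str] = set()
    for tr in tracks.trajectories:
        if tr.track_id in seen:
            report.duplicate_frame_violations.append(
                f"track {tr.track_id!r}: duplicate track id in set")
        seen.add(tr.track_id)
        frames = [d.frame for d in tr.detections]
        if len(set(frames)) != len(frames):
            dup = sorted({f for f in frames if frames.count(f) > 1})
            report.duplicate_frame_violations.append(
                f"track {tr.track_id!r}: duplicated frame(s) {dup}")
        ts = [d.t for d in sorted(tr.detections, key=lambda d: d.frame)]
        if any(b < a for a, b in zip(ts, ts[1:])):
            report.non_monotone_time_violations.append(
                f"track {tr.track_id!r}: time decreases between consecutive frames")
    return report
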