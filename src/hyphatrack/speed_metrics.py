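"""Instantaneous speeds and the study's trajectory/sample exclusion rules.

The instantaneous speed of a tracked cell is the Euclidean distance between
its positions in two *consecutive* frames divided by the inter-frame time.
Pairs of detections spanning a frame gap yield no speed sample.

Three exclusion rules clean the data before any distribution analysis,
applied in a fixed, logged order:

1. drop trajectories observed for less than ``min_duration`` seconds
   (cells crossing the focal plane only transiently, default 0.25 s);
2. drop trajectories whose total path length is less than
   ``min_path_length`` µm (microcolony jitter, default 5 µm);
3. on the survivors, drop individual speed samples exceeding ``v_max``
   (tracking artifacts, default 100 µm/s).

Exclusions are strict ("shorter than", "exceeding"): boundary values are
retained.  The fraction of samples removed by the speed cutoff is reported
relative to the samples that survived the trajectory-level filters.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, asdict

import numpy as np

from .trajectory_io import TrackSet, Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "SpeedSample",
    "FilterConfig",
    "FilterReport",
    "SpeedSummary",
    "SpeedDataError",
    "instantaneous_speeds",
    "trajectory_path_length",
    "apply_filters",
    "summarize_speeds",
    "speeds_array",
]


class SpeedDataError(ValueError):
    """Raised when a track's timestamps make a speed undefined (dt <= 0)."""


@dataclass(frozen=True)
class SpeedSample:
    """One inter-frame speed measurement in µm/s, with provenance."""

    speed: float
    track_id: str
    frame_pair: tuple[int, int]
    dt: float


@dataclass(frozen=True)
class FilterConfig:
    """Exclusion thresholds; defaults are the study's stringency settings."""

    v_max: float = 100.0            # µm/s, upper speed cutoff
    min_path_length: float = 5.0    # µm, minimum trajectory path length
    min_duration: float = 0.25      # s, minimum trajectory duration

    def __post_init__(self) -> None:
        if min(self.v_max, self.min_path_length, self.min_duration) <= 0:
            raise ValueError("filter thresholds must be strictly positive")


@dataclass
class FilterReport:
    n_tracks_in: int = 0
    n_tracks_removed_duration: int = 0
    n_tracks_removed_length: int = 0
    n_speed_samples_before_cutoff: int = 0
    n_speed_samples_removed_by_cutoff: int = 0

    @property
    def n_tracks_retained(self) -> int:
        return (self.n_tracks_in - self.n_tracks_removed_duration
                - self.n_tracks_removed_length)

    @property
    def n_speed_samples_retained(self) -> int:
        return self.n_speed_samples_before_cutoff - self.n_speed_samples_removed_by_cutoff

    @property
    def cutoff_excluded_percent(self) -> float:
        if self.n_speed_samples_before_cutoff == 0:
            return 0.0
        return 100.0 * self.n_speed_samples_removed_by_cutoff / self.n_speed_samples_before_cutoff

    def to_dict(self) -> dict:
        d = asdict(self)
        d["n_tracks_retained"] = self.n_tracks_retained
        d["n_speed_samples_retained"] = self.n_speed_samples_retained
        d["cutoff_excluded_percent"] = self.cutoff_excluded_percent
        return d


@dataclass(frozen=True)
class SpeedSummary:
    """n, arithmetic mean and sample sd (n-1 denominator) of speeds, µm/s."""

    n: int
    mean: float | None
    sd: float | None

    def __str__(self) -> str:
        if self.n == 0 or self.mean is None:
            return "—"
        if self.sd is None:
            return f"{self.mean:.2f}"
        return f"{self.mean:.2f} ± {self.sd:.2f}"


def instantaneous_speeds(tracks: TrackSet) -> list[SpeedSample]:
    """One speed sample per consecutive-frame detection pair.

    Pairs whose frame indices differ by more than 1 (the cell was lost for
    one or more frames) contribute nothing.
    """
    samples: list[SpeedSample] = []
    for tr in tracks.trajectories:
        for a, b in zip(tr.detections, tr.detections[1:]):
            if b.frame - a.frame != 1:
                continue
            dt = b.t - a.t
            if dt <= 0:
                raise SpeedDataError(
                    f"track {tr.track_id!r}: non-positive time step {dt} "
                    f"between frames {a.frame} and {b.frame}")
            speed = math.hypot(b.x - a.x, b.y - a.y) / dt
            samples.append(SpeedSample(speed, tr.track_id, (a.frame, b.frame), dt))
    return samples


def trajectory_path_length(traj: Trajectory) -> float:
    """Total path length in µm: sum of consecutive-detection displacements.

    All detection pairs contribute, including those across frame gaps; a
    single-detection track has length 0.
    """
    if not traj.detections:
        raise ValueError("trajectory has no detections")
    return sum(
        math.hypot(b.x - a.x, b.y - a.y)
        for a, b in zip(traj.detections, traj.detections[1:])
    )


def _duration(traj: Trajectory) -> float:
    return traj.detections[-1].t - traj.detections[0].t


def apply_filters(
    tracks: TrackSet, cfg: FilterConfig | None = None
) -> tuple[list[SpeedSample], FilterReport]:
    """Apply the three exclusion rules; return retained samples and a report.

    Order: duration filter, then path-length filter, then the per-sample
    speed cutoff on the surviving trajectories.  Boundary values (duration
    exactly ``min_duration``, length exactly ``min_path_length``, speed
    exactly ``v_max``) are retained.
    """
    cfg = cfg or FilterConfig()
    report = FilterReport(n_tracks_in=len(tracks))

    survivors: list[Trajectory] = []
    for tr in tracks.trajectories:
        if _duration(tr) < cfg.min_duration:
            report.n_tracks_removed_duration += 1
        elif trajectory_path_length(tr) < cfg.min_path_length:
            report.n_tracks_removed_length += 1
        else:
            survivors.append(tr)

    samples = instantaneous_speeds(
        TrackSet(survivors, frame_interval=tracks.frame_interval, source=tracks.source))
    report.n_speed_samples_before_cutoff = len(samples)
    retained = [s for s in samples if s.speed <= cfg.v_max]
    report.n_speed_samples_removed_by_cutoff = len(samples) - len(retained)
    logger.info(
        "apply_filters: %d tracks in, %d removed (duration), %d removed (length); "
        "%d samples, %d above %g µm/s (%.3f%%)",
        report.n_tracks_in, report.n_tracks_removed_duration,
        report.n_tracks_removed_length, report.n_speed_samples_before_cutoff,
        report.n_speed_samples_removed_by_cutoff, cfg.v_max,
        report.cutoff_excluded_percent)
    return retained, report


def speeds_array(samples: list[SpeedSample]) -> np.ndarray:
    """Pool SpeedSample speeds into a float array (µm/s)."""
    return np.asarray([s.speed for s in samples], dtype=float)


def summarize_speeds(samples) -> SpeedSummary:
    """Mean and sample standard deviation of a set of speeds.

    Accepts either SpeedSample lists or bare numeric arrays.  An empty input
    yields an explicit empty summary, not an exception; a single value has
    no defined sd.
    """
    if len(samples) and isinstance(samples[0], SpeedSample):
        values = speeds_array(samples)
    else:
        values = np.asarray(samples, dtype=float)
    n = values.size
    if n == 0:
        return SpeedSummary(0, None, None)
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if n >= 2 else None
    return SpeedSummary(n, mean, sd)
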