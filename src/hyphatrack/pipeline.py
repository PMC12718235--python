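"""End-to-end dispersal-speed analysis: read → filter → fit → split → compare.

The flow mirrors the study's statistical analysis: per input file, tracks
are read and filtered and their instantaneous speeds pooled per population;
each population's pooled speeds are fitted against the candidate pool and
ranked; the two populations' best-fit densities are intersected inside the
low-speed bracket to choose the slow/fast threshold; regime summaries and
slow fractions are produced per file and combined; finally the full
distributions are compared by the Kolmogorov–Smirnov test and the regime
means by Kruskal–Wallis tests.  Every stochastic stage is seeded, every
choice logged, so a report is reproducible byte-for-byte from its config.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import __version__
from .dist_fitting import FitResult, ModelRanking, default_pool, rank_models
from .nonparam_tests import TestResult, kruskal_wallis, ks_two_sample
from .regime_analysis import RegimeSplit, select_threshold, split_at
from .speed_metrics import (
    FilterConfig,
    FilterReport,
    apply_filters,
    speeds_array,
    summarize_speeds,
)
from .trajectory_io import TrackSet, read_tracks

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "RunReport", "analyze_populations", "render_table"]


@dataclass(frozen=True)
class AnalysisConfig:
    """All knobs of one analysis run, serializable into the report."""

    dialect: str = "minimal"
    calibration_um_per_unit: float = 1.0
    frame_interval_s: float = 0.024
    filter: FilterConfig = field(default_factory=FilterConfig)
    criterion: str = "bic"
    n_restarts: int = 20
    bracket: tuple[float, float] = (1.0, 10.0)
    subrange_cut: float = 60.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        io = raw.get("io", {})
        filt = raw.get("filter", {})
        fitting = raw.get("fitting", {})
        regime = raw.get("regime", {})
        return cls(
            dialect=io.get("dialect", "minimal"),
            calibration_um_per_unit=float(io.get("calibration_um_per_unit", 1.0)),
            frame_interval_s=float(io.get("frame_interval_s", 0.024)),
            filter=FilterConfig(
                v_max=float(filt.get("v_max", 100.0)),
                min_path_length=float(filt.get("min_path_length", 5.0)),
                min_duration=float(filt.get("min_duration", 0.25)),
            ),
            criterion=fitting.get("criterion", "bic"),
            n_restarts=int(fitting.get("n_restarts", 20)),
            bracket=tuple(regime.get("bracket", (1.0, 10.0))),
            subrange_cut=float(regime.get("cut", 60.0)),
            seed=int(raw.get("seed", 0)),
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bracket"] = list(self.bracket)
        return d


@dataclass
class FileResult:
    name: str
    filter_report: FilterReport
    speeds: np.ndarray


@dataclass
class PopulationResult:
    name: str
    files: list[FileResult]
    ranking: ModelRanking | None

    @property
    def speeds(self) -> np.ndarray:
        if not self.files:
            return np.empty(0)
        return np.concatenate([f.speeds for f in self.files])

    @property
    def best(self) -> FitResult | None:
        return self.ranking.best if self.ranking is not None else None


@dataclass
class RunReport:
    """Complete result of one analysis run, JSON-serializable."""

    config: AnalysisConfig
    populations: dict[str, PopulationResult]
    threshold: float | None = None
    intersection_roots: tuple[float, ...] = ()
    splits: dict[str, RegimeSplit] = field(default_factory=dict)
    per_file_splits: dict[str, dict[str, RegimeSplit]] = field(default_factory=dict)
    ks: TestResult | None = None
    kw_slow: TestResult | None = None
    kw_fast: TestResult | None = None
    warnings: list[str] = field(default_factory=list)
    version: str = __version__

    def to_dict(self) -> dict:
        pops = {}
        for name, pop in self.populations.items():
            pops[name] = {
                "files": [
                    {"name": f.name,
                     "filter_report": f.filter_report.to_dict(),
                     "n_retained": int(f.speeds.size)}
                    for f in pop.files
                ],
                "n_measurements": int(pop.speeds.size),
                "ranking": pop.ranking.to_records() if pop.ranking else None,
                "best_family": pop.best.spec.name if pop.best else None,
            }
        return {
            "version": self.version,
            "config": self.config.to_dict(),
            "populations": pops,
            "threshold_um_per_s": self.threshold,
            "intersection_roots": list(self.intersection_roots),
            "regime_splits": {k: v.to_dict() for k, v in self.splits.items()},
            "per_file_regime_splits": {
                pop: {f: s.to_dict() for f, s in files.items()}
                for pop, files in self.per_file_splits.items()
            },
            "ks_test": self.ks.to_dict() if self.ks else None,
            "kruskal_wallis_slow": self.kw_slow.to_dict() if self.kw_slow else None,
            "kruskal_wallis_fast": self.kw_fast.to_dict() if self.kw_fast else None,
            "warnings": self.warnings,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)


def _load_population(
    name: str,
    inputs: Sequence,
    config: AnalysisConfig,
) -> PopulationResult:
    files: list[FileResult] = []
    for item in inputs:
        if isinstance(item, TrackSet):
            tracks, label = item, item.source or f"{name}[{len(files)}]"
        else:
            tracks = read_tracks(item, dialect=config.dialect,
                                 calibration=config.calibration_um_per_unit,
                                 frame_interval=config.frame_interval_s)
            label = Path(item).name
        retained, report = apply_filters(tracks, config.filter)
        files.append(FileResult(label, report, speeds_array(retained)))
    return PopulationResult(name, files, ranking=None)


def analyze_populations(
    populations: Mapping[str, Sequence],
    config: AnalysisConfig | None = None,
) -> RunReport:
    """Run the full pipeline on one or more populations of track files.

    ``populations`` maps a population name (e.g. a strain) to a list of
    inputs, each either a path to a track CSV or an in-memory TrackSet.
    Model ranking runs per population; threshold selection and the
    between-population tests require exactly two non-empty populations and
    are skipped (with a warning recorded in the report) otherwise.
    """
    if not populations:
        raise ValueError("need at least one population")
    config = config or AnalysisConfig()
    report = RunReport(config=config, populations={})

    for i, (name, inputs) in enumerate(populations.items()):
        pop = _load_population(name, inputs, config)
        if pop.speeds.size >= 10:
            pop.ranking = rank_models(
                pop.speeds, pool=default_pool((0.0, config.filter.v_max)),
                criterion=config.criterion, seed=config.seed + 97 * i,
                n_restarts=config.n_restarts)
            logger.info("population %s: n=%d, best fit %s",
                        name, pop.speeds.size, pop.best.spec.name)
        else:
            report.warnings.append(
                f"population {name!r}: only {pop.speeds.size} retained samples; "
                "model fitting skipped")
        report.populations[name] = pop

    fitted = [p for p in report.populations.values() if p.best is not None]
    if len(fitted) == 2:
        report.threshold = select_threshold(
            fitted[0].best, fitted[1].best, bracket=config.bracket)
        if report.threshold is None:
            report.warnings.append(
                f"no density intersection in bracket {config.bracket}")
        else:
            from .regime_analysis import pdf_intersections
            inter = pdf_intersections(fitted[0].best, fitted[1].best, config.bracket)
            report.intersection_roots = inter.roots
    elif len(fitted) < 2:
        report.warnings.append(
            "between-population analysis needs two fitted populations; skipped")

    if report.threshold is not None:
        pooled = {name: pop.speeds for name, pop in report.populations.items()}
        report.splits = split_at(pooled, report.threshold)
        report.per_file_splits = {
            name: split_at({f.name: f.speeds for f in pop.files}, report.threshold)
            for name, pop in report.populations.items()
        }
        names = [p.name for p in fitted]
        a, b = (report.populations[n].speeds for n in names)
        report.ks = ks_two_sample(a, b)
        slow = [report.splits[n].slow for n in names]
        fast = [report.splits[n].fast for n in names]
        if all(s.size for s in slow):
            report.kw_slow = kruskal_wallis(slow)
        if all(f.size for f in fast):
            report.kw_fast = kruskal_wallis(fast)
    return report


def _fmt(summary) -> str:
    return str(summary)


def render_table(report: RunReport) -> str:
    """Render per-file and combined regime summaries as a plain-text table.

    Layout per population: one row per input file plus a combined row, with
    the number of independent speed measurements and the mean ± sd speed in
    the slow and fast regimes (em-dash for an empty regime).
    """
    lines: list[str] = []
    header = f"{'dataset':<42}{'N':>8}  {'slow speed (µm/s)':>20}  {'fast speed (µm/s)':>20}"
    for name, pop in report.populations.items():
        lines.append(name)
        lines.append(header)
        per_file = report.per_file_splits.get(name, {})
        for f in pop.files:
            split = per_file.get(f.name)
            slow = _fmt(split.slow_summary) if split else "—"
            fast = _fmt(split.fast_summary) if split else "—"
            lines.append(f"{f.name:<42}{f.speeds.size:>8}  {slow:>20}  {fast:>20}")
        combined = report.splits.get(name)
        slow = _fmt(combined.slow_summary) if combined else "—"
        fast = _fmt(combined.fast_summary) if combined else "—"
        lines.append(f"{'Combined data for ' + name:<42}{pop.speeds.size:>8}  "
                     f"{slow:>20}  {fast:>20}")
        lines.append("")
    if report.threshold is not None:
        lines.append(f"slow/fast threshold: {report.threshold:.2f} µm/s "
                     f"(density intersection in bracket {report.config.bracket})")
        for name, split in report.splits.items():
            lines.append(f"  {name}: slow fraction {split.slow_fraction:.2f}%")
    if report.ks is not None:
        lines.append(f"KS test (full distributions): D={report.ks.statistic:.4f}, "
                     f"p={report.ks.p_value:.3g}")
    if report.kw_slow is not None:
        lines.append(f"Kruskal–Wallis (slow regime): H={report.kw_slow.statistic:.4f}, "
                     f"p={report.kw_slow.p_value:.3g}")
    if report.kw_fast is not None:
        lines.append(f"Kruskal–Wallis (fast regime): H={report.kw_fast.statistic:.4f}, "
                     f"p={report.kw_fast.p_value:.3g}")
    return "\n".join(lines)
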