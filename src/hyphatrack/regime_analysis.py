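"""Slow/fast regime separation at intersections of fitted speed densities.

The two populations' best-fit densities are evaluated on a grid inside a
bracket (by default (1, 10) µm/s, the zoomed-in low-speed region where the
curves cross); each sign change of their difference is refined by bisection
to a root.  The smallest root in the bracket becomes the slow/fast
threshold: measurements strictly below it are "slow", measurements at or
above it are "fast" (the tie convention is immaterial for continuous data
but is fixed and documented).  A robustness check refits each sub-range
independently with the support truncated to the sub-range, mirroring the
observation that even the split halves are best described by mixtures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import optimize

from .dist_fitting import (
    DistributionSpec,
    FitResult,
    ModelRanking,
    FitInputError,
    default_pool,
    rank_models,
)
from .speed_metrics import SpeedSummary, summarize_speeds

logger = logging.getLogger(__name__)

__all__ = [
    "IntersectionSet",
    "RegimeSplit",
    "SubrangeRefit",
    "pdf_intersections",
    "select_threshold",
    "split_at",
    "subrange_refit",
]


@dataclass(frozen=True)
class IntersectionSet:
    """Sorted speeds where two densities cross within a search interval."""

    roots: tuple[float, ...]
    interval: tuple[float, float]
    grid_points: int

    def __len__(self) -> int:
        return len(self.roots)


@dataclass
class RegimeSplit:
    """One population's speeds partitioned at a threshold, with summaries."""

    threshold: float
    slow: np.ndarray
    fast: np.ndarray
    slow_summary: SpeedSummary
    fast_summary: SpeedSummary

    @property
    def n(self) -> int:
        return self.slow.size + self.fast.size

    @property
    def slow_fraction(self) -> float:
        """Percent of measurements below the threshold (0 for an empty population)."""
        return 100.0 * self.slow.size / self.n if self.n else 0.0

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "n": self.n,
            "slow": {"n": self.slow_summary.n, "mean": self.slow_summary.mean,
                     "sd": self.slow_summary.sd},
            "fast": {"n": self.fast_summary.n, "mean": self.fast_summary.mean,
                     "sd": self.fast_summary.sd},
            "slow_fraction_percent": self.slow_fraction,
        }


def _as_pdf(fit) -> Callable[[np.ndarray], np.ndarray]:
    if isinstance(fit, FitResult):
        if not fit.converged:
            raise ValueError("cannot intersect a non-converged fit")
        return fit.pdf
    if callable(fit):
        return fit
    raise TypeError("expected a FitResult or a pdf callable")


def pdf_intersections(
    fit_a,
    fit_b,
    interval: tuple[float, float] = (1.0, 10.0),
    grid_points: int = 10_000,
) -> IntersectionSet:
    """Locate crossings of two densities inside ``interval``.

    Sign changes of ``pdf_a - pdf_b`` on a uniform grid are bracketed and
    refined by bisection to an x-tolerance below 1e-9; tangential contacts
    (touching without a sign change) are not reported.  No sign change at
    all yields an empty set, not an error.

    Either argument may be a :class:`FitResult` or any callable density
    (the latter allows closed-form checks against untruncated models).
    """
    lo, hi = interval
    if not lo < hi:
        raise ValueError("interval must satisfy lo < hi")
    pdf_a, pdf_b = _as_pdf(fit_a), _as_pdf(fit_b)
    grid = np.linspace(lo, hi, grid_points)
    diff = np.asarray(pdf_a(grid), dtype=float) - np.asarray(pdf_b(grid), dtype=float)

    roots: list[float] = []
    sign = np.sign(diff)
    for i in np.flatnonzero(sign[:-1] * sign[1:] < 0):
        f = lambda v: float(pdf_a(v) - pdf_b(v))  # noqa: E731
        root = optimize.brentq(f, grid[i], grid[i + 1], xtol=1e-12, rtol=8.9e-16)
        roots.append(float(root))
    # grid points landing exactly on a crossing
    for i in np.flatnonzero(sign == 0):
        if 0 < i < grid_points - 1 and sign[i - 1] * sign[i + 1] < 0:
            roots.append(float(grid[i]))
    return IntersectionSet(tuple(sorted(roots)), (lo, hi), grid_points)


def select_threshold(
    fit_a,
    fit_b,
    bracket: tuple[float, float] = (1.0, 10.0),
    grid_points: int = 10_000,
) -> float | None:
    """The regime boundary: the largest density crossing inside ``bracket``.

    Two fitted mixtures typically cross more than once: low crossings sit
    inside the slow bulk where both densities are large, while the upper
    crossing marks the hand-over from the slow bulk to the fast tail — the
    biologically meaningful slow/fast boundary — so the largest root is
    selected.  All roots found are logged so the (deliberately explicit)
    choice is auditable; ``None`` when the densities do not cross at all.
    """
    inter = pdf_intersections(fit_a, fit_b, bracket, grid_points)
    if not inter.roots:
        logger.warning("no density intersection in bracket %s", bracket)
        return None
    logger.info("density intersections in %s: %s; selected %.6g µm/s",
                bracket, [round(r, 6) for r in inter.roots], inter.roots[-1])
    return inter.roots[-1]


def split_at(
    samples_by_population: Mapping[str, Sequence[float]],
    threshold: float,
) -> dict[str, RegimeSplit]:
    """Partition each population's speeds into slow (< threshold) and fast (>=)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    out: dict[str, RegimeSplit] = {}
    for name, values in samples_by_population.items():
        v = np.asarray(values, dtype=float)
        slow = v[v < threshold]
        fast = v[v >= threshold]
        out[name] = RegimeSplit(
            threshold=float(threshold),
            slow=slow,
            fast=fast,
            slow_summary=summarize_speeds(slow),
            fast_summary=summarize_speeds(fast),
        )
    return out


@dataclass
class SubrangeRefit:
    """Independent model rankings for the sub-ranges below and above a cut."""

    cut: float
    ranking_slow: ModelRanking | None
    ranking_fast: ModelRanking | None
    slow_failure: str | None = None
    fast_failure: str | None = None

    @property
    def mixtures_dominate(self) -> bool:
        """True when the top-3 of *both* sub-rankings are all mixture models."""
        for ranking in (self.ranking_slow, self.ranking_fast):
            if ranking is None:
                return False
            top = ranking.top(3)
            if len(top) < 3 or not all(f.spec.mixture for f in top):
                return False
        return True


def subrange_refit(
    samples,
    cut: float = 60.0,
    pool: Sequence[DistributionSpec] | None = None,
    seed: int = 0,
    v_max: float = 100.0,
    n_restarts: int = 20,
) -> SubrangeRefit:
    """Split speeds at ``cut`` and rank models independently on each half.

    The support of each candidate is truncated to its sub-range ((0, cut]
    below, [cut, v_max] above) so the likelihoods remain proper.  A
    sub-range too small to fit is flagged while the other is still returned.
    """
    x = np.asarray(samples, dtype=float)
    slow, fast = x[x < cut], x[x >= cut]
    result = SubrangeRefit(cut=float(cut), ranking_slow=None, ranking_fast=None)

    for label, values, support in (
        ("slow", slow, (0.0, cut)),
        ("fast", fast, (cut, v_max)),
    ):
        if pool is None:
            sub_pool = default_pool(support)
        else:
            sub_pool = [replace(spec, support=support) for spec in pool]
        try:
            ranking = rank_models(values, sub_pool, seed=seed, n_restarts=n_restarts)
        except (FitInputError, RuntimeError, ValueError) as exc:
            setattr(result, f"{label}_failure", str(exc))
            logger.warning("subrange_refit %s side failed: %s", label, exc)
            continue
        setattr(result, f"ranking_{label}", ranking)
    return result
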