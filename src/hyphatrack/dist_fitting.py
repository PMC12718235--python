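"""Maximum-likelihood fitting and ranking of speed-distribution models.

Cell speed data on mycelial networks are nonnegative and hard-cut at the
artifact cutoff ``v_max``, so every candidate density is truncated to a
support interval ``(lo, hi]`` and renormalized there.  Candidates are seven
single families (lognormal, Cauchy, normal, gamma, Weibull, exponential,
uniform) and six two-component mixtures pairing each non-uniform family
with a uniform background:

    f(x) = w * f_component(x) / Z_component + (1 - w) / (hi - lo)

where ``Z_component`` renormalizes the component to the support and the
uniform bounds are fixed to the support (this keeps the mixture
identifiable).  Parameters are estimated by bounded multi-start numerical
likelihood maximization (not EM: the truncated Cauchy admits no closed-form
EM step, and multiple starts guard against the mixture likelihood's local
optima).  Fits are ranked by log-likelihood and the AIC, BIC and
Hannan-Quinn information criteria:

    AIC = 2k - 2 logL
    BIC = k ln(n) - 2 logL
    HQC = 2k ln(ln n) - 2 logL

with ``k`` the number of free parameters (the mixture weight counts; the
fixed uniform bounds do not).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "DistributionSpec",
    "FitResult",
    "ICSet",
    "ModelRanking",
    "FitInputError",
    "UnfittedError",
    "default_pool",
    "pdf",
    "fit_mle",
    "information_criteria",
    "rank_models",
]

_NLL_PENALTY = 1e12


class FitInputError(ValueError):
    """Samples violate the fit preconditions (outside support, too few)."""


class UnfittedError(RuntimeError):
    """PDF/CDF evaluation requested on a spec with no fitted parameters."""


# --------------------------------------------------------------------------
# family registry: base scipy distribution + parameterization metadata

class _Family(NamedTuple):
    name: str
    param_names: tuple[str, ...]
    frozen: Callable[[np.ndarray], "stats.rv_continuous"]
    bounds: Callable[[np.ndarray, float, float], list[tuple[float, float]]]
    init: Callable[[np.ndarray, float, float], np.ndarray]
    logpdf: Callable[[np.ndarray, np.ndarray], np.ndarray]
    cdf: Callable[[np.ndarray, np.ndarray], np.ndarray]


_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


# closed-form log-densities and CDFs (hot path of the likelihood; the scipy
# frozen objects above are kept only for ppf-based sampling)

def _lognorm_logpdf(x, p):
    lx = np.log(x)
    return -lx - math.log(p[1]) - _LOG_SQRT_2PI - ((lx - p[0]) / p[1]) ** 2 / 2.0


def _lognorm_cdf(v, p):
    with np.errstate(divide="ignore"):
        return special.ndtr((np.log(np.maximum(v, 1e-300)) - p[0]) / p[1]) * (v > 0)


def _cauchy_logpdf(x, p):
    z = (x - p[0]) / p[1]
    return -math.log(math.pi * p[1]) - np.log1p(z * z)


def _cauchy_cdf(v, p):
    return np.arctan((v - p[0]) / p[1]) / math.pi + 0.5


def _normal_logpdf(x, p):
    return -math.log(p[1]) - _LOG_SQRT_2PI - ((x - p[0]) / p[1]) ** 2 / 2.0


def _normal_cdf(v, p):
    return special.ndtr((v - p[0]) / p[1])


def _gamma_logpdf(x, p):
    a, th = p
    return (a - 1.0) * np.log(x) - x / th - special.gammaln(a) - a * math.log(th)


def _gamma_cdf(v, p):
    return special.gammainc(p[0], np.maximum(v, 0.0) / p[1])


def _weibull_logpdf(x, p):
    c, lam = p
    z = x / lam
    return math.log(c / lam) + (c - 1.0) * np.log(z) - z**c


def _weibull_cdf(v, p):
    return -np.expm1(-((np.maximum(v, 0.0) / p[1]) ** p[0]))


def _expon_logpdf(x, p):
    return -math.log(p[0]) - x / p[0]


def _expon_cdf(v, p):
    return -np.expm1(-np.maximum(v, 0.0) / p[0])


def _lognorm_frozen(p):
    return stats.lognorm(s=p[1], scale=math.exp(p[0]))


def _lognorm_init(x, lo, hi):
    lx = np.log(x)
    return np.array([float(np.mean(lx)), max(float(np.std(lx)), 1e-2)])


def _cauchy_init(x, lo, hi):
    q1, q2, q3 = np.percentile(x, [25, 50, 75])
    return np.array([float(q2), max(float((q3 - q1) / 2), 1e-2)])


def _normal_init(x, lo, hi):
    return np.array([float(np.mean(x)), max(float(np.std(x)), 1e-2)])


def _gamma_frozen(p):
    return stats.gamma(a=p[0], scale=p[1])


def _gamma_init(x, lo, hi):
    m, v = float(np.mean(x)), float(np.var(x))
    v = max(v, 1e-6)
    return np.array([np.clip(m * m / v, 0.05, 500.0), np.clip(v / m, 1e-3, hi)])


def _weibull_frozen(p):
    return stats.weibull_min(c=p[0], scale=p[1])


def _weibull_init(x, lo, hi):
    return np.array([1.2, max(float(np.mean(x)), 1e-2)])


def _expon_frozen(p):
    return stats.expon(scale=p[0])


def _expon_init(x, lo, hi):
    return np.array([max(float(np.mean(x) - lo), 1e-2)])


_FAMILIES: dict[str, _Family] = {
    "lognormal": _Family(
        "lognormal", ("mu", "sigma"), _lognorm_frozen,
        lambda x, lo, hi: [(-15.0, math.log(hi) + 3.0), (1e-3, 10.0)],
        _lognorm_init, _lognorm_logpdf, _lognorm_cdf),
    "cauchy": _Family(
        "cauchy", ("x0", "gamma"), lambda p: stats.cauchy(loc=p[0], scale=p[1]),
        lambda x, lo, hi: [(-hi, 2.0 * hi), (1e-3, 2.0 * hi)],
        _cauchy_init, _cauchy_logpdf, _cauchy_cdf),
    "normal": _Family(
        "normal", ("mu", "sigma"), lambda p: stats.norm(loc=p[0], scale=p[1]),
        lambda x, lo, hi: [(-hi, 2.0 * hi), (1e-3, 2.0 * hi)],
        _normal_init, _normal_logpdf, _normal_cdf),
    "gamma": _Family(
        "gamma", ("shape", "scale"), _gamma_frozen,
        lambda x, lo, hi: [(5e-2, 500.0), (1e-4, 10.0 * hi)],
        _gamma_init, _gamma_logpdf, _gamma_cdf),
    "weibull": _Family(
        "weibull", ("shape", "scale"), _weibull_frozen,
        lambda x, lo, hi: [(5e-2, 50.0), (1e-4, 10.0 * hi)],
        _weibull_init, _weibull_logpdf, _weibull_cdf),
    "exponential": _Family(
        "exponential", ("scale",), _expon_frozen,
        lambda x, lo, hi: [(1e-4, 10.0 * hi)],
        _expon_init, _expon_logpdf, _expon_cdf),
}


@dataclass(frozen=True)
class DistributionSpec:
    """A candidate model: a family, optionally mixed with a uniform background.

    ``support`` is the half-open interval ``(lo, hi]`` (µm/s) to which the
    component density is truncated; the uniform background spans the same
    interval with fixed bounds.
    """

    family: str
    mixture: bool = False
    support: tuple[float, float] = (0.0, 100.0)

    def __post_init__(self) -> None:
        if self.family != "uniform" and self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "uniform" and self.mixture:
            raise ValueError("the uniform background cannot be mixed with itself")
        lo, hi = self.support
        if not lo < hi:
            raise ValueError("support must satisfy lo < hi")

    @property
    def name(self) -> str:
        return f"{self.family}+uniform" if self.mixture else self.family

    @property
    def param_names(self) -> tuple[str, ...]:
        if self.family == "uniform":
            return ()
        names = _FAMILIES[self.family].param_names
        return names + ("w",) if self.mixture else names

    @property
    def n_params(self) -> int:
        return len(self.param_names)


def default_pool(support: tuple[float, float] = (0.0, 100.0)) -> list[DistributionSpec]:
    """The default candidate pool: 7 single families + 6 component+uniform mixtures."""
    singles = [DistributionSpec(f, support=support) for f in _FAMILIES]
    singles.append(DistributionSpec("uniform", support=support))
    mixtures = [DistributionSpec(f, mixture=True, support=support) for f in _FAMILIES]
    return singles + mixtures


# --------------------------------------------------------------------------
# log-density machinery

def _component_logpdf(spec: DistributionSpec, theta: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Log-density of the truncated component, -inf outside the support."""
    lo, hi = spec.support
    fam = _FAMILIES[spec.family]
    z = float(fam.cdf(np.asarray(hi), theta) - fam.cdf(np.asarray(lo), theta))
    if not np.isfinite(z) or z < 1e-300:
        return np.full(np.shape(x), -np.inf)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        lp = fam.logpdf(x, theta) - math.log(z)
    return np.where(_inside(x, lo, hi), np.nan_to_num(lp, nan=-np.inf), -np.inf)


def _inside(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    # support is (0, hi] for the full range but closed at lo for sub-ranges
    # starting above zero ([cut, hi]), where samples sit exactly on the cut
    lower = x > lo if lo == 0.0 else x >= lo
    return lower & (x <= hi)


def _model_logpdf(spec: DistributionSpec, params: np.ndarray, x: np.ndarray) -> np.ndarray:
    lo, hi = spec.support
    x = np.asarray(x, dtype=float)
    inside = _inside(x, lo, hi)
    log_u = -math.log(hi - lo)
    if spec.family == "uniform":
        return np.where(inside, log_u, -np.inf)
    if not spec.mixture:
        return _component_logpdf(spec, params, x)
    theta, w = params[:-1], float(params[-1])
    comp = _component_logpdf(spec, theta, x)
    if w <= 0.0:
        out = np.full_like(comp, log_u)
    elif w >= 1.0:
        out = comp
    else:
        out = np.logaddexp(math.log(w) + comp, math.log1p(-w) + log_u)
    return np.where(inside, out, -np.inf)


@dataclass(frozen=True)
class FitResult:
    """A fitted model: evaluates its PDF/CDF, samples, and carries its logL."""

    spec: DistributionSpec
    params: dict[str, float]
    log_likelihood: float
    n: int
    converged: bool = True
    n_restarts_used: int = 0
    boundary: bool = False

    def _param_vector(self) -> np.ndarray:
        return np.array([self.params[k] for k in self.spec.param_names])

    def logpdf(self, x) -> np.ndarray:
        return _model_logpdf(self.spec, self._param_vector(), np.asarray(x, dtype=float))

    def pdf(self, x) -> np.ndarray:
        with np.errstate(over="ignore"):
            return np.exp(self.logpdf(x))

    def cdf(self, x) -> np.ndarray:
        lo, hi = self.spec.support
        x = np.clip(np.asarray(x, dtype=float), lo, hi)
        u = (x - lo) / (hi - lo)
        if self.spec.family == "uniform":
            return u
        p = self._param_vector()
        theta = p[:-1] if self.spec.mixture else p
        dist = _FAMILIES[self.spec.family].frozen(theta)
        z = dist.cdf(hi) - dist.cdf(lo)
        comp = (dist.cdf(x) - dist.cdf(lo)) / z
        if not self.spec.mixture:
            return comp
        w = self.params["w"]
        return w * comp + (1.0 - w) * u

    def sample(self, size: int, seed: int | np.random.Generator = 0) -> np.ndarray:
        """Draw speeds from the fitted model by inverse-CDF of the truncated component."""
        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        lo, hi = self.spec.support
        if self.spec.family == "uniform":
            return rng.uniform(lo, hi, size)
        p = self._param_vector()
        theta = p[:-1] if self.spec.mixture else p
        dist = _FAMILIES[self.spec.family].frozen(theta)
        c_lo, c_hi = dist.cdf(lo), dist.cdf(hi)

        def draw_component(k: int) -> np.ndarray:
            u = rng.uniform(c_lo, c_hi, k)
            return dist.ppf(u)

        if not self.spec.mixture:
            return draw_component(size)
        w = self.params["w"]
        from_comp = rng.random(size) < w
        out = rng.uniform(lo, hi, size)
        k = int(from_comp.sum())
        if k:
            out[from_comp] = draw_component(k)
        return out


def pdf(fit: FitResult, x) -> np.ndarray:
    """Density of a fitted model at ``x`` (zero outside the support)."""
    if not isinstance(fit, FitResult):
        raise UnfittedError("pdf() requires a FitResult with fitted parameters")
    return fit.pdf(x)


# --------------------------------------------------------------------------
# fitting

def _check_samples(x: np.ndarray, spec: DistributionSpec) -> None:
    lo, hi = spec.support
    if np.any(~np.isfinite(x)):
        raise FitInputError("samples contain non-finite values")
    if np.any(x <= 0) or np.any(x < lo) or np.any(x > hi):
        raise FitInputError(
            f"samples outside the support ({lo}, {hi}] (min {x.min()}, max {x.max()})")


def _initial_points(
    spec: DistributionSpec,
    x: np.ndarray,
    bounds: list[tuple[float, float]],
    n_restarts: int,
    rng: np.random.Generator,
    nested: FitResult | None,
) -> list[np.ndarray]:
    fam = _FAMILIES[spec.family]
    lo, hi = spec.support
    theta0 = np.clip(fam.init(x, lo, hi),
                     [b[0] for b in bounds[: len(fam.param_names)]],
                     [b[1] for b in bounds[: len(fam.param_names)]])
    points: list[np.ndarray] = []
    if spec.mixture:
        for w0 in (0.7, 0.95):
            points.append(np.append(theta0, w0))
        if nested is not None and nested.converged:
            theta_n = np.array([nested.params[k] for k in nested.spec.param_names])
            points.append(np.append(theta_n, 1.0 - 1e-4))
    else:
        points.append(theta0)
    lows = np.array([b[0] for b in bounds])
    highs = np.array([b[1] for b in bounds])
    while len(points) < n_restarts:
        points.append(rng.uniform(lows, highs))
    return points[:n_restarts]


def fit_mle(
    samples,
    spec: DistributionSpec,
    n_restarts: int = 20,
    seed: int = 0,
) -> FitResult:
    """Fit ``spec`` to speed samples by bounded multi-start maximum likelihood.

    Deterministic given ``seed``.  The first starting points are
    moment-based (and, for mixtures, the nested single-family fit with the
    weight near 1, which guarantees the mixture's likelihood dominates its
    nested family's up to optimizer tolerance); the remainder are drawn
    uniformly within the parameter bounds.  Non-convergence of every
    restart yields a flagged result, not an exception.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 10:
        raise FitInputError(f"need at least 10 samples to fit, got {x.size}")
    _check_samples(x, spec)
    lo, hi = spec.support

    if spec.family == "uniform":
        logl = -x.size * math.log(hi - lo)
        return FitResult(spec, {}, logl, int(x.size), converged=True)

    bounds = _FAMILIES[spec.family].bounds(x, lo, hi)
    nested = None
    if spec.mixture:
        bounds = bounds + [(0.0, 1.0)]
        nested = fit_mle(x, replace(spec, mixture=False),
                         n_restarts=max(3, n_restarts // 3), seed=seed + 1)

    def nll(p: np.ndarray) -> float:
        lp = _model_logpdf(spec, p, x)
        total = float(np.sum(lp))
        if not np.isfinite(total):
            return _NLL_PENALTY
        return -total

    rng = np.random.default_rng(seed)
    best: optimize.OptimizeResult | None = None
    n_used = 0
    for x0 in _initial_points(spec, x, bounds, n_restarts, rng, nested):
        n_used += 1
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
        if not np.isfinite(res.fun) or res.fun >= _NLL_PENALTY:
            continue
        if best is None or res.fun < best.fun:
            best = res

    if best is None:
        return FitResult(spec, dict.fromkeys(spec.param_names, float("nan")),
                         float("-inf"), int(x.size), converged=False,
                         n_restarts_used=n_used)

    params = dict(zip(spec.param_names, (float(v) for v in best.x)))
    boundary = spec.mixture and (params["w"] < 1e-3 or params["w"] > 1 - 1e-3)
    return FitResult(spec, params, -float(best.fun), int(x.size),
                     converged=True, n_restarts_used=n_used, boundary=boundary)


class ICSet(NamedTuple):
    log_likelihood: float
    aic: float
    bic: float
    hqc: float


def information_criteria(fit: FitResult) -> ICSet:
    """Log-likelihood, AIC, BIC and Hannan-Quinn criterion of a converged fit."""
    if not fit.converged:
        raise ValueError("information criteria are undefined for a non-converged fit")
    n, k, ll = fit.n, fit.spec.n_params, fit.log_likelihood
    if n <= math.e:
        raise ValueError(f"HQC requires n > e, got n={n}")
    return ICSet(
        log_likelihood=ll,
        aic=2.0 * k - 2.0 * ll,
        bic=k * math.log(n) - 2.0 * ll,
        hqc=2.0 * k * math.log(math.log(n)) - 2.0 * ll,
    )


_CRITERIA = {"bic", "aic", "hqc", "logl"}


@dataclass
class ModelRanking:
    """Candidate fits sorted by an information criterion (or logL)."""

    criterion: str
    fits: list[FitResult] = field(default_factory=list)
    failures: dict[str, str] = field(default_factory=dict)

    @property
    def best(self) -> FitResult:
        return self.fits[0]

    def top(self, k: int = 10) -> list[FitResult]:
        return self.fits[:k]

    def to_frame(self, k: int = 10) -> pd.DataFrame:
        rows = []
        for rank, fit in enumerate(self.top(k), start=1):
            ics = information_criteria(fit)
            rows.append({
                "rank": rank,
                "family": fit.spec.name,
                "params": "; ".join(f"{name}={v:.4g}" for name, v in fit.params.items()),
                "logL": ics.log_likelihood,
                "AIC": ics.aic,
                "BIC": ics.bic,
                "HQC": ics.hqc,
            })
        return pd.DataFrame(rows)

    def to_records(self, k: int = 10) -> list[dict]:
        recs = []
        for rank, fit in enumerate(self.top(k), start=1):
            ics = information_criteria(fit)
            recs.append({
                "rank": rank, "family": fit.spec.name, "params": fit.params,
                "logL": ics.log_likelihood, "AIC": ics.aic, "BIC": ics.bic,
                "HQC": ics.hqc, "boundary": fit.boundary,
            })
        return recs


def rank_models(
    samples,
    pool: Sequence[DistributionSpec] | None = None,
    criterion: str = "bic",
    seed: int = 0,
    n_restarts: int = 20,
) -> ModelRanking:
    """Fit every spec in the pool and sort by the chosen criterion.

    Ascending for information criteria, descending for log-likelihood.
    Deterministic given ``seed`` and invariant to the order of ``samples``.
    """
    criterion = criterion.lower()
    if criterion not in _CRITERIA:
        raise ValueError(f"criterion must be one of {sorted(_CRITERIA)}")
    x = np.sort(np.asarray(samples, dtype=float))
    if pool is None:
        pool = default_pool()
    if not pool:
        raise ValueError("candidate pool is empty")

    fits: list[FitResult] = []
    failures: dict[str, str] = {}
    for i, spec in enumerate(pool):
        try:
            fit = fit_mle(x, spec, n_restarts=n_restarts, seed=seed + 1000 * i)
        except FitInputError as exc:
            failures[spec.name] = str(exc)
            continue
        if fit.converged:
            fits.append(fit)
        else:
            failures[spec.name] = "no restart converged"
    if not fits:
        raise RuntimeError(f"all candidate fits failed: {failures}")

    def key(fit: FitResult) -> float:
        ics = information_criteria(fit)
        if criterion == "logl":
            return -ics.log_likelihood
        return getattr(ics, criterion)

    fits.sort(key=key)
    return ModelRanking(criterion=criterion, fits=fits, failures=failures)
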