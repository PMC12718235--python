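"""Two-sample Kolmogorov–Smirnov and Kruskal–Wallis tests.

Both tests compare strain speed distributions without distributional
assumptions.  The KS statistic is the supremum distance between the two
empirical CDFs evaluated over the pooled sample points; the Kruskal–Wallis
H statistic uses midranks with the standard tie correction

    H = [12 / (N(N+1))] * sum_i n_i (Rbar_i - (N+1)/2)^2
        / (1 - sum_t (t^3 - t) / (N^3 - N))

Asymptotic p-values (Kolmogorov distribution with effective sample size
n_x n_y / (n_x + n_y); chi-square with g-1 degrees of freedom) are the
default — at the study's sample sizes (thousands of measurements per
strain) they are indistinguishable from exact ones.  Exact enumeration
(KS, small pooled n) and seeded label permutation (KW) are available for
small-sample verification.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

__all__ = ["TestResult", "ks_two_sample", "kruskal_wallis"]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n_per_group: tuple[int, ...]
    method: str

    def to_dict(self) -> dict:
        return {"statistic": self.statistic, "p_value": self.p_value,
                "n_per_group": list(self.n_per_group), "method": self.method}


def _ks_statistic(x: np.ndarray, y: np.ndarray) -> float:
    pooled = np.concatenate([x, y])
    ecdf_x = np.searchsorted(np.sort(x), pooled, side="right") / x.size
    ecdf_y = np.searchsorted(np.sort(y), pooled, side="right") / y.size
    return float(np.max(np.abs(ecdf_x - ecdf_y)))


def ks_two_sample(x, y, mode: str = "asymptotic") -> TestResult:
    """Two-sided two-sample Kolmogorov–Smirnov test.

    ``mode="exact"`` enumerates every partition of the pooled sample into
    groups of the observed sizes (permitted for pooled n <= 16) and reports
    the exact tail probability of D under the null.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    d = _ks_statistic(x, y)
    nx, ny = x.size, y.size

    if mode == "asymptotic":
        en = nx * ny / (nx + ny)
        p = float(stats.kstwobign.sf(np.sqrt(en) * d))
        method = "asymptotic (Kolmogorov distribution)"
    elif mode == "exact":
        if nx + ny > 16:
            raise ValueError("exact KS enumeration is limited to pooled n <= 16")
        pooled = np.concatenate([x, y])
        idx = range(nx + ny)
        count = total = 0
        for pick in combinations(idx, nx):
            mask = np.zeros(nx + ny, dtype=bool)
            mask[list(pick)] = True
            d_perm = _ks_statistic(pooled[mask], pooled[~mask])
            total += 1
            if d_perm >= d - 1e-12:
                count += 1
        p = count / total
        method = "exact (full enumeration)"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return TestResult(d, min(p, 1.0), (nx, ny), method)


def _kw_h(groups: list[np.ndarray]) -> float:
    """H with midranks and tie correction; 0 when all pooled values tie."""
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    offsets = np.cumsum([0] + [g.size for g in groups])
    h = 0.0
    for i, g in enumerate(groups):
        r_mean = ranks[offsets[i]:offsets[i + 1]].mean()
        h += g.size * (r_mean - (n_total + 1) / 2.0) ** 2
    h *= 12.0 / (n_total * (n_total + 1))
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - np.sum(counts**3 - counts) / (n_total**3 - n_total)
    if correction == 0.0:  # every pooled value identical
        return 0.0
    return float(h / correction)


def kruskal_wallis(
    groups,
    mode: str = "asymptotic",
    n_permutations: int = 10_000,
    seed: int = 0,
) -> TestResult:
    """Kruskal–Wallis rank test across two or more groups.

    ``mode="permutation"`` estimates the p-value by seeded random
    relabelling (``n_permutations`` draws).  All values identical across
    all groups is a degenerate but legal input: H = 0, p = 1.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    if any(g.size == 0 for g in gs):
        raise ValueError("every group must be non-empty")
    n_total = sum(g.size for g in gs)
    if n_total < 3:
        raise ValueError("need at least 3 observations in total")

    h = _kw_h(gs)
    df = len(gs) - 1
    pooled = np.concatenate(gs)
    if np.all(pooled == pooled[0]):
        return TestResult(0.0, 1.0, tuple(g.size for g in gs), "degenerate (all ties)")

    if mode == "asymptotic":
        p = float(stats.chi2.sf(h, df))
        method = f"asymptotic (chi-square, {df} df)"
    elif mode == "permutation":
        rng = np.random.default_rng(seed)
        sizes = np.cumsum([g.size for g in gs])[:-1]
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(pooled)
            if _kw_h(np.split(perm, sizes)) >= h - 1e-12:
                count += 1
        p = (count + 1) / (n_permutations + 1)
        method = f"permutation ({n_permutations} draws)"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return TestResult(h, min(p, 1.0), tuple(g.size for g in gs), method)
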