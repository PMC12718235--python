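# Methods

## Problem and scope

Motile bacteria disperse through water-unsaturated habitats along the
liquid films that coat fungal and oomycete hyphae ("fungal highways").
High-speed fluorescence video of individual cells moving on a mycelial
network, processed by an automated tracker, yields frame-wise positions of
thousands of short cell tracks. `hyphatrack` implements the downstream
statistics for such data: instantaneous-speed extraction with principled
exclusion rules, maximum-likelihood fitting of candidate speed
distributions (including heavy-tailed mixtures), information-criterion
model ranking, a slow/fast regime split at an intersection of fitted
densities, and nonparametric between-population comparisons. A seeded
synthetic-trajectory generator with a full imaging observation model makes
the entire pipeline testable without microscope data.

Because cells cannot be re-identified once they leave the focal plane, the
unit of analysis throughout is the *independent speed measurement* (one
inter-frame displacement), never the cell.

## Speeds and exclusion rules

The instantaneous speed of a cell is the Euclidean distance between its
positions in two **consecutive** frames divided by the inter-frame time
(default 0.024 s; always an explicit, logged parameter, since acquisition
metadata and file naming conventions can disagree). Pairs that span a
frame gap yield no measurement. Three exclusion rules are applied in a
fixed order:

1. **duration < 0.25 s** — tracks removed (cells crossing the focal plane
   transiently, whose out-of-plane motion corrupts planar speeds);
2. **path length < 5 µm** — tracks removed (cells rearranging inside
   microcolonies; the motion is real but is not dispersal). Path length
   sums all consecutive-detection displacements, including across gaps;
3. **speed > 100 µm/s** — individual measurements removed (tracking
   artifacts, e.g. identity switches between a cell leaving the plane and
   another entering).

Exclusions use strict inequalities; boundary values are retained. The
cutoff-excluded percentage is reported with the post-track-filter sample
count as denominator. The order (track-level rules first, then the
per-sample cutoff) is a fixed design choice: the cutoff targets residual
per-frame artifacts on otherwise valid tracks.

## Distribution fitting

All candidate densities are truncated to the support `(0, v_max]` and
renormalized; speeds are nonnegative and hard-cut at `v_max = 100 µm/s` by
the filter, so untruncated likelihoods would be improper (the Cauchy, with
support ℝ, only makes sense for these data after truncation). Whether to
fit truncated or untruncated forms is this package's documented choice.

Candidates are seven single families — lognormal, Cauchy, normal, gamma,
Weibull, exponential, uniform — and six mixtures pairing each non-uniform
family with a uniform background:

    f(x) = w · f_comp(x) / Z_comp + (1 − w) · 1/(hi − lo),   w ∈ [0, 1]

with `Z_comp` the component mass on the support. The uniform component's
bounds are fixed to the support, which keeps the mixture identifiable.
The exact candidate list is configurable; the two mixtures named above are
always members of the default pool.

Estimation is direct bounded maximization of the truncated log-likelihood
(L-BFGS-B) with multi-start: a moment-based start, for mixtures the nested
single-family fit with weight ≈ 1 (which guarantees the mixture's
log-likelihood dominates its nested family's up to optimizer tolerance),
and seeded uniform draws within the parameter bounds (default 20 starts).
EM is deliberately not used: the truncated Cauchy has no closed-form EM
step, and multi-start handles the mixture likelihood's local optima. A
fitted weight within 1e-3 of 0 or 1 is flagged as a boundary solution.

Fits are ranked (default: BIC, ascending) by

    AIC = 2k − 2 logL,  BIC = k ln n − 2 logL,  HQC = 2k ln(ln n) − 2 logL

with `k` the number of free parameters — the mixture weight counts, the
fixed uniform bounds do not. Because equal-complexity models shift
equally, the (unknowable) alternative counting convention could not change
any within-pool comparison between models of equal k.

## Regime split

The slow/fast boundary is the intersection of the two populations' best-fit
densities inside a bracket (default (1, 10) µm/s, the zoomed-in low-speed
region). Crossings are located by sign changes of the density difference
on a 10,000-point grid, refined by bisection to below 1e-9 in x;
tangential contacts are ignored. Two fitted mixtures typically cross more
than once: low crossings sit inside the slow bulk where both densities are
large, while the largest crossing marks the hand-over from the slow bulk to
the fast tail. The **largest** root in the bracket is therefore selected
(all roots are logged). The threshold convention is `slow: v < t`,
`fast: v ≥ t`; ties have measure zero for continuous data, so the
convention is immaterial but fixed.

A robustness check refits each sub-range independently after splitting at
an arbitrary 60 µm/s, with each candidate's support truncated to its
sub-range (`(0, 60]` and `[60, v_max]`) so the sub-likelihoods remain
proper, and reports whether the top three fits on both sides are still
mixtures.

## Nonparametric comparisons

The two-sample Kolmogorov–Smirnov statistic is the supremum ECDF distance
over pooled sample points; its p-value uses the asymptotic Kolmogorov
distribution with effective size `n_x n_y/(n_x+n_y)`. The Kruskal–Wallis
statistic uses midranks with the standard tie correction and a chi-square
reference with g−1 degrees of freedom. At the study's scale (thousands of
measurements per strain) the asymptotics are exact for practical purposes;
exact enumeration (KS, pooled n ≤ 16) and seeded permutation (KW) modes
exist so small oracles can verify the implementations. The KS test
compares the full speed distributions; Kruskal–Wallis compares pooled
measurements per regime (the alternative — per-replicate means — is noted
but not implemented, as the pooled reading is the one consistent with
extremely small p-values at these sample sizes).

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes; its
defaults are calibration targets, not measured biological parameters (the
study publishes no generative model).

**Geometry.** A branching random tree of planar polylines grows from an
origin toward a target edge (default 8 branches, 5 µm growth steps, a
300 × 300 µm field). Agents move in 1D arc length along the route from
the origin to one leaf, with reflection at route ends — cells travel in
the liquid film hugging hyphae, so 1D-on-network is the minimal faithful
geometry.

**Behavior.** Three states with Markov switching: *microcolony* (position
held at an anchor, occasionally displaced by a ~0.05 µm rearrangement at
~1 event/s — cells pushed by neighbours, with true path length far below
the 5 µm filter), *slow* (per-step speeds from a lognormal law, a few
µm/s) and *fast* (a heavy-tailed law truncated at `v_true_max = 115 µm/s`,
the observed pre-cutoff maximum, so the 100 µm/s filter removes a small
realistic fraction). Switches occur at a configurable rate (presets:
0.05 s⁻¹) and jump to a state drawn from the configured proportions, which
makes those proportions the chain's stationary distribution; initial
states are assigned in exact proportional counts (shuffled) so the
realized composition is stable at small agent counts.

**Observation.** Positions are sampled every 0.024 s with isotropic
Gaussian localization noise (default sd 0.01 µm) and focal-plane dropout
(default 0.0015 per frame, mean off-time 0.12 s). A reappearing agent
receives a fresh track id by default, mirroring the impossibility of
re-identifying unlabeled cells; the ground-truth linkage from every track
to its generating agent is retained.

**Strain presets.** `UWC1-like` uses a Cauchy-tailed fast law,
`KT2440-like` a lognormal-tailed fast law; both are tuned so that, after
standard filtering, ≈2/3 of measurements fall below ~5 µm/s, the tail
reaches ~100 µm/s, and the best-fit mixture family recovered by the
pipeline matches the preset's character (Cauchy+uniform vs
lognormal+uniform). Calibration notes: at 41.7 fps, iid per-frame jitter
would accumulate enough *path length* for microcolony tracks to survive
the 5 µm filter, hence the sparse-rearrangement model; track fragmentation
disproportionately removes slow tracks (a 2 µm/s cell needs 2.5 s to
accumulate 5 µm), hence the low dropout rate and 4 s tracks; and the
localization-noise convolution reshapes a narrow lognormal bulk toward a
Cauchy-like peak, hence the KT2440-like preset's wide log-sd (0.95).

**What the generator does not emulate:** hydrodynamics and flagellar
physics, hyphal growth during imaging, cell division, spatially varying
film thickness, and pixelation/PSF effects beyond Gaussian localization
noise. Passing tests therefore demonstrate the *statistical machinery* —
not that real cells follow these laws.

## Problem sizes and numerical choices

Simulated study-scale runs use two populations of roughly 6,000–7,000
retained measurements (the magnitude of the study's per-strain totals),
built from ~40–50 agents observed for 4 s at 0.024 s resolution. Model
recovery checks use 3,000–5,000 direct draws per dataset and 6–10
optimizer restarts; at these sizes the moment-based and nested starting
points make further restarts redundant. Densities are evaluated in closed
form (scipy.special); truncation masses below 1e-300 mark a parameter
point as infeasible. Bisection tolerances: 1e-12 absolute in x for
density crossings; quadrature checks of PDF normalization hold to 1e-6.
Degenerate inputs are handled explicitly: empty speed sets yield empty
summaries (never exceptions), a population without enough samples to fit
is reported with a warning, and identical values across all groups give
H = 0, p = 1.

## Known limitations

- The threshold depends on the fitted families of *both* populations; with
  near-identical populations the densities may not cross in the bracket,
  in which case no split is produced (reported explicitly).
- Asymptotic p-values are approximate below a few dozen samples per group;
  use the exact/permutation modes there.
- The 2-parameter component + uniform mixture cannot represent a
  structured fast tail; if the tail is strongly peaked, model selection
  may prefer a heavy-tailed single component over the mixture.
- Speeds are planar; any z-motion biases speeds downward and is only
  mitigated, not removed, by the duration filter.
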