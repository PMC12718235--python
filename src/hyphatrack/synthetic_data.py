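"""Ground-truth-labelled synthetic trajectories on a simulated hyphal network.

The generator emulates the statistical structure of bacterial dispersal
recordings on mycelial networks so the full analysis pipeline can be
exercised offline with known ground truth:

* a branching planar network grown from an origin toward a target, along
  whose polylines agents move in 1D arc length (cells travel in the liquid
  film hugging hyphae, so 1D-on-network plus transverse jitter is the
  minimal faithful geometry);
* three behavioral states — microcolony (sub-µm positional jitter around a
  fixed anchor), slow movers (lognormal speeds, a few µm/s) and fast movers
  (a heavy-tailed law reaching ~100 µm/s, truncated at ``v_true_max``) —
  with Markovian switching whose stationary distribution equals the
  configured state proportions;
* an imaging observation model: positions sampled at the frame interval
  with isotropic Gaussian localization noise, and focal-plane dropout that
  fragments tracks (a reappearing cell cannot be re-identified, so it
  receives a fresh track id by default).

Everything is deterministic given a seed, and every observed detection maps
back to exactly one agent at one time via the returned linkage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import stats

from .trajectory_io import Detection, Trajectory, TrackSet, DEFAULT_FRAME_INTERVAL

__all__ = [
    "HyphalNetwork",
    "AgentConfig",
    "ObservationModel",
    "AgentPath",
    "generate_network",
    "simulate_agents",
    "observe",
    "paper_like_dataset",
]


# --------------------------------------------------------------------------
# network

@dataclass(frozen=True)
class HyphalNetwork:
    """A tree of planar polylines (µm) grown from an origin point.

    ``parents[i]`` is ``(parent_index, vertex_index)`` for branch i (or
    ``None`` for the trunk): branch i starts at that vertex of its parent,
    which makes the network connected by construction.
    """

    segments: tuple[np.ndarray, ...]
    parents: tuple[tuple[int, int] | None, ...]
    box: tuple[float, float]

    @property
    def n_branches(self) -> int:
        return len(self.segments)

    def leaf_tips(self) -> np.ndarray:
        return np.array([seg[-1] for seg in self.segments])

    def is_connected(self) -> bool:
        for i, parent in enumerate(self.parents):
            if parent is None:
                continue
            j, k = parent
            if not np.allclose(self.segments[i][0], self.segments[j][k]):
                return False
        return self.parents.count(None) == 1

    def route_to_leaf(self, branch: int) -> np.ndarray:
        """Polyline from the origin to the tip of ``branch`` (tree path)."""
        parts: list[np.ndarray] = []
        i: int | None = branch
        cut: int | None = None
        while i is not None:
            seg = self.segments[i] if cut is None else self.segments[i][: cut + 1]
            parts.append(seg)
            parent = self.parents[i]
            i, cut = parent if parent is not None else (None, None)
        pts = np.concatenate(parts[::-1])
        keep = np.ones(len(pts), dtype=bool)
        keep[1:] = np.any(np.diff(pts, axis=0) != 0, axis=1)
        return pts[keep]


def generate_network(
    seed: int,
    n_branches: int = 8,
    step_um: float = 5.0,
    box_um: tuple[float, float] = (300.0, 300.0),
    wiggle: float = 0.25,
) -> HyphalNetwork:
    """Grow a branching random walk from the origin toward the far edge.

    Each active tip advances ``step_um`` per growth step, heading toward the
    target with angular noise ``wiggle`` (radians; 0 gives straight lines).
    New branches bud from the current tip of a randomly chosen existing
    branch until ``n_branches`` exist, so the tree has exactly that many
    leaf tips.  Deterministic given ``seed``.
    """
    if n_branches < 1:
        raise ValueError("need at least one branch")
    w, h = box_um
    if step_um >= min(w, h):
        raise ValueError(f"step_um={step_um} too large for box {box_um}")
    rng = np.random.default_rng(seed)
    origin = np.array([0.0, h / 2.0])
    target_x = w

    segments: list[list[np.ndarray]] = [[origin]]
    parents: list[tuple[int, int] | None] = [None]
    active = [0]
    n_steps = int(math.ceil(1.6 * w / step_um))
    spawn_steps = sorted(rng.integers(1, max(2, n_steps // 2), size=n_branches - 1))

    for step in range(n_steps):
        while spawn_steps and spawn_steps[0] <= step and len(segments) < n_branches:
            spawn_steps.pop(0)
            src = int(rng.choice(active)) if active else 0
            attach_vertex = len(segments[src]) - 1
            segments.append([segments[src][attach_vertex].copy()])
            parents.append((src, attach_vertex))
            active.append(len(segments) - 1)
        still_active = []
        for i in active:
            tip = segments[i][-1]
            base_angle = math.atan2(h / 2.0 - tip[1], max(target_x - tip[0], step_um))
            angle = base_angle + (rng.normal(0.0, wiggle) if wiggle > 0 else 0.0)
            new = tip + step_um * np.array([math.cos(angle), math.sin(angle)])
            new[1] = float(np.clip(new[1], 0.0, h))
            segments[i].append(new)
            if new[0] < target_x - step_um:
                still_active.append(i)
        active = still_active
        if not active:
            break
    return HyphalNetwork(
        tuple(np.array(s) for s in segments), tuple(parents), (w, h))


# --------------------------------------------------------------------------
# agents

MICROCOLONY, SLOW, FAST = 0, 1, 2
_STATE_NAMES = ("microcolony", "slow", "fast")


@dataclass(frozen=True)
class AgentConfig:
    """Behavioral parameters of the simulated population.

    ``proportions`` is both the initial state distribution and the
    stationary distribution of the switching chain (switches jump to a
    state drawn from ``proportions`` at rate ``switch_rate``).  Speeds are
    in µm/s; the fast law is truncated to ``(0, v_true_max]`` so that the
    100 µm/s analysis cutoff removes a small realistic fraction.
    """

    n_agents: int = 100
    proportions: tuple[float, float, float] = (0.15, 0.57, 0.28)
    slow_mu: float = 0.45       # log-space mean of the slow lognormal law
    slow_sigma: float = 0.62    # log-space sd
    fast_law: Literal["cauchy", "lognormal"] = "cauchy"
    fast_params: tuple[float, float] = (20.0, 15.0)  # (x0, gamma) or (mu, sigma)
    v_true_max: float = 115.0
    switch_rate: float = 0.2    # per s
    jitter_sd: float = 0.05     # µm, size of a microcolony rearrangement
    rearrange_rate: float = 1.0  # per s, microcolony rearrangement events

    def __post_init__(self) -> None:
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError("state proportions must sum to 1")
        if min(self.v_true_max, self.jitter_sd + 1e-300) <= 0:
            raise ValueError("scales must be positive")


@dataclass
class AgentPath:
    """Ground truth for one agent: positions, state labels, drawn speeds."""

    agent_id: int
    times: np.ndarray
    xy: np.ndarray
    states: np.ndarray
    speeds: np.ndarray  # per-step drawn speed (0 in the microcolony state)


def _draw_fast_speeds(cfg: AgentConfig, size: int, rng: np.random.Generator) -> np.ndarray:
    """Inverse-CDF draws from the fast law truncated to (0, v_true_max]."""
    a, b = cfg.fast_params
    if cfg.fast_law == "cauchy":
        dist = stats.cauchy(loc=a, scale=b)
    elif cfg.fast_law == "lognormal":
        dist = stats.lognorm(s=b, scale=math.exp(a))
    else:
        raise ValueError(f"unknown fast law {cfg.fast_law!r}")
    c0, c1 = dist.cdf(0.0), dist.cdf(cfg.v_true_max)
    return np.asarray(dist.ppf(rng.uniform(c0, c1, size)), dtype=float)


def _arc_interp(points: np.ndarray):
    """Return (total length, position-at-arc-length function) for a polyline."""
    seg = np.diff(points, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = float(cum[-1])

    def at(s: float) -> np.ndarray:
        s = float(np.clip(s, 0.0, total))
        i = int(np.searchsorted(cum, s, side="right") - 1)
        i = min(i, len(seg_len) - 1)
        frac = 0.0 if seg_len[i] == 0 else (s - cum[i]) / seg_len[i]
        return points[i] + frac * seg[i]

    return total, at


def simulate_agents(
    net: HyphalNetwork,
    cfg: AgentConfig,
    duration_s: float,
    seed: int,
    dt: float = DEFAULT_FRAME_INTERVAL,
) -> list[AgentPath]:
    """Simulate agents moving along network routes for ``duration_s``.

    Each agent follows the route from the origin to one random leaf,
    starting at a random arc position, with per-step speeds drawn from its
    current state's law and reflection at route ends.  Microcolony agents
    jitter isotropically around a fixed anchor.  Deterministic given
    ``seed``.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if net.n_branches == 0:
        raise ValueError("empty network")
    rng = np.random.default_rng(seed)
    n_steps = int(round(duration_s / dt))
    times = np.arange(n_steps + 1) * dt
    p = np.asarray(cfg.proportions)

    # stratified initial states: exact proportional counts, shuffled, so the
    # realized composition matches the configured proportions at any n
    counts = np.floor(p * cfg.n_agents).astype(int)
    remainder = cfg.n_agents - counts.sum()
    for i in np.argsort(-(p * cfg.n_agents - counts))[:remainder]:
        counts[i] += 1
    initial_states = rng.permutation(np.repeat(np.arange(3), counts))

    paths: list[AgentPath] = []
    for agent in range(cfg.n_agents):
        branch = int(rng.integers(net.n_branches))
        total, at = _arc_interp(net.route_to_leaf(branch))
        s = float(rng.uniform(0.0, total))
        direction = 1.0 if rng.random() < 0.5 else -1.0
        state = int(initial_states[agent])
        anchor = at(s)

        xy = np.empty((n_steps + 1, 2))
        states = np.empty(n_steps + 1, dtype=np.int8)
        speeds = np.zeros(n_steps + 1)
        xy[0] = anchor if state == MICROCOLONY else at(s)
        states[0] = state
        p_switch = 1.0 - math.exp(-cfg.switch_rate * dt)

        slow_draws = np.exp(rng.normal(cfg.slow_mu, cfg.slow_sigma, n_steps))
        fast_draws = _draw_fast_speeds(cfg, n_steps, rng)
        switch_u = rng.random(n_steps)
        jitter = rng.normal(0.0, cfg.jitter_sd, (n_steps, 2))
        rearrange_u = rng.random(n_steps)
        p_rearrange = 1.0 - math.exp(-cfg.rearrange_rate * dt)

        for k in range(n_steps):
            if switch_u[k] < p_switch:
                new_state = int(rng.choice(3, p=p))
                if new_state == MICROCOLONY and state != MICROCOLONY:
                    anchor = at(s)
                state = new_state
            if state == MICROCOLONY:
                # cells in microcolonies hold position and only occasionally
                # get pushed into a new spot by neighbours, so the true path
                # length stays far below the 5 µm inclusion threshold
                if rearrange_u[k] < p_rearrange:
                    xy[k + 1] = anchor + jitter[k]
                else:
                    xy[k + 1] = xy[k]
                speeds[k + 1] = 0.0
            else:
                v = slow_draws[k] if state == SLOW else fast_draws[k]
                s += direction * v * dt
                if s < 0.0:
                    s, direction = -s, 1.0
                elif s > total:
                    s, direction = 2.0 * total - s, -1.0
                xy[k + 1] = at(s)
                speeds[k + 1] = v
            states[k + 1] = state
        paths.append(AgentPath(agent, times.copy(), xy, states, speeds))
    return paths


# --------------------------------------------------------------------------
# observation

@dataclass(frozen=True)
class ObservationModel:
    """Imaging model: sampling interval, localization noise, focal dropout.

    ``p_dropout`` is the per-frame probability that a visible agent leaves
    the focal plane; off-times are geometric with mean ``mean_off_time``
    seconds.  With ``relabel`` on (the default) a reappearing agent starts
    a new track, mirroring the impossibility of re-identifying unlabeled
    cells.
    """

    frame_interval: float = DEFAULT_FRAME_INTERVAL
    noise_sd: float = 0.01        # µm
    p_dropout: float = 0.0015     # per frame
    mean_off_time: float = 0.12   # s
    relabel: bool = True

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if not 0.0 <= self.p_dropout <= 1.0:
            raise ValueError("p_dropout must be a probability")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be nonnegative")


def observe(
    paths: list[AgentPath],
    om: ObservationModel,
    seed: int,
) -> tuple[TrackSet, dict[str, int]]:
    """Sample agent paths through the imaging model into a TrackSet.

    Returns the TrackSet plus a linkage table mapping every observed track
    id to the generating agent id (ground-truth conservation: each
    detection belongs to exactly one agent at one time).
    """
    rng = np.random.default_rng(seed)
    p_return = 1.0 - math.exp(-om.frame_interval / max(om.mean_off_time, 1e-12))
    trajectories: list[Trajectory] = []
    linkage: dict[str, int] = {}

    for path in paths:
        n_frames = len(path.times)
        noise = rng.normal(0.0, om.noise_sd, (n_frames, 2)) if om.noise_sd > 0 else 0.0
        observed = path.xy + noise
        visible = True
        segment = 0
        detections: list[Detection] = []

        def flush() -> None:
            nonlocal detections
            if detections:
                tid = f"a{path.agent_id}_s{segment}" if om.relabel else f"a{path.agent_id}"
                if om.relabel or not any(t.track_id == tid for t in trajectories):
                    trajectories.append(Trajectory(tid, detections))
                    linkage[tid] = path.agent_id
                else:  # same id continues after a gap
                    next(t for t in trajectories if t.track_id == tid).detections.extend(detections)
            detections = []

        for k in range(n_frames):
            if visible:
                if rng.random() < om.p_dropout:
                    visible = False
                    flush()
                    segment += 1
            else:
                if rng.random() < p_return:
                    visible = True
            if visible:
                detections.append(Detection(
                    k, float(observed[k, 0]), float(observed[k, 1]),
                    float(k * om.frame_interval)))
        flush()
    return (TrackSet(trajectories, frame_interval=om.frame_interval, source="synthetic"),
            linkage)


# --------------------------------------------------------------------------
# study-like presets

#: Per-strain presets.  The values are calibration targets of the generator
#: (≈2/3 of filtered measurements below ~5 µm/s, a heavy tail reaching
#: ~100 µm/s, slow-regime means near 2 µm/s), not measured biological
#: parameters: the study publishes no generative model.
_STRAIN_PRESETS: dict[str, dict] = {
    "uwc1": dict(
        proportions=(0.14, 0.60, 0.26),
        slow_mu=0.50, slow_sigma=0.60,
        fast_law="cauchy", fast_params=(18.0, 14.0),
        switch_rate=0.05,
    ),
    "kt2440": dict(
        proportions=(0.11, 0.62, 0.27),
        slow_mu=0.19, slow_sigma=0.95,
        fast_law="lognormal", fast_params=(3.15, 0.95),
        switch_rate=0.05,
    ),
}

_AGENT_DURATION_S = 4.0
_SAMPLES_PER_MOVER = 0.97 * (_AGENT_DURATION_S / DEFAULT_FRAME_INTERVAL)


def paper_like_dataset(
    strain_profile: str,
    n_target_samples: int,
    seed: int,
) -> tuple[TrackSet, dict]:
    """Generate a study-like population of tracks with ground truth.

    ``strain_profile`` selects the preset: ``"UWC1-like"`` (Cauchy-tailed
    fast law) or ``"KT2440-like"`` (lognormal-tailed fast law).
    ``n_target_samples`` sets the approximate number of speed measurements
    that survive the standard filters.  Returns the TrackSet and a ground
    truth dict (config, agent paths, track-to-agent linkage).
    """
    if n_target_samples < 1000:
        raise ValueError("n_target_samples must be at least 1000")
    key = strain_profile.lower().replace("-like", "")
    if key not in _STRAIN_PRESETS:
        raise ValueError(f"unknown strain profile {strain_profile!r}; "
                         f"expected one of {sorted(_STRAIN_PRESETS)}")
    preset = _STRAIN_PRESETS[key]
    moving_fraction = 1.0 - preset["proportions"][MICROCOLONY]
    n_agents = max(2, round(n_target_samples / (moving_fraction * _SAMPLES_PER_MOVER)))
    cfg = AgentConfig(n_agents=n_agents, **preset)

    net = generate_network(seed=seed, n_branches=8, step_um=5.0, box_um=(300.0, 300.0))
    paths = simulate_agents(net, cfg, duration_s=_AGENT_DURATION_S, seed=seed + 1)
    om = ObservationModel()
    tracks, linkage = observe(paths, om, seed=seed + 2)
    ground_truth = {
        "strain_profile": strain_profile,
        "config": cfg,
        "observation": om,
        "paths": paths,
        "linkage": linkage,
    }
    return tracks, ground_truth
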