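import math

import numpy as np
import pytest

from hyphatrack.dist_fitting import rank_models
from hyphatrack.speed_metrics import apply_filters, speeds_array
from hyphatrack.synthetic_data import (
    MICROCOLONY,
    AgentConfig,
    ObservationModel,
    generate_network,
    observe,
    paper_like_dataset,
    simulate_agents,
)


class TestNetwork:
    def test_deterministic_given_seed(self):
        a = generate_network(seed=1, n_branches=1)
        b = generate_network(seed=1, n_branches=1)
        assert len(a.segments) == 1
        np.testing.assert_array_equal(a.segments[0], b.segments[0])

    def test_different_seeds_differ(self):
        a = generate_network(seed=1, n_branches=3)
        b = generate_network(seed=2, n_branches=3)
        assert not np.array_equal(a.segments[0], b.segments[0])

    def test_branch_count_and_connectivity(self):
        net = generate_network(seed=5, n_branches=8)
        assert net.n_branches == 8
        assert net.leaf_tips().shape == (8, 2)
        assert net.is_connected()
        # every leaf is reachable from the origin along a finite route
        origin = net.segments[0][0]
        for b in range(net.n_branches):
            route = net.route_to_leaf(b)
            np.testing.assert_allclose(route[0], origin)
            np.testing.assert_allclose(route[-1], net.segments[b][-1])

    def test_oversized_step_rejected(self):
        with pytest.raises(ValueError, match="too large"):
            generate_network(seed=1, step_um=500.0, box_um=(300.0, 300.0))


class TestAgents:
    def test_pure_microcolony_population_is_filtered_out(self):
        net = generate_network(seed=2, n_branches=4)
        cfg = AgentConfig(n_agents=30, proportions=(1.0, 0.0, 0.0), jitter_sd=0.05)
        paths = simulate_agents(net, cfg, duration_s=10.0, seed=3)
        # true path lengths stay far below the 5 µm inclusion threshold
        for p in paths:
            steps = np.diff(p.xy, axis=0)
            assert np.hypot(steps[:, 0], steps[:, 1]).sum() < 5.0
        tracks, _ = observe(paths, ObservationModel(noise_sd=0.0, p_dropout=0.0), seed=4)
        retained, report = apply_filters(tracks)
        assert retained == []
        assert report.n_tracks_removed_length == 30

    def test_constant_fast_runner_speed_recovered_exactly(self):
        # straight network, sigma -> 0 limit via a degenerate Cauchy scale
        net = generate_network(seed=1, n_branches=1, wiggle=0.0)
        cfg = AgentConfig(n_agents=5, proportions=(0.0, 0.0, 1.0),
                          fast_law="cauchy", fast_params=(50.0, 1e-12),
                          switch_rate=0.0)
        paths = simulate_agents(net, cfg, duration_s=1.0, seed=7)
        tracks, _ = observe(paths, ObservationModel(noise_sd=0.0, p_dropout=0.0), seed=8)
        speeds = speeds_array(apply_filters(tracks)[0])
        assert speeds.size > 0
        # exact on straight stretches; the rare frame containing a reflection
        # at a route end folds the displacement and can only shorten it
        exact = np.isclose(speeds, 50.0, atol=1e-6)
        assert exact.mean() > 0.95
        assert (speeds <= 50.0 + 1e-6).all()

    def test_state_occupancy_matches_configured_proportions(self):
        net = generate_network(seed=4, n_branches=4)
        cfg = AgentConfig(n_agents=1000, proportions=(0.3, 0.4, 0.3), switch_rate=0.2)
        paths = simulate_agents(net, cfg, duration_s=2.0, seed=5)
        states = np.concatenate([p.states for p in paths])
        occupancy = [np.mean(states == k) for k in range(3)]
        np.testing.assert_allclose(occupancy, (0.3, 0.4, 0.3), atol=0.03)

    def test_empty_network_rejected(self):
        net = generate_network(seed=1, n_branches=1)
        with pytest.raises(ValueError, match="duration"):
            simulate_agents(net, AgentConfig(n_agents=1), duration_s=0.0, seed=1)


class TestObserve:
    def test_zero_noise_zero_dropout_reproduces_path_speeds(self):
        net = generate_network(seed=1, n_branches=1, wiggle=0.0)
        cfg = AgentConfig(n_agents=3, proportions=(0.0, 1.0, 0.0),
                          slow_mu=1.0, slow_sigma=0.3, switch_rate=0.0)
        paths = simulate_agents(net, cfg, duration_s=1.0, seed=2)
        tracks, linkage = observe(paths, ObservationModel(noise_sd=0.0, p_dropout=0.0),
                                  seed=3)
        assert len(tracks) == 3
        by_agent = {p.agent_id: p for p in paths}
        for tr in tracks.trajectories:
            truth = by_agent[linkage[tr.track_id]]
            # straight segments: observed per-frame speed equals the drawn speed
            for a, b in zip(tr.detections, tr.detections[1:]):
                observed = math.hypot(b.x - a.x, b.y - a.y) / (b.t - a.t)
                assert observed == pytest.approx(truth.speeds[b.frame], abs=1e-9)

    def test_dropout_fragments_tracks(self):
        net = generate_network(seed=1, n_branches=2)
        cfg = AgentConfig(n_agents=40, proportions=(0.0, 1.0, 0.0))
        paths = simulate_agents(net, cfg, duration_s=2.0, seed=2)
        om = ObservationModel(p_dropout=0.1, mean_off_time=0.5)
        tracks, linkage = observe(paths, om, seed=3)
        assert len(tracks) > 40
        # ground-truth conservation: every track maps to exactly one agent
        assert set(linkage) == {t.track_id for t in tracks.trajectories}
        n_det = sum(len(t) for t in tracks.trajectories)
        assert n_det <= sum(len(p.times) for p in paths)

    def test_static_agent_apparent_speed_matches_rayleigh_monte_carlo(self):
        # a perfectly still agent observed with localization noise sigma:
        # consecutive-frame displacement is Rayleigh(sigma*sqrt(2))
        sigma, dt = 0.1, 0.024
        net = generate_network(seed=1, n_branches=1)
        cfg = AgentConfig(n_agents=60, proportions=(1.0, 0.0, 0.0),
                          jitter_sd=1e-12, rearrange_rate=0.0)
        paths = simulate_agents(net, cfg, duration_s=4.0, seed=4)
        om = ObservationModel(noise_sd=sigma, p_dropout=0.0)
        tracks, _ = observe(paths, om, seed=5)
        speeds = np.concatenate([
            [math.hypot(b.x - a.x, b.y - a.y) / dt
             for a, b in zip(t.detections, t.detections[1:])]
            for t in tracks.trajectories])
        rng = np.random.default_rng(6)
        mc = np.linalg.norm(rng.normal(0, sigma, (100_000, 2))
                            - rng.normal(0, sigma, (100_000, 2)), axis=1) / dt
        closed_form = sigma * math.sqrt(2) * math.sqrt(math.pi / 2) / dt
        assert np.mean(mc) == pytest.approx(closed_form, rel=0.01)
        assert np.mean(speeds) == pytest.approx(np.mean(mc), rel=0.02)


class TestPaperLikeDataset:
    def test_bit_identical_given_seed(self):
        a, _ = paper_like_dataset("UWC1-like", 1500, seed=11)
        b, _ = paper_like_dataset("UWC1-like", 1500, seed=11)
        assert len(a) == len(b)
        for ta, tb in zip(a.trajectories, b.trajectories):
            assert ta.track_id == tb.track_id
            assert ta.detections == tb.detections

    def test_small_target_yield_is_close(self):
        tracks, _ = paper_like_dataset("UWC1-like", 1000, seed=3)
        retained, _ = apply_filters(tracks)
        assert len(retained) < 1100

    def test_unknown_profile_rejected(self):
        with pytest.raises(ValueError, match="strain profile"):
            paper_like_dataset("coli-like", 2000, seed=1)
        with pytest.raises(ValueError, match="at least 1000"):
            paper_like_dataset("UWC1-like", 10, seed=1)

    def test_slow_fraction_near_two_thirds(self):
        tracks, _ = paper_like_dataset("UWC1-like", 7000, seed=9)
        v = speeds_array(apply_filters(tracks)[0])
        slow_fraction = 100 * np.mean(v < 5.44)
        assert 60 <= slow_fraction <= 72
        assert v.max() > 60  # heavy tail reaches high speeds
        assert v.max() <= 100

    def test_generating_family_recovered_across_seeds(self):
        """Top-1 by BIC matches the generating mixture in most seeds."""
        hits = {"UWC1-like": 0, "KT2440-like": 0}
        want = {"UWC1-like": "cauchy+uniform", "KT2440-like": "lognormal+uniform"}
        seeds = range(5)
        for key in hits:
            for seed in seeds:
                tracks, _ = paper_like_dataset(key, 6000, seed=seed)
                v = speeds_array(apply_filters(tracks)[0])
                best = rank_models(v, seed=1, n_restarts=6).best.spec.name
                hits[key] += best == want[key]
        assert hits["UWC1-like"] >= 4
        assert hits["KT2440-like"] >= 3
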