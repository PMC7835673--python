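"""Unit tests for the run-and-tumble colony simulator."""

import math

import numpy as np
import pytest

from biofilm_adapt.active_sim import (
    ActiveSimConfig,
    Colony,
    InsufficientSamplingError,
    TimestepTooLargeError,
    estimate_diffusion,
    fit_doubling_time,
    grow_and_divide,
    minimum_separation,
    new_colony,
    pair_force,
    run_colony,
    run_single,
    step,
)


@pytest.fixture
def config():
    return ActiveSimConfig()


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError, match="dt"):
            ActiveSimConfig(dt=100.0, tau_run=35.0)
        with pytest.raises(ValueError, match="length"):
            ActiveSimConfig(l0=0.5, w=0.8)
        with pytest.raises(ValueError, match="non-negative"):
            ActiveSimConfig(attraction_strength=-0.1)

    def test_elongation_doubles_length_over_t_dup(self, config):
        assert config.elongation_rate * config.t_dup * 3600.0 == pytest.approx(
            config.l0
        )


class TestPairForce:
    def test_zero_at_minimum_separation(self, config):
        d = minimum_separation(config)
        assert d == pytest.approx(2.0 ** (1.0 / 6.0) * config.w)
        assert pair_force(d, config) == pytest.approx(0.0, abs=1e-9)

    def test_repulsive_below_attractive_above(self, config):
        d = minimum_separation(config)
        assert pair_force(0.9 * d, config) > 0.0
        assert pair_force(1.2 * d, config) < 0.0

    def test_attraction_scales_with_strength(self, config):
        from dataclasses import replace

        d = 1.2 * minimum_separation(config)
        weak = replace(config, attraction_strength=0.0)
        half = replace(config, attraction_strength=0.1)
        assert pair_force(d, weak) == pytest.approx(0.0, abs=1e-12)
        assert pair_force(d, half) == pytest.approx(0.5 * pair_force(d, config))


class TestMotion:
    def test_ballistic_run_between_tumbles(self):
        """An isolated cell advances v*dt per step along its heading."""
        cfg = ActiveSimConfig(tau_run=1e9, dt=0.1)  # tumbles never fire
        colony = new_colony(cfg, n=1)
        x0, y0, th = colony.x[0], colony.y[0], colony.theta[0]
        step(colony, cfg, n_steps=100, seed=1, grow=False)
        dist = math.hypot(colony.x[0] - x0, colony.y[0] - y0)
        assert dist == pytest.approx(cfg.v * 0.1 * 100, rel=1e-9)
        assert colony.theta[0] == pytest.approx(th)

    def test_periodic_wrapping(self):
        cfg = ActiveSimConfig(tau_run=1e9, dt=0.1, box=10.0)
        colony = new_colony(cfg, n=1)
        colony.x[0], colony.y[0] = 9.99, 5.0
        colony.theta[0] = 0.0
        colony.target[0] = 0.0
        step(colony, cfg, n_steps=10, seed=1, grow=False)
        assert 0.0 <= colony.x[0] < 10.0

    def test_overlap_raises_timestep_error(self):
        cfg = ActiveSimConfig()
        colony = new_colony(cfg, n=2)
        # two parallel rods overlapping far deeper than half a width
        colony.x[:] = (100.0, 100.0)
        colony.y[:] = (100.0, 100.2)
        colony.theta[:] = 0.0
        colony.target[:] = 0.0
        with pytest.raises(TimestepTooLargeError, match="reduce dt"):
            step(colony, cfg, n_steps=1, seed=1, grow=False)

    def test_deterministic_given_seed(self):
        cfg = ActiveSimConfig()
        a = new_colony(cfg, n=5, rng=np.random.default_rng(3))
        b = new_colony(cfg, n=5, rng=np.random.default_rng(3))
        step(a, cfg, n_steps=200, seed=7, grow=True)
        step(b, cfg, n_steps=200, seed=7, grow=True)
        assert np.array_equal(a.x, b.x) and np.array_equal(a.theta, b.theta)


class TestDivision:
    def test_division_preserves_total_length_and_axis(self):
        cfg = ActiveSimConfig(division_noise=0.0)
        colony = new_colony(cfg, n=1)
        colony.length[0] = 2.0 * cfg.l0
        colony.theta[0] = 0.3
        total_before = colony.length.sum()
        grow_and_divide(colony, cfg, np.random.default_rng(0))
        assert colony.n == 2
        assert colony.length.sum() == pytest.approx(total_before)
        assert np.allclose(colony.theta, 0.3)
        # daughters sit end-to-end along the mother's axis
        dx = colony.x[1] - colony.x[0]
        dy = colony.y[1] - colony.y[0]
        assert math.hypot(dx, dy) == pytest.approx(cfg.l0)
        # collinear with the mother's axis (direction defined modulo pi)
        off_axis = abs(math.atan2(dy, dx) - 0.3) % math.pi
        assert min(off_axis, math.pi - off_axis) == pytest.approx(0.0, abs=1e-9)

    def test_daughters_get_fresh_ids_and_parent(self):
        cfg = ActiveSimConfig()
        colony = new_colony(cfg, n=1)
        colony.length[0] = 2.0 * cfg.l0
        mother = int(colony.ids[0])
        grow_and_divide(colony, cfg, np.random.default_rng(0))
        assert set(colony.parents) == {mother}
        assert len(set(colony.ids)) == 2
        assert mother not in set(colony.ids)

    def test_short_cells_do_not_divide(self):
        cfg = ActiveSimConfig()
        colony = new_colony(cfg, n=3)
        grow_and_divide(colony, cfg, np.random.default_rng(0))
        assert colony.n == 3

    def test_orientation_noise_applied(self):
        cfg = ActiveSimConfig(division_noise=0.5)
        colony = new_colony(cfg, n=1)
        colony.length[0] = 2.0 * cfg.l0
        colony.theta[0] = 0.0
        grow_and_divide(colony, cfg, np.random.default_rng(12))
        assert not np.allclose(colony.theta, 0.0)


class TestGrowthCurve:
    def test_counts_double_each_hour(self):
        cfg = ActiveSimConfig()
        traj = run_colony(cfg, hours=3.0, seed=5)
        assert traj.counts[0] == 1
        assert traj.counts[-1] == 8

    def test_fit_doubling_time_exact_exponential(self):
        t = np.linspace(0.0, 6.0, 61)
        n = 2.0 ** (t / 1.25)
        assert fit_doubling_time(t, n) == pytest.approx(1.25, rel=1e-9)

    def test_fit_rejects_nonpositive_counts(self):
        with pytest.raises(ValueError, match="positive"):
            fit_doubling_time(np.array([0.0, 1.0]), np.array([1.0, 0.0]))

    def test_fit_rejects_non_growing(self):
        with pytest.raises(ValueError, match="non-growing"):
            fit_doubling_time(np.array([0.0, 1.0, 2.0]), np.array([4.0, 2.0, 1.0]))


class TestDiffusion:
    def test_single_walker_ballistic_limit(self):
        cfg = ActiveSimConfig(tau_run=1e12)
        times, pos = run_single(cfg, total_time_s=100.0, n_walkers=1, seed=2)
        disp = np.hypot(pos[-1, 0, 0], pos[-1, 0, 1])
        assert disp == pytest.approx(cfg.v * 100.0, rel=1e-9)

    def test_insufficient_sampling_raises(self):
        cfg = ActiveSimConfig()
        times, pos = run_single(cfg, total_time_s=100.0, n_walkers=4, seed=2)
        with pytest.raises(InsufficientSamplingError, match="tau_run"):
            estimate_diffusion(times, pos, cfg.tau_run)

    def test_run_single_deterministic(self):
        cfg = ActiveSimConfig()
        _, a = run_single(cfg, total_time_s=500.0, n_walkers=3, seed=8)
        _, b = run_single(cfg, total_time_s=500.0, n_walkers=3, seed=8)
        assert np.array_equal(a, b)
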