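"""Unit tests for the two-compartment population model."""

import math

import numpy as np
import pytest

from biofilm_adapt.ode_model import (
    DEFAULT_INITIAL,
    PRESET_NAMES,
    PopulationParams,
    SystemState,
    Trajectory,
    carrying_capacity,
    growth_rate,
    preset,
    rhs,
    rk4_step,
    simulate,
)


@pytest.fixture
def params():
    return preset("shaking")


class TestMonodProportionality:
    def test_growth_rate_zero_without_nutrient(self, params):
        assert growth_rate(0.0, params) == 0.0

    def test_growth_rate_is_mu_max_at_reference(self, params):
        assert growth_rate(params.c_ref, params) == pytest.approx(params.mu_max)

    def test_growth_rate_linear_in_nutrient(self, params):
        assert growth_rate(0.5, params) == pytest.approx(0.5 * params.mu_max)

    def test_negative_concentration_rejected(self, params):
        with pytest.raises(ValueError, match="non-negative"):
            growth_rate(-0.1, params)
        with pytest.raises(ValueError, match="non-negative"):
            carrying_capacity(-0.1, params)

    def test_capacity_proportional(self, params):
        assert carrying_capacity(0.25, params) == pytest.approx(0.25 * params.K_max)


class TestRhs:
    def test_death_phase_survives_nutrient_exhaustion(self, params):
        """At c = 0 the quadratic death term persists: drho/dt < 0."""
        state = SystemState(rho_b=1.0, rho_p=0.0, c_b=0.0, c_p=0.0)
        d = rhs(state, preset("shaking"))
        assert d.rho_b < 0.0

    def test_exchange_antisymmetric(self, params):
        """Pure exchange (no growth) conserves total cells instant by instant."""
        p = PopulationParams(
            mu_max=0.0, K_max=1.0, k_plus=0.7, k_minus=0.3, D_n=0.0,
            delta=0.0, beta=0.0,
        )
        state = SystemState(rho_b=0.4, rho_p=0.6, c_b=1.0, c_p=0.2)
        d = rhs(state, p)
        assert d.rho_b + d.rho_p == pytest.approx(0.0, abs=1e-15)

    def test_diffusion_antisymmetric(self):
        p = PopulationParams(
            mu_max=0.0, K_max=1.0, k_plus=0.0, k_minus=0.0, D_n=2.0,
            delta=0.0, beta=0.0,
        )
        state = SystemState(rho_b=0.0, rho_p=0.0, c_b=0.8, c_p=0.1)
        d = rhs(state, p)
        assert d.c_b + d.c_p == pytest.approx(0.0, abs=1e-15)

    def test_nonfinite_state_rejected(self, params):
        with pytest.raises(ValueError, match="non-finite"):
            rhs(SystemState(math.nan, 0.0, 1.0, 1.0), params)


class TestRk4Step:
    def test_exponential_one_step_accuracy(self):
        """Against exp growth of a dilute culture: 4th-order local error."""
        p = PopulationParams(
            mu_max=1.0, K_max=1e12, k_plus=0.0, k_minus=0.0, D_n=0.0,
            delta=0.0, beta=0.0,
        )
        s0 = SystemState(rho_b=1e-6, rho_p=0.0, c_b=1.0, c_p=1.0)
        out = rk4_step(s0, p, 0.1)
        assert out.rho_b == pytest.approx(1e-6 * math.exp(0.1), rel=1e-8)
        assert out.t == pytest.approx(0.1)

    def test_nonpositive_dt_rejected(self, params):
        with pytest.raises(ValueError, match="dt"):
            rk4_step(DEFAULT_INITIAL, params, 0.0)


class TestSimulate:
    def test_grid_and_lengths(self, params):
        traj = simulate(params, DEFAULT_INITIAL, 10.0, dt=0.01, record_every=10)
        assert len(traj) == 101
        assert traj.t[0] == 0.0
        assert traj.t[-1] == pytest.approx(10.0)
        assert np.allclose(np.diff(traj.t), 0.1)

    def test_negative_initial_rejected(self, params):
        with pytest.raises(ValueError, match="negative"):
            simulate(params, SystemState(-1.0, 0.0, 1.0, 1.0), 1.0)

    def test_record_every_must_divide(self, params):
        with pytest.raises(ValueError, match="record_every"):
            simulate(params, DEFAULT_INITIAL, 1.0, dt=0.01, record_every=7)

    def test_blowup_raises_floating_point_error_naming_time(self):
        # unchecked exponential growth (no nutrient drain, huge capacity)
        # overflows within the run at this step size
        runaway = PopulationParams(
            mu_max=1e3, K_max=1e300, k_plus=0.0, k_minus=0.0, D_n=0.0,
            delta=0.0, beta=0.0,
        )
        with pytest.raises(FloatingPointError, match="t="):
            simulate(runaway, SystemState(1.0, 1.0, 1.0, 1.0), 50.0, dt=1.0)

    def test_total_nutrient_non_increasing(self):
        for name in PRESET_NAMES:
            traj = simulate(preset(name), DEFAULT_INITIAL, 72.0, dt=0.01, record_every=100)
            total = traj.c_b + traj.c_p
            assert np.all(np.diff(total) <= 1e-12)

    def test_interp_matches_grid(self, params):
        traj = simulate(params, DEFAULT_INITIAL, 10.0, dt=0.01, record_every=10)
        assert traj.interp(np.array([traj.t[5]]), "rho_b")[0] == pytest.approx(
            traj.rho_b[5]
        )


class TestTrajectoryValidation:
    def test_nonuniform_grid_rejected(self, params):
        with pytest.raises(ValueError, match="uniform"):
            Trajectory(
                t=np.array([0.0, 1.0, 3.0]),
                rho_b=np.zeros(3),
                rho_p=np.zeros(3),
                c_b=np.ones(3),
                c_p=np.ones(3),
                params=params,
                dt=1.0,
            )


class TestPresets:
    def test_unknown_condition_lists_valid_names(self):
        with pytest.raises(ValueError, match="shaking"):
            preset("vigorous")

    def test_presets_differ_only_in_exchange(self):
        a, b = preset("shaking"), preset("static")
        assert a.k_plus > a.k_minus  # attachment-dominated
        assert b.k_minus > b.k_plus  # detachment-dominated
        assert a.D_n > b.D_n
        for shared in ("mu_max", "K_max", "delta", "beta", "c_ref"):
            assert getattr(a, shared) == getattr(b, shared)

    def test_dilute_doubling_time_is_one_hour(self):
        """mu_max = ln 2 per hour by calibration."""
        assert preset("shaking").mu_max == pytest.approx(math.log(2.0))

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="k_plus"):
            PopulationParams(
                mu_max=1.0, K_max=1.0, k_plus=-1.0, k_minus=0.0, D_n=0.0,
                delta=0.0, beta=0.0,
            )

    def test_params_dict_round_trip(self, params):
        assert PopulationParams.from_dict(params.to_dict()) == params
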