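"""Unit tests for the coarse-grained oscillatory-shear model."""

import numpy as np
import pytest

from biofilm_adapt.shear_sim import (
    COMPOSITIONS,
    DPDParams,
    ShearProtocol,
    add_crosslinks,
    build_system,
    equilibrate,
    evaluate_master_curve,
    oscillate,
    stress_ratio_curve,
    stress_response,
)


@pytest.fixture(scope="module")
def small_system():
    """One small equilibrated static-condition system shared by the module."""
    return build_system("static", n_beads=300, seed=17, equil_steps=800)


class TestBuild:
    def test_compositions_match_condition(self):
        for condition, frac in COMPOSITIONS.items():
            system = build_system(condition, n_beads=600, seed=1, equil_steps=0)
            assert system.bacteria_fraction() == pytest.approx(frac, abs=0.03)
            assert system.composition["solvent"] == pytest.approx(0.6, abs=0.02)

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError, match="static"):
            build_system("turbulent", n_beads=300)

    def test_box_matches_density(self, small_system):
        assert small_system.n / small_system.box**3 == pytest.approx(
            small_system.params.density
        )

    def test_zero_total_momentum_at_build(self):
        system = build_system("shaking", n_beads=300, seed=2, equil_steps=0)
        assert np.abs(system.vel.sum(axis=0)).max() < 1e-12

    def test_fd_sigma_default(self):
        p = DPDParams()
        assert p.resolved_sigma_r() == pytest.approx(
            np.sqrt(2.0 * p.gamma_d * p.temperature)
        )


class TestDynamics:
    def test_momentum_conserved(self, small_system):
        system = small_system.copy()
        p0 = system.vel.sum(axis=0)
        equilibrate(system, 200, seed=3)
        p1 = system.vel.sum(axis=0)
        assert np.abs(p1 - p0).max() < 1e-10

    def test_fluctuation_dissipation_violation_overheats(self):
        """Random kicks above the FD value must drive T off target."""
        params = DPDParams(sigma_r=2.0 * np.sqrt(2.0 * 4.5))  # 2x FD value
        system = build_system("static", n_beads=300, seed=5, params=params,
                              equil_steps=0)
        temp = equilibrate(system, 1200, seed=6)
        assert temp[600:].mean() > 1.5  # way beyond the 5% band


class TestCrosslinks:
    def test_registry_grows_by_exact_count(self, small_system):
        system = small_system.copy()
        add_crosslinks(system, 40, seed=7, relax_steps=20)
        assert system.xlinks.shape == (40, 2)

    def test_links_join_distinct_non_solvent_molecules(self, small_system):
        system = small_system.copy()
        add_crosslinks(system, 40, seed=7, relax_steps=20)
        for i, j in system.xlinks:
            assert system.types[i] != 0 and system.types[j] != 0
            assert system.mol_id[i] != system.mol_id[j]

    def test_no_duplicate_links(self, small_system):
        system = small_system.copy()
        add_crosslinks(system, 60, seed=8, relax_steps=20)
        pairs = {tuple(p) for p in system.xlinks}
        assert len(pairs) == 60

    def test_infeasible_request_reports_placed_count(self, small_system):
        system = small_system.copy()
        with pytest.raises(ValueError, match="placed"):
            add_crosslinks(system, 10**6, seed=9, relax_steps=0)

    def test_deterministic_given_seed(self, small_system):
        a = small_system.copy()
        b = small_system.copy()
        add_crosslinks(a, 30, seed=11, relax_steps=0)
        add_crosslinks(b, 30, seed=11, relax_steps=0)
        assert np.array_equal(a.xlinks, b.xlinks)


class TestProtocol:
    def test_validation(self):
        with pytest.raises(ValueError, match="cycles"):
            ShearProtocol(gamma_0=0.1, n_cycles=1)
        with pytest.raises(ValueError, match="gamma_0"):
            ShearProtocol(gamma_0=-0.1)
        with pytest.raises(ValueError, match="omega"):
            ShearProtocol(gamma_0=0.1, omega=0.0)

    def test_oscillate_returns_strain_trace(self, small_system):
        system = small_system.copy()
        proto = ShearProtocol(gamma_0=0.3, n_cycles=2)
        t, gamma, sigma = oscillate(system, proto, seed=13)
        assert len(t) == len(gamma) == len(sigma)
        assert np.max(np.abs(gamma)) == pytest.approx(0.3, rel=1e-3)


class TestStressRatioCurve:
    def test_identical_system_and_seed_gives_ratio_one(self, small_system):
        """Self-comparison with shared seeds is exactly 1 (determinism)."""
        linked = add_crosslinks(small_system.copy(), 10, seed=3)
        proto = ShearProtocol(gamma_0=0.3, n_cycles=4)
        a = stress_response(linked.copy(), proto, seed=9)
        b = stress_response(linked.copy(), proto, seed=9)
        assert a > 0.0
        assert b / a == 1.0

    def test_table_structure(self, small_system):
        static_sys = small_system.copy()
        shaking_sys = small_system.copy()
        out = stress_ratio_curve(
            static_sys,
            shaking_sys,
            crosslink_ratios=np.array([1.0, 2.0]),
            n_xlink_static=10,
            amplitudes=np.array([0.3]),
            n_cycles=4,
            seed=5,
        )
        np.testing.assert_allclose(out["x"], [1.0, 2.0])
        assert out["ratio"].shape == out["spread"].shape == (2,)
        assert np.all(np.isfinite(out["ratio"])) and np.all(out["ratio"] > 0.0)
        assert out["failures"] == []
        assert out["n_xlink_static"] == 10

    def test_sub_one_ratio_rejected(self, small_system):
        with pytest.raises(ValueError, match=">= 1"):
            stress_ratio_curve(
                small_system.copy(),
                small_system.copy(),
                crosslink_ratios=np.array([0.5]),
                n_xlink_static=5,
                amplitudes=np.array([0.3]),
            )


class TestMasterCurve:
    def test_quadratic_coefficients(self):
        x = np.array([0.0, 1.0, 2.0])
        np.testing.assert_allclose(
            evaluate_master_curve(x), 0.75 * x**2 + 4.4 * x - 1.14
        )

    def test_scalar_input_returns_float(self):
        assert isinstance(evaluate_master_curve(3.0), float)

    def test_negative_ratio_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            evaluate_master_curve(-1.0)
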