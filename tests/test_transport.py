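import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitoradial import (
    SimParams,
    SimState,
    advance_state,
    drift_velocity,
    mean_position_sweep,
    run_simulation,
)

from conftest import ks_distance_to_r_squared


class TestDriftVelocity:
    def test_zero_signal_is_pure_retrograde(self):
        assert drift_velocity(0.0, 0.4, 0.25) == pytest.approx(-0.25)

    def test_balanced_at_unit_signal(self):
        assert drift_velocity(1.0, 0.4, 0.4) == pytest.approx(0.0)

    def test_reference_parameter_set(self):
        # (pka, v+, v-) = (0.7, 0.4, 0.4) -> -0.12/1.7
        assert drift_velocity(0.7, 0.4, 0.4) == pytest.approx(-0.0706, abs=1e-4)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            drift_velocity(-0.1, 0.4, 0.4)
        with pytest.raises(ValueError):
            drift_velocity(0.5, -0.4, 0.4)

    @given(st.floats(min_value=0, max_value=50), st.floats(min_value=1e-3, max_value=50))
    @settings(max_examples=40, deadline=None)
    def test_bounded_and_increasing(self, pka, dp):
        v = drift_velocity(pka, 0.4, 0.3)
        assert -0.3 <= v < 0.4  # the lower bound is attained at pka = 0
        assert drift_velocity(pka + dp, 0.4, 0.3) > v


class TestSimParams:
    def test_stability_guard(self):
        with pytest.raises(ValueError, match="dt"):
            SimParams(dt=0.2, k_unbind=1.0)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            SimParams(k_bind=-0.1)

    def test_vdrift_property(self):
        assert SimParams().v_drift == pytest.approx(drift_velocity(0.7, 0.4, 0.4))


class TestAdvanceState:
    def test_bound_walker_steps_radially(self):
        # v_drift ~= 0.1 outward, no diffusion; walker at r=0.5
        params = SimParams(pka_signal=1e9, v_plus=0.1, v_minus=0.0, diffusion=0.0, k_bind=0.0, dt=0.01)
        state = SimState(np.array([[0.3, 0.4]]), np.array([True]))
        rng = np.random.default_rng(0)
        theta_before = np.arctan2(0.4, 0.3)
        advance_state(state, params, rng)
        r = np.hypot(*state.positions[0])
        theta_after = np.arctan2(state.positions[0][1], state.positions[0][0])
        if state.bound[0]:  # still bound: moved radially outward by ~v*dt
            assert r == pytest.approx(0.5 + 0.1 * 0.01, abs=1e-12)
            assert theta_after == pytest.approx(theta_before)
        else:  # unbound this step: no diffusion, position frozen
            assert r == pytest.approx(0.5)

    def test_reflection_at_boundary(self):
        from mitoradial.transport import _reflect_radially

        pos = np.array([[1.05, 0.0], [0.0, -1.2], [0.5, 0.5]])
        _reflect_radially(pos)
        np.testing.assert_allclose(pos[0], [0.95, 0.0])
        np.testing.assert_allclose(pos[1], [0.0, -0.8])
        np.testing.assert_allclose(pos[2], [0.5, 0.5])

    def test_null_dynamics_frozen(self):
        params = SimParams(k_bind=0.0, diffusion=0.0)
        state = SimState(np.array([[0.1, 0.2], [0.5, -0.3]]), np.array([False, False]))
        start = state.positions.copy()
        rng = np.random.default_rng(1)
        for _ in range(100):
            advance_state(state, params, rng)
        np.testing.assert_array_equal(state.positions, start)

    def test_confinement_invariant(self):
        params = SimParams(k_bind=0.5, pka_signal=5.0, diffusion=0.3, dt=0.01)
        rng = np.random.default_rng(2)
        from mitoradial.transport import initial_state

        state = initial_state(params.replace(n_mito=500), rng)
        for _ in range(500):
            advance_state(state, params, rng)
            assert np.all(state.radii <= 1.0 + 1e-12)

    def test_inward_drift_passes_through_origin(self):
        params = SimParams(pka_signal=0.0, v_plus=0.0, v_minus=0.5, diffusion=0.0, k_bind=0.0, dt=0.01)
        state = SimState(np.array([[0.003, 0.0]]), np.array([True]))
        rng = np.random.default_rng(3)
        advance_state(state, params, rng)
        if state.bound[0]:
            # r = |0.003 - 0.005| = 0.002 on the opposite ray
            np.testing.assert_allclose(state.positions[0], [-0.002, 0.0], atol=1e-12)


class TestRunSimulation:
    def test_unbiased_diffusion_matches_uniform_disk_law(self):
        res = run_simulation(SimParams(k_bind=0.0, diffusion=0.05, n_mito=5000, n_steps=1500, seed=10))
        assert ks_distance_to_r_squared(res.radii) < 0.03
        assert res.mean_radius == pytest.approx(2.0 / 3.0, abs=0.02)

    def test_strong_outward_drift_accumulates_periphery(self):
        res = run_simulation(
            SimParams(pka_signal=10.0, k_bind=1.0, v_plus=0.4, v_minus=0.4, n_mito=2000, n_steps=4000, seed=4)
        )
        assert res.mean_radius > 2.0 / 3.0

    def test_determinism(self):
        p = SimParams(n_mito=300, n_steps=500, seed=9)
        r1, r2 = run_simulation(p), run_simulation(p)
        np.testing.assert_array_equal(r1.radii, r2.radii)
        np.testing.assert_array_equal(r1.mean_radius_trajectory, r2.mean_radius_trajectory)

    def test_radii_confined(self):
        res = run_simulation(SimParams(n_mito=500, n_steps=1000, diffusion=0.2, seed=5))
        assert np.all(res.radii <= 1.0)
        assert np.all(res.radii >= 0.0)

    def test_convergence_mode_stops_and_reports(self):
        res = run_simulation(SimParams(k_bind=0.0, diffusion=0.05, n_mito=2000, seed=6))
        assert res.converged
        assert res.n_steps_run < 100_000

    def test_timestep_robustness(self):
        base = SimParams(n_mito=3000, n_steps=8000, dt=0.02, diffusion=0.01, seed=7)
        halved = SimParams(n_mito=3000, n_steps=16000, dt=0.01, diffusion=0.01, seed=7)
        r1, r2 = run_simulation(base), run_simulation(halved)
        se = r1.radii.std(ddof=1) / np.sqrt(r1.radii.size)
        assert abs(r1.mean_radius - r2.mean_radius) < 3 * se + 3 * 1e-3

    def test_monotone_in_pka(self):
        means = []
        for pka in (0.2, 1.0, 5.0):
            res = run_simulation(
                SimParams(pka_signal=pka, k_bind=0.25, diffusion=0.01, n_mito=3000, n_steps=6000, seed=8)
            )
            means.append(res.mean_radius)
        se = 0.25 / np.sqrt(3000)
        assert means[1] >= means[0] - 2 * se
        assert means[2] >= means[1] - 2 * se
        assert means[2] > means[0]


class TestMeanPositionSweep:
    def test_shape_and_kbind_zero_flat(self):
        base = SimParams(n_mito=1200, n_steps=3000, dt=0.02, diffusion=0.02, seed=11)
        mean_r, stderr = mean_position_sweep([0.2, 1.0, 5.0], [0.0, 0.5], base)
        assert mean_r.shape == (3, 2)
        flat = mean_r[:, 0]
        assert flat.max() - flat.min() < 0.02
        assert np.all(stderr > 0)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            mean_position_sweep([], [0.1], SimParams())
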