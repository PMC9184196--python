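import dataclasses
import math

import numpy as np
import pytest

from fhnsync import (
    ControllerSchedule,
    CouplingMatrix,
    DelayPair,
    ErrorState,
    HistoryBuffer,
    SimulationDiverged,
    control_delayed,
    control_nondelayed,
    drive_rhs,
    error_system_rhs,
    euler_maruyama_step,
    integrate_error_system,
    lag_error,
    reference_scenario,
    rk4_step,
    run_simulation,
    slave_rhs,
)

from conftest import SUITE_SEED


@pytest.fixture()
def cfg_sched():
    return reference_scenario("nondelayed_nonnoisy")


class TestRightHandSides:
    def test_zero_state_gives_pure_ees_on_membranes(self, cfg_sched):
        cfg, _ = cfg_sched
        d = drive_rhs(np.zeros(10), 0.0, cfg)
        np.testing.assert_allclose(d[:5], 0.1 / (2 * math.pi * 0.129), rtol=1e-14)
        np.testing.assert_array_equal(d[5:], 0.0)

    def test_recovery_derivative_is_linear(self, cfg_sched):
        cfg, _ = cfg_sched
        state = np.concatenate([np.full(5, 0.3), np.full(5, 2.0)])
        d = drive_rhs(state, 1.0, cfg)
        np.testing.assert_allclose(d[5:], cfg.b_vec * 0.3 - cfg.c_vec * 2.0, rtol=1e-14)

    def test_coupling_vanishes_for_equal_membranes(self, cfg_sched):
        cfg, _ = cfg_sched
        uncoupled = dataclasses.replace(cfg, coupling=CouplingMatrix(np.zeros((5, 5))))
        state = np.concatenate([np.full(5, 0.7), np.linspace(0, 1, 5)])
        np.testing.assert_allclose(
            drive_rhs(state, 2.5, cfg), drive_rhs(state, 2.5, uncoupled), atol=1e-16
        )

    def test_slave_equals_drive_without_control(self, cfg_sched):
        cfg, _ = cfg_sched
        state = np.linspace(-0.2, 0.4, 10)
        np.testing.assert_array_equal(
            slave_rhs(state, 3.0, cfg, u=None), drive_rhs(state, 3.0, cfg)
        )

    def test_control_acts_on_membranes_only(self, cfg_sched):
        cfg, _ = cfg_sched
        state = np.linspace(-0.2, 0.4, 10)
        u = np.arange(1.0, 6.0)
        with_u = slave_rhs(state, 3.0, cfg, u=u)
        without = slave_rhs(state, 3.0, cfg)
        np.testing.assert_allclose(with_u[:5] - without[:5], u, rtol=1e-14)
        np.testing.assert_array_equal(with_u[5:], without[5:])

    def test_common_noise_cancels_in_state_difference(self):
        cfg, _ = reference_scenario("nondelayed_noisy")
        state = np.linspace(-0.2, 0.4, 10)
        xi = np.array([0.5, -1.0, 2.0, 0.0, 3.3])
        diff = slave_rhs(state, 1.0, cfg, noise_sample=xi, u=None) - drive_rhs(
            state, 1.0, cfg, noise_sample=xi
        )
        np.testing.assert_array_equal(diff, 0.0)

    def test_noisy_variant_requires_noise_sample(self):
        cfg, _ = reference_scenario("nondelayed_noisy")
        with pytest.raises(ValueError):
            drive_rhs(np.zeros(10), 0.0, cfg)

    def test_delayed_variant_requires_history(self):
        cfg, _ = reference_scenario("delayed_nonnoisy")
        with pytest.raises(ValueError):
            drive_rhs(np.zeros(10), 1.0, cfg)


class TestControlLaws:
    def test_zero_errors_give_zero_control(self, cfg_sched):
        cfg, sched = cfg_sched
        err = ErrorState(np.zeros(5), np.zeros(5))
        np.testing.assert_array_equal(control_nondelayed(err, 12.3, cfg, sched), 0.0)

    def test_membrane_error_gain(self, cfg_sched):
        # u_1 = 2*e_x1*(g_11 + b_1 + c_1) at a time where sin(wt) = 0
        cfg, sched = cfg_sched
        err = ErrorState(np.array([1.0, 0, 0, 0, 0]), np.zeros(5))
        u = control_nondelayed(err, 0.0, cfg, sched)
        g11 = cfg.coupling.G[0, 0]
        assert u[0] == pytest.approx(2 * (g11 + 1.0 + 0.001))
        np.testing.assert_array_equal(u[1:], 0.0)

    def test_recovery_error_gain(self, cfg_sched):
        # u_1 = -2*e_y1*(g_12 - b_1 - c_1) at a time where cos(wt) = 0
        cfg, sched = cfg_sched
        t = (math.pi / 2) / cfg.ees.omega
        err = ErrorState(np.zeros(5), np.array([1.0, 0, 0, 0, 0]))
        u = control_nondelayed(err, t, cfg, sched)
        g12 = cfg.coupling.G[0, 1]
        # only the e_y branch contributes (e_x = 0)
        assert u[0] == pytest.approx(-2 * (g12 - 1.0 - 0.001), rel=1e-12)

    def test_nondelayed_law_rejects_delayed_config(self):
        cfg, sched = reference_scenario("delayed_nonnoisy")
        err = ErrorState(np.zeros(5), np.zeros(5))
        with pytest.raises(ValueError):
            control_nondelayed(err, 0.0, cfg, sched)

    def test_delayed_law_value(self):
        cfg, sched = reference_scenario("delayed_nonnoisy")
        # isolate neuron 1 with g_11 := 0.001, b=1, c=0.001
        G = np.zeros((5, 5))
        G[0, 0] = 0.001
        cfg = dataclasses.replace(cfg, coupling=CouplingMatrix(G))
        err = ErrorState(np.array([1.0, 0, 0, 0, 0]), np.zeros(5))
        u = control_delayed(err, cfg, sched)
        assert u[0] == pytest.approx(-0.001 * 0.999)
        np.testing.assert_array_equal(u[1:], 0.0)

    def test_delayed_law_vanishes_when_b_equals_c(self):
        cfg, sched = reference_scenario("delayed_nonnoisy")
        params = tuple(dataclasses.replace(p, b=0.5, c=0.5) for p in cfg.params)
        cfg = dataclasses.replace(cfg, params=params)
        err = ErrorState(np.ones(5), np.ones(5))
        np.testing.assert_array_equal(control_delayed(err, cfg, sched), 0.0)

    def test_delayed_law_rejects_nondelayed_config(self, cfg_sched):
        cfg, sched = cfg_sched
        with pytest.raises(ValueError):
            control_delayed(ErrorState(np.zeros(5), np.zeros(5)), cfg, sched)


class TestLagError:
    def test_zero_delays_reduce_to_instantaneous(self):
        err = lag_error(lambda t: np.array([1.0, 0.0]), lambda t: np.array([0.0, 0.0]),
                        5.0, DelayPair(0.0, 0.0))
        assert err.ex[0] == 0.5

    def test_constant_trajectories_ignore_delays(self):
        err = lag_error(lambda t: np.array([0.8, 0.1]), lambda t: np.array([0.2, 0.1]),
                        5.0, DelayPair(0.4, 0.2))
        assert err.ex[0] == pytest.approx(0.3)
        assert err.ey[0] == pytest.approx(0.0)

    def test_linear_trajectories_expose_delay_difference(self):
        f = lambda t: np.array([t, t])
        err = lag_error(f, f, 5.0, DelayPair(0.4, 0.2))
        assert err.ex[0] == pytest.approx(-0.1)


class TestSteppers:
    def test_rk4_exponential_decay(self):
        # one-step amplification is the degree-4 Taylor polynomial of e^{-h}:
        # 1 - 0.1 + 0.005 - 1e-3/6 + 1e-4/24 = 0.90483750000
        y = rk4_step(lambda t, y: -y, 0.0, np.array([1.0]), 0.1)
        expected = sum((-0.1) ** k / math.factorial(k) for k in range(5))
        assert y[0] == pytest.approx(expected, abs=1e-15)
        assert y[0] == pytest.approx(math.exp(-0.1), abs=1e-7)

    def test_rk4_constant_field(self):
        y = rk4_step(lambda t, y: np.zeros_like(y), 0.0, np.array([3.7]), 0.1)
        assert y[0] == 3.7

    def test_euler_maruyama_zero_noise_is_explicit_euler(self):
        f = lambda t, y: -2 * y
        y0 = np.array([1.5])
        a = euler_maruyama_step(f, 0.0, y0, 0.05, noise_increment=np.zeros(1))
        b = y0 + 0.05 * f(0.0, y0)
        np.testing.assert_array_equal(a, b)

    def test_rk4_fourth_order_on_exponential(self):
        # halving dt shrinks the one-interval error ~16x
        def integrate(dt):
            y = np.array([1.0])
            t = 0.0
            while t < 1.0 - 1e-12:
                y = rk4_step(lambda t, y: -y, t, y, dt)
                t += dt
            return abs(y[0] - math.exp(-1.0))

        ratio = integrate(0.1) / integrate(0.05)
        assert 8 < ratio < 32


class TestHistoryBuffer:
    def test_grid_point_lookup_is_exact(self):
        h = HistoryBuffer(2, 0.1, 10, np.array([1.0, 2.0]))
        h.append(np.array([3.0, 4.0]))
        np.testing.assert_array_equal(h.lookup(0.1), [3.0, 4.0])
        np.testing.assert_array_equal(h.lookup(0.0), [1.0, 2.0])

    def test_prehistory_is_constant_initial_condition(self):
        h = HistoryBuffer(1, 0.1, 10, np.array([5.0]))
        np.testing.assert_array_equal(h.lookup(-3.0), [5.0])

    def test_linear_interpolation_between_grid_points(self):
        h = HistoryBuffer(1, 0.1, 10, np.array([0.0]))
        h.append(np.array([1.0]))
        assert h.lookup(0.05)[0] == pytest.approx(0.5)

    def test_lookup_beyond_horizon_rejected(self):
        h = HistoryBuffer(1, 0.1, 10, np.array([0.0]))
        with pytest.raises(ValueError):
            h.lookup(0.2)


class TestRunSimulation:
    def test_uniform_grid_and_error_consistency(self, cfg_sched):
        cfg, sched = cfg_sched
        traj = run_simulation(cfg, sched, 2.0, dt=0.01)
        np.testing.assert_allclose(np.diff(traj.times), 0.01, rtol=1e-12)
        recomputed = (traj.drive - traj.slave) / 2.0
        assert np.max(np.abs(recomputed - traj.errors)) < 1e-12

    def test_control_zero_before_activation(self, cfg_sched):
        cfg, sched = cfg_sched
        sched = dataclasses.replace(sched, t_on=1.0)
        traj = run_simulation(cfg, sched, 2.0, dt=0.01)
        on = traj.times >= 1.0
        np.testing.assert_array_equal(traj.control[~on], 0.0)
        np.testing.assert_array_equal(traj.controller_active, on)
        assert np.any(traj.control[on] != 0.0)

    def test_noisy_run_reproducible_from_seed(self):
        cfg, sched = reference_scenario("nondelayed_noisy")
        a = run_simulation(cfg, sched, 2.0, dt=0.01, seed=11)
        b = run_simulation(cfg, sched, 2.0, dt=0.01, seed=11)
        np.testing.assert_array_equal(a.drive, b.drive)
        np.testing.assert_array_equal(a.slave, b.slave)

    def test_noisy_run_uses_common_noise(self):
        # the same realization hits both membrane blocks, so the noise cancels
        # exactly in the half-errors: after one step the errors of two runs
        # with different seeds are still bitwise identical
        cfg, sched = reference_scenario("nondelayed_noisy")
        a = run_simulation(cfg, sched, 1.0, dt=0.01, seed=1)
        b = run_simulation(cfg, sched, 1.0, dt=0.01, seed=2)
        assert np.max(np.abs(a.drive - b.drive)) > 1e-6
        # equality up to cancellation roundoff in (x + inc) - (y + inc)
        np.testing.assert_allclose(a.errors[:2], b.errors[:2], atol=1e-15)

    def test_divergence_abort(self, cfg_sched):
        cfg, sched = cfg_sched
        bad = dataclasses.replace(cfg, drive_ic=np.full(10, 50.0))
        with pytest.raises(SimulationDiverged):
            run_simulation(bad, sched, 5.0, dt=0.01)

    def test_law_variant_mismatch_rejected(self):
        cfg, _ = reference_scenario("nondelayed_nonnoisy")
        with pytest.raises(ValueError):
            run_simulation(cfg, ControllerSchedule(law="delayed", t_on=0.0), 1.0)

    def test_noisy_variant_rejects_rk4(self):
        cfg, sched = reference_scenario("nondelayed_noisy")
        with pytest.raises(ValueError):
            run_simulation(cfg, sched, 1.0, method="rk4")

    def test_subgrid_delay_rejected(self):
        cfg, sched = reference_scenario("delayed_nonnoisy", tau1=0.001, tau2=0.2)
        with pytest.raises(ValueError):
            run_simulation(cfg, sched, 1.0, dt=0.005)

    def test_delayed_errors_are_lagged(self):
        cfg, sched = reference_scenario("delayed_nonnoisy")
        traj = run_simulation(cfg, sched, 2.0, dt=0.01)
        k = 150  # t = 1.5 > max delay
        t = traj.times[k]
        xs = traj.drive_lookup(t - 0.4)
        ys = traj.slave_lookup(t - 0.2)
        np.testing.assert_allclose(traj.errors[k, :5], (xs[:5] - ys[:5]) / 2, atol=1e-12)

    def test_controlled_run_synchronizes(self, bench_runs):
        # the headline behavior for the non-delayed benchmark: errors collapse
        # after activation at t=150
        traj = bench_runs["nondelayed_nonnoisy", True]
        k = np.searchsorted(traj.times, 180.0)
        assert np.max(np.abs(traj.errors[k:])) < 1e-4


class TestErrorSystem:
    def test_origin_is_equilibrium(self, cfg_sched):
        cfg, _ = cfg_sched
        err = ErrorState(np.zeros(5), np.zeros(5))
        d = error_system_rhs(err, 0.0, 10.0, cfg, np.zeros(5), np.zeros(5),
                             np.zeros(5), strict=False)
        np.testing.assert_array_equal(d.ex, 0.0)
        np.testing.assert_array_equal(d.ey, 0.0)

    def test_recovery_error_channel(self, cfg_sched):
        cfg, _ = cfg_sched
        err = ErrorState(np.zeros(5), np.array([1.0, 0, 0, 0, 0]))
        d = error_system_rhs(err, 0.0, 10.0, cfg, np.zeros(5), np.zeros(5),
                             np.zeros(5), strict=False)
        assert d.ex[0] == pytest.approx(-1.0)
        assert d.ey[0] == pytest.approx(-0.001)

    def test_heterogeneous_r_rejected_in_strict_mode(self, cfg_sched):
        cfg, _ = cfg_sched
        err = ErrorState(np.zeros(5), np.zeros(5))
        with pytest.raises(ValueError):
            error_system_rhs(err, 0.0, 10.0, cfg, np.zeros(5), np.zeros(5), np.zeros(5))

    def test_dual_path_consistency_short(self):
        # reduced error system replayed along a direct run reproduces the
        # stored errors within integration tolerance
        cfg, sched = reference_scenario("nondelayed_nonnoisy")
        params = tuple(dataclasses.replace(p, r=10.0) for p in cfg.params)
        cfg = dataclasses.replace(cfg, params=params)
        sched = dataclasses.replace(sched, t_on=5.0)
        traj = run_simulation(cfg, sched, 10.0, dt=0.005, seed=SUITE_SEED)
        replay = integrate_error_system(traj, shared_r=10.0)
        assert np.max(np.abs(replay - traj.errors)) < 10 * traj.dt
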