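"""Hybrid dynamics: accelerations, collision, GRFs, step/walk simulation, energy."""

import math

import numpy as np
import pytest

from anklewalker import (
    HybridState,
    NumericsConfig,
    Phase,
    Termination,
    WalkerParams,
    accel_double_stance,
    accel_double_stance_newton_euler,
    accel_single_stance,
    ankle_spring_torque,
    collision_map,
    double_stance_end_angle,
    dpsi_dtheta,
    energy_audit,
    fixed_point,
    grf_leading,
    grf_single_stance,
    grf_trailing,
    simulate_step,
    simulate_walk,
)


def _ds_state(theta, theta_dot=-1.0, **kw):
    return HybridState(theta=theta, theta_dot=theta_dot, phase=Phase.DOUBLE_STANCE, **kw)


class TestAccelerations:
    def test_double_stance_onset_hand_value(self, params):
        # m g L sin(alpha) = 392.4, T*psi' = 133.4645*(-4), m L^2 = 80
        T = params.k * (params.mu - params.psi0)
        expected = (392.4 + T * (-4.0)) / 80.0
        got = accel_double_stance(_ds_state(params.alpha), T, params)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(-1.768, abs=2e-3)

    def test_unactuated_upright_equilibrium(self, params):
        # theta = 0 is below the double-stance range geometrically, so use
        # the reduced generalized-force form at the toe-off angle with T=0
        theta_f = double_stance_end_angle(params)
        got = accel_double_stance(_ds_state(theta_f), 0.0, params)
        assert got == pytest.approx(params.g / params.L * math.sin(theta_f), rel=1e-12)

    def test_generalized_force_equals_newton_euler(self, params):
        theta_f = double_stance_end_angle(params)
        for th in np.linspace(theta_f, params.alpha, 41):
            for T in (0.0, 50.0, params.k * (params.mu - params.psi0)):
                a1 = accel_double_stance(_ds_state(th), T, params)
                a2 = accel_double_stance_newton_euler(_ds_state(th), T, params)
                assert a1 == pytest.approx(a2, rel=1e-9, abs=1e-12)

    @pytest.mark.parametrize(
        "theta, expected", [(0.0, 0.0), (-math.pi / 6, -4.905)]
    )
    def test_single_stance_pendulum(self, params, theta, expected):
        st = HybridState(theta=theta, theta_dot=-1.0, phase=Phase.SINGLE_STANCE)
        assert accel_single_stance(st, params) == pytest.approx(expected, abs=1e-9)


class TestCollisionMap:
    def test_period_one_speeds(self, params):
        theta_post, thd_post = collision_map(-1.84410, params)
        assert theta_post == params.alpha
        assert thd_post == pytest.approx(-0.92205, abs=1e-9)

    def test_zero_maps_to_zero(self, params):
        assert collision_map(0.0, params)[1] == 0.0

    def test_kinetic_energy_ratio_is_exactly_cos_sq_2alpha(self, params):
        _, post = collision_map(-1.3, params)
        assert (post / -1.3) ** 2 == math.cos(2 * params.alpha) ** 2

    def test_rolling_limit_no_loss(self):
        p = WalkerParams(alpha=0.06, l=0.1)
        _, post = collision_map(-1.0, p)
        assert post == pytest.approx(-1.0, abs=0.015)


class TestGroundReactionForces:
    def test_trailing_force_at_onset(self, params):
        # independent construction: A=(-0.8,0), D=(-1,0), C=(-0.5, sqrt(3)/2)
        AC = math.sqrt(0.84)
        cos_dac = (-0.2 * 0.3) / (0.2 * AC)
        moment_arm = 0.2 * math.sqrt(1 - cos_dac**2)
        T = params.k * (params.mu - params.psi0)
        assert grf_trailing(params.alpha, params, T) == pytest.approx(
            T / moment_arm, rel=1e-12
        )
        assert grf_trailing(params.alpha, params, T) == pytest.approx(706.2, abs=0.5)

    def test_zero_torque_zero_force(self, params):
        assert grf_trailing(0.3, params, 0.0) == 0.0

    def test_two_force_member_identity(self, params):
        # F_A cos(theta - phi)/L == -T psi'(theta)/L^2 for any theta, T
        from anklewalker import line_angle_phi

        theta_f = double_stance_end_angle(params)
        for th in np.linspace(theta_f, params.alpha, 19):
            T = ankle_spring_torque(min(params.mu, float(th) + 2.3), params) + 5.0
            FA = grf_trailing(th, params, T)
            lhs = FA * math.cos(th - line_angle_phi(th, params)) / params.L
            rhs = -T * dpsi_dtheta(th, params) / params.L**2
            assert lhs == pytest.approx(rhs, rel=1e-9)

    def test_leading_force_at_period_one_onset(self, params):
        T = params.k * (params.mu - params.psi0)
        thd_star, _ = fixed_point(params)
        FB = grf_leading(params.alpha, thd_star, params, T)
        assert FB == pytest.approx(149.5, rel=0.01)

    def test_leading_force_static_stand(self, params):
        assert grf_leading(0.0, 0.0, params, 0.0) == pytest.approx(
            params.m * params.g, rel=1e-12
        )

    def test_centrifugal_fly_off_sign(self, params):
        assert grf_leading(params.alpha, -10.0, params, 0.0) < 0

    def test_single_stance_force(self, params):
        assert grf_single_stance(0.0, 0.0, params) == pytest.approx(784.8)
        vC = 1.84410
        f = grf_single_stance(-params.alpha, vC / params.L, params)
        assert f == pytest.approx(407.6, abs=0.5)
        v_flyoff = math.sqrt(params.g * params.L * math.cos(params.alpha))
        assert grf_single_stance(-params.alpha, v_flyoff / params.L, params) == (
            pytest.approx(0.0, abs=1e-9)
        )


class TestSimulateStep:
    def test_period_one_step_period(self, params, oracle):
        res, traj, nxt = simulate_step(
            HybridState(theta=params.alpha, theta_dot=oracle.theta_dot_star),
            None,
            params,
        )
        assert res.termination is Termination.COMPLETED
        assert res.duration == pytest.approx(0.967, abs=0.002)
        # fixed point: post-step velocity returns to the initial one
        assert nxt.theta_dot == pytest.approx(oracle.theta_dot_star, abs=1e-8)
        assert nxt.trailing_leg != HybridState(theta=params.alpha, theta_dot=-1).trailing_leg

    def test_all_grf_positive_along_period_one_gait(self, params, oracle):
        res, traj, _ = simulate_step(
            HybridState(theta=params.alpha, theta_dot=oracle.theta_dot_star),
            None,
            params,
        )
        assert res.min_grf_leading > 0
        assert res.min_grf_single_stance > 0
        ds = traj.phase == 0
        assert np.all(traj.F_A[ds] >= -1e-9)
        assert np.all(traj.F_B[ds] > 0)
        assert np.nanmin(traj.f_ss) > 0

    def test_min_leading_grf_at_double_stance_onset(self, params, oracle):
        res, traj, _ = simulate_step(
            HybridState(theta=params.alpha, theta_dot=oracle.theta_dot_star),
            None,
            params,
        )
        ds = traj.phase == 0
        assert res.min_grf_leading == pytest.approx(traj.F_B[ds][0], rel=1e-9)

    def test_subcritical_stiffness_falls_back(self, params):
        p = params.with_(k=60.0)  # below k_C ~ 67.5
        thd0 = -0.8
        res, _, _ = simulate_step(
            HybridState(theta=p.alpha, theta_dot=thd0), None, p
        )
        assert res.termination is Termination.FALL_BACK

    def test_degenerate_start_is_immediate_fall_back(self, params):
        res, _, _ = simulate_step(
            HybridState(theta=params.alpha, theta_dot=0.0), None, params
        )
        assert res.termination is Termination.FALL_BACK

    def test_duration_converged_in_tolerance(self, params, oracle):
        durs = []
        for tol in (1e-11, 5e-12):
            res, _, _ = simulate_step(
                HybridState(theta=params.alpha, theta_dot=oracle.theta_dot_star),
                None,
                params,
                NumericsConfig(tol=tol),
            )
            durs.append(res.duration)
        assert abs(durs[0] - durs[1]) < 1e-8


class TestSimulateWalk:
    def test_geometric_convergence_of_velocity_errors(self, params, oracle):
        thd_star = oracle.theta_dot_star
        steps, _ = simulate_walk(
            HybridState(theta=params.alpha, theta_dot=-1.2), 8, None, params
        )
        errs = np.array([abs(s.start_theta_dot - thd_star) for s in steps])
        # errors at steps 2..6: geometric decay at the Floquet ratio
        ratios = errs[3:7] / errs[2:6]
        assert np.allclose(ratios, 0.25, rtol=0.02)

    def test_constant_periods_on_the_limit_cycle(self, params, oracle):
        steps, strides = simulate_walk(
            HybridState(theta=params.alpha, theta_dot=oracle.theta_dot_star),
            10,
            None,
            params,
        )
        durs = np.array([s.duration for s in steps])
        assert np.all(np.abs(durs - durs[0]) < 1e-6)
        assert len(strides) == 5
        assert strides[0].stride_period == pytest.approx(2 * durs[0], abs=1e-9)

    def test_early_stop_on_fall_back(self, params):
        p = params.with_(k=60.0)
        steps, _ = simulate_walk(
            HybridState(theta=p.alpha, theta_dot=-0.8), 10, None, p
        )
        assert len(steps) < 10
        assert steps[-1].termination is Termination.FALL_BACK


class TestEnergyAudit:
    def test_period_one_step_balances(self, params, oracle):
        res, traj, _ = simulate_step(
            HybridState(theta=params.alpha, theta_dot=oracle.theta_dot_star),
            None,
            params,
        )
        audit = energy_audit(traj, params, res)
        assert abs(audit.double_stance_residual) < 1e-6
        assert abs(audit.single_stance_residual) < 1e-6
        assert audit.collision_ke_ratio_error == pytest.approx(0.0, abs=1e-12)

    def test_spring_work_closed_form(self, params, oracle):
        res, _, _ = simulate_step(
            HybridState(theta=params.alpha, theta_dot=oracle.theta_dot_star),
            None,
            params,
        )
        W = 0.5 * params.k * (params.mu - params.psi0) ** 2
        assert res.ankle_work == pytest.approx(W, rel=1e-12)
        assert W == pytest.approx(oracle.spring_work, rel=1e-10)
        assert W == pytest.approx(102.02, abs=0.01)

    def test_balance_holds_off_the_limit_cycle(self, params):
        res, traj, _ = simulate_step(
            HybridState(theta=params.alpha, theta_dot=-1.2), None, params
        )
        audit = energy_audit(traj, params, res)
        assert abs(audit.double_stance_residual) < 1e-6
        assert abs(audit.single_stance_residual) < 1e-6
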