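"""Four-bar-linkage kinematics: closed forms against brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from anklewalker import (
    LinkageSingularityError,
    WalkerParams,
    ankle_angle,
    ankle_spring_torque,
    calibrated_stiffness,
    double_stance_end_angle,
    dpsi_dtheta,
    line_angle_phi,
    linkage_state,
    singular_theta,
    toe_offset,
)
from anklewalker.fixtures import psi_oracle


class TestParams:
    def test_defaults_expose_derived_quantities(self, params):
        assert params.toe_offset == pytest.approx(0.8)
        assert params.step_length == pytest.approx(1.0)
        assert params.psi0 == pytest.approx(math.pi / 2 - math.pi / 6)

    @pytest.mark.parametrize(
        "bad",
        [
            dict(alpha=2.0),  # >= pi/2
            dict(mu=1.0),  # spring not cocked: mu < pi/2 - alpha
            dict(mu=3.2),  # >= pi
            dict(l=1.1),  # foot longer than the step
            dict(m=-1.0),
            dict(k=0.0),
        ],
    )
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            WalkerParams(**bad)

    def test_stiffness_calibration_matches_peak_torque_rule(self, params):
        # peak plantar-flexion torque ~ 17% of body weight x leg length
        target = 0.17 * params.m * params.g * params.L
        assert target == pytest.approx(133.416, abs=1e-3)
        k = calibrated_stiffness(params)
        assert k == pytest.approx(87.3, abs=0.05)
        assert k * (params.mu - params.psi0) == pytest.approx(target, rel=1e-12)


class TestToeOffset:
    def test_standard_value(self, params):
        assert toe_offset(params) == pytest.approx(0.8, abs=1e-12)

    def test_wide_step_angle(self):
        p = WalkerParams(alpha=0.6, l=0.2)
        assert toe_offset(p) == pytest.approx(2 * math.sin(0.6) - 0.2)

    def test_foot_spanning_whole_step_rejected(self, params):
        with pytest.raises(ValueError):
            WalkerParams(l=2 * params.L * math.sin(params.alpha))


class TestAnkleAngle:
    @pytest.mark.parametrize(
        "theta, expected",
        [
            (math.pi / 6, math.pi / 3),  # flat trailing foot at onset
            (0.25, 2.1064),  # law-of-cosines hand value
        ],
    )
    def test_known_values(self, params, theta, expected):
        assert ankle_angle(theta, params) == pytest.approx(expected, abs=2e-4)

    def test_mu_reached_exactly_at_double_stance_end(self, params):
        theta_f = double_stance_end_angle(params)
        assert ankle_angle(theta_f, params) == pytest.approx(params.mu, abs=1e-12)

    def test_matches_circle_intersection_oracle(self, params):
        theta_f = double_stance_end_angle(params)
        for th in np.linspace(theta_f, params.alpha, 23):
            assert ankle_angle(th, params) == pytest.approx(
                psi_oracle(th, params), abs=1e-10
            )

    def test_singularity_reported_as_typed_error(self, params):
        th_sing = singular_theta(params)
        with pytest.raises(LinkageSingularityError):
            ankle_angle(th_sing - 0.01, params)

    def test_strictly_decreasing_in_theta(self, params):
        theta_f = double_stance_end_angle(params)
        ths = np.linspace(theta_f, params.alpha, 200)
        psis = np.array([ankle_angle(t, params) for t in ths])
        assert np.all(np.diff(psis) < 0)


class TestLineAngle:
    def test_double_stance_onset(self, params):
        assert line_angle_phi(params.alpha, params) == pytest.approx(
            math.atan2(math.sqrt(3) / 2, 0.3), abs=1e-12
        )

    def test_double_stance_end(self, params):
        theta_f = double_stance_end_angle(params)
        assert line_angle_phi(theta_f, params) == pytest.approx(0.998092, abs=1e-5)

    def test_within_first_quadrant_on_range(self, params):
        theta_f = double_stance_end_angle(params)
        for th in np.linspace(theta_f, params.alpha, 50):
            assert 0 < line_angle_phi(th, params) < math.pi / 2


class TestDpsiDtheta:
    def test_value_at_onset_is_minus_four(self, params):
        assert dpsi_dtheta(params.alpha, params) == pytest.approx(-4.0, abs=1e-12)

    def test_value_at_toe_off(self, params):
        theta_f = double_stance_end_angle(params)
        assert dpsi_dtheta(theta_f, params) == pytest.approx(-7.3629, abs=1e-3)

    def test_matches_central_finite_difference(self, params):
        theta_f = double_stance_end_angle(params)
        h = 1e-6
        for th in np.linspace(theta_f + 2 * h, params.alpha - 2 * h, 17):
            fd = (ankle_angle(th + h, params) - ankle_angle(th - h, params)) / (2 * h)
            assert dpsi_dtheta(th, params) == pytest.approx(fd, rel=1e-6)


class TestDoubleStanceEndAngle:
    def test_standard_value_against_bisection(self, params, oracle):
        assert double_stance_end_angle(params) == pytest.approx(
            oracle.theta_f, abs=1e-9
        )

    def test_zero_extent_when_spring_starts_uncocked(self, params):
        p = params.with_(mu=math.pi / 2 - params.alpha + 1e-9)
        assert double_stance_end_angle(p) == pytest.approx(params.alpha, abs=1e-6)

    def test_no_solution_raises(self, params):
        with pytest.raises(ValueError):
            double_stance_end_angle(params.with_(mu=3.14159, l=0.7))


class TestSpringTorque:
    def test_peak_at_onset_matches_calibration(self, params):
        T = ankle_spring_torque(params.psi0, params)
        assert T == pytest.approx(133.46, abs=0.01)

    def test_released_spring_does_not_pull_back(self, params):
        assert ankle_spring_torque(params.mu, params) == 0.0
        assert ankle_spring_torque(params.mu + 0.1, params) == 0.0

    def test_vectorised(self, params):
        psis = np.array([params.psi0, params.mu, params.mu + 0.5])
        T = ankle_spring_torque(psis, params)
        assert T[0] > 0 and T[1] == 0 and T[2] == 0


class TestLinkageState:
    def test_flat_foot_configuration_at_onset(self, params):
        ls = linkage_state(params.alpha, params)
        assert ls.D[0] == pytest.approx(-2 * params.L * math.sin(params.alpha), abs=1e-12)
        assert ls.D[1] == pytest.approx(0.0, abs=1e-12)
        assert ls.psi == pytest.approx(math.pi / 2 - params.alpha, abs=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(u=st.floats(0.0, 1.0))
    def test_triangle_identity_and_heel_above_ground(self, u):
        p = WalkerParams()
        theta_f = double_stance_end_angle(p)
        th = theta_f + u * (p.alpha - theta_f)
        ls = linkage_state(th, p)
        # law of cosines AC^2 = l^2 + L^2 - 2 l L cos(psi)
        lhs = ls.AC**2
        rhs = p.l**2 + p.L**2 - 2 * p.l * p.L * math.cos(ls.psi)
        assert lhs == pytest.approx(rhs, rel=1e-10)
        assert ls.D[1] >= -1e-12  # ankle never below ground in double stance
        assert abs(p.L - math.hypot(ls.D[0] + p.L * math.sin(th), ls.D[1] - p.L * math.cos(th))) < 1e-9
        assert ls.dpsi_dtheta < 0
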