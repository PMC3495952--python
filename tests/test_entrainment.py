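"""Entrainment, phase locking and the speed-vs-phase experiments."""

import math

import numpy as np
import pytest

from anklewalker import (
    EntrainmentCriterion,
    GatingPolicy,
    HybridState,
    Leg,
    Phase,
    PulseTrain,
    StrideRecord,
    default_pulse,
    detect_entrainment,
    fixed_point,
    gait_existence_check,
    main_branch_width,
    phase_series,
    pulse_torque,
    secondary_basin_width,
    simulate_perturbed,
    simulate_walk,
    speed_vs_phase,
)


@pytest.fixture(scope="module")
def base(params):
    return gait_existence_check(params)


@pytest.fixture(scope="module")
def two_tau0(base):
    return 2 * base.step_period


class TestPulseTrain:
    def test_activity_window(self, params):
        p = default_pulse(params, period=2.0, offset=0.3)
        assert p.amplitude == pytest.approx(13.35, abs=0.01)
        assert p.active(0.35) and p.active(2.39)
        assert not p.active(0.25) and not p.active(0.41)

    def test_invalid_width_rejected(self):
        with pytest.raises(ValueError):
            PulseTrain(amplitude=1.0, width=3.0, period=2.0)

    def test_offset_normalised_into_period(self):
        p = PulseTrain(amplitude=1.0, width=0.1, period=2.0, offset=4.3)
        assert p.offset == pytest.approx(0.3)


class TestPulseTorqueGating:
    def test_active_trailing_double_stance(self, params):
        pulse = default_pulse(params, period=2.0, offset=0.0)
        st = HybridState(theta=params.alpha, theta_dot=-1.0, trailing_leg=Leg.LEG_A)
        assert pulse_torque(0.05, st, pulse, params) == pytest.approx(pulse.amplitude)

    def test_nullified_in_swing(self, params):
        pulse = default_pulse(params, period=2.0, offset=0.0)
        st = HybridState(
            theta=0.1, theta_dot=-1.0, phase=Phase.SINGLE_STANCE, trailing_leg=Leg.LEG_A
        )
        assert pulse_torque(0.05, st, pulse, params) == 0.0

    def test_nullified_on_other_leg(self, params):
        pulse = default_pulse(params, period=2.0, offset=0.0, perturbed_leg=Leg.LEG_A)
        st = HybridState(theta=params.alpha, theta_dot=-1.0, trailing_leg=Leg.LEG_B)
        assert pulse_torque(0.05, st, pulse, params) == 0.0

    def test_inactive_between_pulses(self, params):
        pulse = default_pulse(params, period=2.0, offset=0.0)
        st = HybridState(theta=params.alpha, theta_dot=-1.0)
        assert pulse_torque(1.0, st, pulse, params) == 0.0

    def test_truncation_vs_extension_past_mu(self, params):
        # theta below toe-off angle: psi > mu
        from anklewalker import double_stance_end_angle

        th = double_stance_end_angle(params) - 0.01
        st = HybridState(theta=th, theta_dot=-1.0)
        trunc = default_pulse(params, period=2.0, offset=0.0)
        ext = default_pulse(
            params, period=2.0, offset=0.0,
            gating_policy=GatingPolicy.EXTEND_WHILE_POSITIVE,
        )
        assert pulse_torque(0.05, st, trunc, params) == 0.0
        assert pulse_torque(0.05, st, ext, params) == pytest.approx(ext.amplitude)


class TestDetectEntrainment:
    def _mk(self, periods, phases):
        return [
            StrideRecord(i, T, 0.3, 0.25, ph, 1.0)
            for i, (T, ph) in enumerate(zip(periods, phases))
        ]

    def test_constant_periods_entrained(self):
        s = self._mk([1.88] * 40, [-0.05] * 40)
        assert detect_entrainment(s, 1.88)

    def test_oscillating_periods_not_entrained(self):
        periods = [1.88 + (0.01 if i % 2 else -0.01) for i in range(40)]
        s = self._mk(periods, [-0.05] * 40)
        assert not detect_entrainment(s, 1.88)

    def test_drifting_phase_not_entrained(self):
        s = self._mk([1.88] * 40, list(np.linspace(-0.5, 0.4, 40)))
        assert not detect_entrainment(s, 1.88)

    def test_insufficient_strides_raise(self):
        s = self._mk([1.88] * 5, [-0.05] * 5)
        with pytest.raises(ValueError):
            detect_entrainment(s, 1.88, EntrainmentCriterion(window=30))


class TestEntrainmentRuns:
    def test_in_basin_period_entrains_for_all_offsets(self, params):
        tau_p = 1.8841  # ~ 2*tau_0 - 50 ms
        locked = []
        for frac in (0.0, 0.25, 0.5, 0.75):
            pulse = default_pulse(params, period=tau_p, offset=frac * tau_p)
            res = simulate_perturbed(params, pulse, 300)
            assert res.entrained, f"offset {frac} did not entrain"
            assert res.final_mean_stride_period == pytest.approx(tau_p, abs=1e-4)
            locked.append(res.locked_phase)
        # locked phase is a global attractor: independent of the offset
        assert max(locked) - min(locked) <= 0.01
        # pulse locks just before toe-off (end of double stance)
        assert -0.15 < np.mean(locked) < 0.0

    @pytest.mark.parametrize("detune", [0.05, 0.1])
    def test_periods_above_natural_do_not_entrain(self, params, two_tau0, detune):
        pulse = default_pulse(params, period=two_tau0 + detune)
        res = simulate_perturbed(params, pulse, 300)
        assert not res.entrained

    def test_large_detuning_below_does_not_entrain(self, params, two_tau0):
        pulse = default_pulse(params, period=two_tau0 - 0.1)
        res = simulate_perturbed(params, pulse, 300)
        assert not res.entrained

    def test_non_entrained_phase_drifts(self, params, two_tau0):
        pulse = default_pulse(params, period=two_tau0 + 0.05)
        res = simulate_perturbed(params, pulse, 100)
        ph = np.unwrap(phase_series(res.strides), period=1.0)
        drift = np.diff(ph[10:])
        # period mismatch accumulates ~ (tau_p - 2 tau_0) per stride
        assert abs(ph[-1] - ph[10]) > 0.3
        assert (np.sign(drift) == np.sign(ph[-1] - ph[10])).mean() > 0.9

    def test_zero_amplitude_reduces_to_unperturbed(self, params, base, two_tau0):
        pulse = PulseTrain(amplitude=0.0, width=0.1, period=1.9)
        thd_star = base.fixed_point_theta_dot
        steps, strides = simulate_walk(
            HybridState(theta=params.alpha, theta_dot=thd_star), 20, pulse, params
        )
        periods = np.array([s.stride_period for s in strides])
        assert np.allclose(periods, two_tau0, atol=1e-8)
        assert all(s.pulse_work == 0 for s in steps)

    def test_pulse_never_slows_or_lengthens_strides(self, params, two_tau0):
        for tau_p in (1.8841, two_tau0 + 0.05):
            pulse = default_pulse(params, period=tau_p, offset=0.4)
            res = simulate_perturbed(params, pulse, 60)
            periods = np.array([s.stride_period for s in res.strides])
            assert np.all(periods <= two_tau0 + 1e-7)

    def test_pulse_work_bounds(self, params):
        pulse = default_pulse(params, period=1.8841, offset=0.7)
        res = simulate_perturbed(params, pulse, 80)
        works = np.array([s.pulse_work for s in res.strides])
        assert np.all(works >= 0)
        assert np.all(works <= pulse.amplitude * (math.pi - params.psi0))


@pytest.fixture(scope="module")
def curve(params):
    return speed_vs_phase(params, phase_grid=161, measure="step")


class TestSpeedVsPhase:
    def test_swing_phase_pulse_leaves_speed_unchanged(self, params, curve, base):
        mid = (np.abs(curve.phases - 0.5)).argmin()
        assert curve.speeds[mid] == pytest.approx(base.average_speed, rel=1e-9)
        assert curve.pulse_work[mid] == 0.0

    def test_speed_never_below_unperturbed(self, curve, base):
        assert np.all(curve.speeds >= base.average_speed - 1e-9)

    def test_range_below_nine_percent(self, curve):
        rng = (curve.speeds.max() - curve.speeds.min()) / curve.speeds.min()
        assert rng < 0.09

    def test_negative_slope_at_end_of_double_stance(self, curve):
        # onsets in (toe_off - width, toe_off): progressively more of the
        # pulse falls into swing, so the speed falls toward v0
        lo = curve.toe_off_phase - curve.width_phase
        hi = curve.toe_off_phase
        sel = (curve.phases > lo + 0.005) & (curve.phases < hi)
        v = curve.speeds[sel]
        assert v.size >= 5
        assert np.all(np.diff(v) < 0)

    def test_secondary_branch_zero_for_monotone_curve(self, curve):
        from dataclasses import replace

        flat = replace(curve, speeds=np.linspace(1.0, 1.1, curve.phases.size))
        assert secondary_basin_width(flat) == 0.0

    def test_main_branch_cross_checks_with_energy_argument(self, params):
        sus = speed_vs_phase(params, phase_grid=101, measure="sustained")
        w = main_branch_width(sus)
        assert 2.0 < w < 6.0
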