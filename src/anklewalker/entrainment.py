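"""Entrainment and phase locking under periodic ankle torque pulses.

A square plantar-flexion torque pulse train (amplitude ``A``, width
``Delta``, period ``tau_p``, initial offset ``delta``) is superimposed
on one ankle's actuation.  Because the legs are massless, any portion
of a pulse delivered while that leg is in swing is nullified; the pulse
contributes only while its leg is the trailing leg in double stance.
The walker entrains to the pulse train -- its stride period converging
to ``tau_p`` -- only for ``tau_p`` in a narrow basin below the
unperturbed stride period ``2*tau_0``, and entrained gaits phase-lock
with the pulse at the end of double stance.

Two gating policies resolve what happens when a pulse is still active
at nominal toe-off (``psi = mu``): ``TRUNCATE_AT_MU`` ends double
stance at ``psi = mu`` regardless and nullifies the remainder of the
pulse; ``EXTEND_WHILE_POSITIVE`` lets the trailing foot keep pushing on
the pulse torque alone until pulse-off or the linkage cap
``psi = pi - eps_cap``.  Truncation is the default: it reproduces the
measured basin of entrainment and its failure threshold (see the
methods note), whereas extension injects a large burst of work near the
linkage singularity and breaks period-one entrainment at moderate
detuning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import IntEnum
from typing import Optional, Sequence

import numpy as np

from . import _kernel
from .dynamics import (
    HybridState,
    Leg,
    NumericsConfig,
    Phase,
    StepResult,
    Termination,
    simulate_walk,
)
from .geometry import ankle_angle
from .params import WalkerParams
from .poincare import fixed_point, gait_existence_check

__all__ = [
    "GatingPolicy",
    "PulseTrain",
    "StrideRecord",
    "EntrainmentCriterion",
    "EntrainmentResult",
    "PhaseSpeedCurve",
    "BasinScan",
    "default_pulse",
    "pulse_torque",
    "build_stride_records",
    "simulate_perturbed",
    "detect_entrainment",
    "phase_series",
    "speed_vs_phase",
    "secondary_basin_width",
    "main_branch_width",
    "basin_scan",
]


class GatingPolicy(IntEnum):
    TRUNCATE_AT_MU = _kernel.TRUNCATE_AT_MU
    EXTEND_WHILE_POSITIVE = _kernel.EXTEND_WHILE_POSITIVE


@dataclass(frozen=True)
class PulseTrain:
    """Periodic square plantar-flexion torque perturbation.

    The train is active at absolute time t iff
    ``((t - offset) mod period) < width``; it is delivered to
    ``perturbed_leg`` and contributes to the dynamics only while that
    leg is the trailing leg in double stance.
    """

    amplitude: float
    width: float = 0.1
    period: float = 2.0
    offset: float = 0.0
    perturbed_leg: Leg = Leg.LEG_A
    gating_policy: GatingPolicy = GatingPolicy.TRUNCATE_AT_MU

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("pulse amplitude must be >= 0")
        if not 0 < self.width < self.period:
            raise ValueError("need 0 < width < period")
        if not 0 <= self.offset < self.period:
            object.__setattr__(self, "offset", self.offset % self.period)

    def active(self, t: float) -> bool:
        return ((t - self.offset) % self.period) < self.width


def default_pulse(
    params: WalkerParams,
    period: float,
    offset: float = 0.0,
    amplitude_fraction: float = 0.1,
    width: float = 0.1,
    perturbed_leg: Leg = Leg.LEG_A,
    gating_policy: GatingPolicy = GatingPolicy.TRUNCATE_AT_MU,
) -> PulseTrain:
    """Standard perturbation: amplitude 10% of the peak ankle torque, width 0.1 s."""
    return PulseTrain(
        amplitude=amplitude_fraction * params.peak_spring_torque,
        width=width,
        period=period,
        offset=offset,
        perturbed_leg=perturbed_leg,
        gating_policy=gating_policy,
    )


@dataclass(frozen=True)
class StrideRecord:
    """Per-stride summary (a stride = two consecutive steps, starting at a
    heel strike that makes the perturbed/reference leg the trailing leg)."""

    stride_index: int
    stride_period: float
    toe_off_time_perturbed_leg: float
    pulse_onset_time_in_stride: Optional[float]
    locked_phase: Optional[float]
    pulse_work: float


@dataclass(frozen=True)
class EntrainmentCriterion:
    """Convergence criterion: over the last ``window`` strides, every
    stride period within ``period_tol`` of tau_p and the locked-phase
    range at most ``phase_range_tol``."""

    window: int = 30
    period_tol: float = 1e-3
    phase_range_tol: float = 0.01


@dataclass(frozen=True)
class EntrainmentResult:
    entrained: bool
    final_mean_stride_period: float
    locked_phase: Optional[float]
    strides: tuple[StrideRecord, ...]
    termination: Termination
    tau_p: float


def pulse_torque(
    t: float,
    state: HybridState,
    pulse: PulseTrain,
    params: WalkerParams,
    eps_cap: float = 0.01,
) -> float:
    """Effective perturbation torque at the trailing ankle at time t [N*m].

    Returns the amplitude A iff (i) the train is active at t, (ii) the
    walker is in double stance, and (iii) the perturbed leg is the
    trailing leg; otherwise 0 (swing-phase nullification).  Under
    TRUNCATE_AT_MU the contribution additionally ends at psi = mu;
    under EXTEND_WHILE_POSITIVE it persists past mu up to the linkage
    cap psi = pi - eps_cap.
    """
    if not pulse.active(t):
        return 0.0
    if state.phase is not Phase.DOUBLE_STANCE:
        return 0.0
    if state.trailing_leg != pulse.perturbed_leg:
        return 0.0
    psi = ankle_angle(state.theta, params)
    if psi > params.mu and pulse.gating_policy == GatingPolicy.TRUNCATE_AT_MU:
        return 0.0
    if psi >= math.pi - eps_cap:
        return 0.0
    return pulse.amplitude


def build_stride_records(
    steps: Sequence[StepResult],
    pulse: Optional[PulseTrain],
    perturbed_parity: int = 0,
) -> list[StrideRecord]:
    """Aggregate consecutive step pairs into stride summaries.

    ``perturbed_parity`` is the index parity (relative to ``steps[0]``)
    of the steps whose trailing leg is the perturbed/reference leg.
    Incomplete trailing pairs and non-completed steps are dropped.
    """
    strides: list[StrideRecord] = []
    i = perturbed_parity
    idx = 0
    while i + 1 < len(steps):
        s0, s1 = steps[i], steps[i + 1]
        if (
            s0.termination is not Termination.COMPLETED
            or s1.termination is not Termination.COMPLETED
        ):
            break
        period = s1.heel_strike_time - s0.start_time
        onset = None
        phase = None
        if pulse is not None and pulse.amplitude > 0:
            # pulse onset nearest the perturbed leg's toe-off
            d = (pulse.offset - s0.toe_off_time) % pulse.period
            if d > pulse.period / 2:
                d -= pulse.period
            onset = s0.toe_off_time + d
            phase = d / period
            # wrap to [-0.5, 0.5)
            phase = (phase + 0.5) % 1.0 - 0.5
        strides.append(
            StrideRecord(
                stride_index=idx,
                stride_period=period,
                toe_off_time_perturbed_leg=s0.toe_off_time,
                pulse_onset_time_in_stride=onset,
                locked_phase=phase,
                pulse_work=s0.pulse_work + s1.pulse_work,
            )
        )
        idx += 1
        i += 2
    return strides


def simulate_perturbed(
    params: WalkerParams,
    pulse: PulseTrain,
    n_strides: int = 300,
    initial: HybridState | None = None,
    numerics: NumericsConfig | None = None,
    criterion: EntrainmentCriterion | None = None,
) -> EntrainmentResult:
    """Walk ``n_strides`` strides under the pulse train and evaluate entrainment.

    The default initial condition is the unperturbed period-one fixed
    point with the perturbed leg trailing first.
    """
    criterion = criterion or EntrainmentCriterion()
    if initial is None:
        thd_star, _ = fixed_point(params)
        initial = HybridState(
            theta=params.alpha,
            theta_dot=thd_star,
            trailing_leg=pulse.perturbed_leg,
        )
    steps, strides = simulate_walk(
        initial, 2 * n_strides, pulse, params, numerics
    )
    termination = steps[-1].termination if steps else Termination.FALL_BACK
    if len(strides) >= criterion.window:
        entrained = detect_entrainment(strides, pulse.period, criterion)
    else:
        entrained = False
    window = strides[-criterion.window :] if strides else []
    mean_period = (
        float(np.mean([s.stride_period for s in window])) if window else math.nan
    )
    locked = (
        float(np.mean([s.locked_phase for s in window]))
        if (entrained and window)
        else None
    )
    return EntrainmentResult(
        entrained=entrained,
        final_mean_stride_period=mean_period,
        locked_phase=locked,
        strides=tuple(strides),
        termination=termination,
        tau_p=pulse.period,
    )


def detect_entrainment(
    strides: Sequence[StrideRecord],
    tau_p: float,
    criterion: EntrainmentCriterion | None = None,
) -> bool:
    """True iff the stride periods have converged to tau_p with a locked phase."""
    criterion = criterion or EntrainmentCriterion()
    if len(strides) < criterion.window:
        raise ValueError(
            f"need at least {criterion.window} strides, got {len(strides)}"
        )
    window = strides[-criterion.window :]
    periods = np.array([s.stride_period for s in window])
    if np.any(np.abs(periods - tau_p) > criterion.period_tol):
        return False
    phases = np.array(
        [s.locked_phase for s in window if s.locked_phase is not None]
    )
    if len(phases) == len(window):
        # guard against the rare wrap at +/-0.5
        if phases.max() - phases.min() > criterion.phase_range_tol:
            shifted = phases % 1.0
            if shifted.max() - shifted.min() > criterion.phase_range_tol:
                return False
    return True


def phase_series(strides: Sequence[StrideRecord]) -> np.ndarray:
    """Locked-phase series Phi_n = (pulse onset - toe-off)/stride period, wrapped to [-0.5, 0.5)."""
    phases = [s.locked_phase for s in strides]
    if any(p is None for p in phases):
        raise ValueError("phase series requires a pulse train")
    return np.array(phases, dtype=float)


# --------------------------------------------------------------------------
# speed vs pulse phase (single-probe experiment)
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PhaseSpeedCurve:
    """Average speed vs pulse-onset phase for a single probe pulse.

    ``measure`` selects what "average speed" means: ``"step"`` is the
    length/duration of the one step containing the pulse's effective
    portion; ``"stride"`` is the length/duration of the two-step stride
    starting at that step, which also captures the energy the pulse
    carries through the following collision; ``"sustained"`` anchors
    one pulse per stride at the prescribed phase and reports the
    steady-state stride speed, so each point is an actually achievable
    (entrainable) locked state.
    """

    phases: np.ndarray
    speeds: np.ndarray
    pulse_work: np.ndarray
    v_unperturbed: float
    stride_period_unperturbed: float
    toe_off_phase: float
    width_phase: float
    measure: str
    stride_length: float


def speed_vs_phase(
    params: WalkerParams,
    pulse_template: PulseTrain | None = None,
    phase_grid: np.ndarray | int = 201,
    measure: str = "step",
    numerics: NumericsConfig | None = None,
) -> PhaseSpeedCurve:
    """Probe the speed change caused by a single pulse at each onset phase.

    Starts on the unperturbed limit cycle (stride phase 0 = double-stance
    onset of the perturbed leg) and applies exactly one pulse with onset
    at each prescribed fraction of the unperturbed stride ``2*tau_0``.
    The perturbation can only accelerate the walker, so the curve never
    falls below the unperturbed speed.
    """
    if measure not in ("step", "stride", "sustained"):
        raise ValueError("measure must be 'step', 'stride' or 'sustained'")
    numerics = numerics or NumericsConfig()
    base = gait_existence_check(params, numerics)
    if not base.feasible:
        raise ValueError("no feasible unperturbed gait to probe")
    tau0 = base.step_period
    v0 = base.average_speed
    thd_star = base.fixed_point_theta_dot
    if pulse_template is None:
        pulse_template = default_pulse(params, period=2.0)
    if isinstance(phase_grid, (int, np.integer)):
        phase_grid = np.linspace(0.0, 1.0, int(phase_grid))
    phases = np.asarray(phase_grid, dtype=float)

    speeds = np.empty_like(phases)
    works = np.zeros_like(phases)
    one_shot_period = 1e6  # a single onset within any probe horizon
    slen = params.step_length
    if measure == "sustained":
        for i, ph in enumerate(phases):
            T, W = _sustained_stride_period(
                params, pulse_template, ph * 2 * tau0, thd_star, numerics
            )
            speeds[i] = 2 * slen / T if math.isfinite(T) else math.nan
            works[i] = W
        toe_off_phase = _unperturbed_toe_off(params, numerics) / (2 * tau0)
        return PhaseSpeedCurve(
            phases=phases,
            speeds=speeds,
            pulse_work=works,
            v_unperturbed=v0,
            stride_period_unperturbed=2 * tau0,
            toe_off_phase=toe_off_phase,
            width_phase=pulse_template.width / (2 * tau0),
            measure=measure,
            stride_length=2 * slen,
        )
    for i, ph in enumerate(phases):
        t_on = ph * 2 * tau0
        probe = PulseTrain(
            amplitude=pulse_template.amplitude,
            width=pulse_template.width,
            period=one_shot_period,
            offset=t_on,
            perturbed_leg=pulse_template.perturbed_leg,
            gating_policy=pulse_template.gating_policy,
        )
        initial = HybridState(
            theta=params.alpha,
            theta_dot=thd_star,
            trailing_leg=probe.perturbed_leg,
        )
        steps, _ = simulate_walk(initial, 8, probe, params, numerics)
        work = np.array([s.pulse_work for s in steps])
        j = int(np.argmax(work))
        if work[j] <= 0 or steps[j].termination is not Termination.COMPLETED:
            speeds[i] = v0
            continue
        works[i] = work[j]
        if measure == "step":
            speeds[i] = slen / steps[j].duration
        else:
            if j + 1 >= len(steps):
                speeds[i] = v0
                continue
            speeds[i] = 2 * slen / (
                steps[j + 1].heel_strike_time - steps[j].start_time
            )
    # unperturbed double-stance fraction of the stride, for branch bookkeeping
    toe_off_phase = _unperturbed_toe_off(params, numerics) / (2 * tau0)
    return PhaseSpeedCurve(
        phases=phases,
        speeds=speeds,
        pulse_work=works,
        v_unperturbed=v0,
        stride_period_unperturbed=2 * tau0,
        toe_off_phase=toe_off_phase,
        width_phase=pulse_template.width / (2 * tau0),
        measure=measure,
        stride_length=2 * slen,
    )


def _sustained_stride_period(
    params: WalkerParams,
    pulse_template: PulseTrain,
    onset_in_stride: float,
    thd_star: float,
    numerics: NumericsConfig,
    n_strides: int = 40,
) -> tuple[float, float]:
    """Steady-state stride period under per-stride anchored forcing.

    Each stride, a single pulse is fired ``onset_in_stride`` seconds
    after the stride's double-stance onset -- a forcing that is locked
    to the gait by construction.  Returns the converged stride period
    and the pulse work of the final stride.
    """
    state = HybridState(
        theta=params.alpha,
        theta_dot=thd_star,
        trailing_leg=pulse_template.perturbed_leg,
    )
    from .dynamics import simulate_step

    period = math.nan
    work = 0.0
    for _ in range(n_strides):
        probe = PulseTrain(
            amplitude=pulse_template.amplitude,
            width=pulse_template.width,
            period=1e6,
            offset=state.t + onset_in_stride,
            perturbed_leg=pulse_template.perturbed_leg,
            gating_policy=pulse_template.gating_policy,
        )
        t_start = state.t
        r0, _, state = simulate_step(state, probe, params, numerics)
        if r0.termination is not Termination.COMPLETED:
            return math.nan, 0.0
        r1, _, state = simulate_step(state, probe, params, numerics)
        if r1.termination is not Termination.COMPLETED:
            return math.nan, 0.0
        period = state.t - t_start
        work = r0.pulse_work + r1.pulse_work
    return period, work


def _unperturbed_toe_off(params: WalkerParams, numerics: NumericsConfig) -> float:
    from .dynamics import simulate_step

    thd_star, _ = fixed_point(params)
    res, _, _ = simulate_step(
        HybridState(theta=params.alpha, theta_dot=thd_star), None, params, numerics
    )
    return res.double_stance_duration


def secondary_basin_width(curve: PhaseSpeedCurve) -> float:
    """Width of the secondary entrainment basin from the early-double-stance
    negative-slope branch of the speed-vs-phase curve, as % of 2*tau_0.

    Restricts the curve to onsets whose pulse lies wholly inside double
    stance, finds the local speed maximum nearest phase 0 and the
    subsequent local minimum, and converts that speed span to a span of
    entrainable stride periods via ``period = stride length / speed``.
    Returns 0 if the early branch is monotone (no negative slope).
    """
    early = curve.phases <= max(curve.toe_off_phase - curve.width_phase, 0.0)
    v = curve.speeds[early]
    if v.size < 3:
        return 0.0
    # local max nearest phase 0
    i = 0
    while i + 1 < v.size and v[i + 1] >= v[i]:
        i += 1
    i_max = i
    while i + 1 < v.size and v[i + 1] <= v[i]:
        i += 1
    v_hi, v_lo = v[i_max], v[i]
    if v_hi <= v_lo:
        return 0.0
    span = curve.stride_length / v_lo - curve.stride_length / v_hi
    return span / curve.stride_period_unperturbed * 100.0


def main_branch_width(curve: PhaseSpeedCurve) -> float:
    """Primary-basin estimate from the curve's speed maximum, as % of 2*tau_0.

    The entrainable stride periods range from the unperturbed period
    down to ``stride length / v_max``; cross-check against
    :func:`basin_scan`.
    """
    v_max = float(curve.speeds.max())
    span = curve.stride_period_unperturbed - curve.stride_length / v_max
    return span / curve.stride_period_unperturbed * 100.0


# --------------------------------------------------------------------------
# basin scan
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class BasinScan:
    """Result of a perturbation-period scan.

    ``entrained[i]`` is True iff the walker entrained to ``tau_p[i]``
    for every tested initial offset (the locked state is a global
    attractor over offsets).
    """

    tau_p: np.ndarray
    entrained: np.ndarray
    locked_phase_mean: np.ndarray
    final_period_error: np.ndarray
    stride_period_unperturbed: float
    policy: GatingPolicy
    n_offsets: int

    @property
    def width_percent(self) -> float:
        """Basin measure as % of the unperturbed stride period."""
        if self.tau_p.size < 2:
            return 0.0
        dt = float(np.mean(np.diff(self.tau_p)))
        return (
            float(self.entrained.sum()) * dt / self.stride_period_unperturbed * 100.0
        )

    @property
    def all_below_natural_period(self) -> bool:
        """True iff every entrained tau_p is at most the unperturbed stride period."""
        return bool(
            np.all(
                self.tau_p[self.entrained]
                <= self.stride_period_unperturbed + 1e-12
            )
        )

    @property
    def max_entrained_detuning(self) -> float:
        """Largest entrained detuning 2*tau_0 - tau_p [s] (nan if none entrained)."""
        if not self.entrained.any():
            return math.nan
        return float(
            self.stride_period_unperturbed - self.tau_p[self.entrained].min()
        )


def basin_scan(
    params: WalkerParams,
    pulse_template: PulseTrain | None = None,
    tau_p_grid: np.ndarray | None = None,
    delta_grid: np.ndarray | int = 8,
    n_strides: int = 300,
    numerics: NumericsConfig | None = None,
    criterion: EntrainmentCriterion | None = None,
) -> BasinScan:
    """Scan perturbation periods for entrainment at multiple initial offsets.

    Defaults follow the standard protocol: tau_p over ``2*tau_0 +/- 0.1``
    s at 2 ms resolution, 8 equispaced initial offsets, 300 strides per
    run; a period is inside the basin only if every offset entrains.
    """
    numerics = numerics or NumericsConfig()
    criterion = criterion or EntrainmentCriterion()
    base = gait_existence_check(params, numerics)
    if not base.feasible:
        raise ValueError("no feasible unperturbed gait")
    two_tau0 = 2 * base.step_period
    if tau_p_grid is None:
        tau_p_grid = np.arange(two_tau0 - 0.1, two_tau0 + 0.1 + 1e-12, 0.002)
    tau_p_grid = np.asarray(tau_p_grid, dtype=float)
    if pulse_template is None:
        pulse_template = default_pulse(params, period=2.0)
    if isinstance(delta_grid, (int, np.integer)):
        n_offsets = int(delta_grid)
        delta_fracs = np.arange(n_offsets) / n_offsets
    else:
        delta_fracs = np.asarray(delta_grid, dtype=float)
        n_offsets = delta_fracs.size

    flags = np.zeros(tau_p_grid.size, dtype=bool)
    locked = np.full(tau_p_grid.size, np.nan)
    perr = np.full(tau_p_grid.size, np.nan)
    for i, tp in enumerate(tau_p_grid):
        ok = True
        phases = []
        errs = []
        for frac in delta_fracs:
            pulse = PulseTrain(
                amplitude=pulse_template.amplitude,
                width=pulse_template.width,
                period=float(tp),
                offset=float(frac * tp),
                perturbed_leg=pulse_template.perturbed_leg,
                gating_policy=pulse_template.gating_policy,
            )
            res = simulate_perturbed(
                params, pulse, n_strides, numerics=numerics, criterion=criterion
            )
            errs.append(res.final_mean_stride_period - tp)
            if not res.entrained:
                ok = False
                break
            phases.append(res.locked_phase)
        flags[i] = ok
        if errs:
            perr[i] = errs[-1]
        if ok and phases:
            locked[i] = float(np.mean(phases))
    return BasinScan(
        tau_p=tau_p_grid,
        entrained=flags,
        locked_phase_mean=locked,
        final_period_error=perr,
        stride_period_unperturbed=two_tau0,
        policy=pulse_template.gating_policy,
        n_offsets=n_offsets,
    )
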