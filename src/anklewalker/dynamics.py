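"""Hybrid event-driven simulation of steps and walks.

One step of the model runs through two continuous phases joined by an
instantaneous collision:

* **double stance** -- actuated four-bar linkage from heel strike
  (``theta = alpha``) until the trailing-ankle spring releases fully
  (``psi = mu``, toe-off); the equation of motion in generalized-force
  form is ``m*L^2*theta_dd = m*g*L*sin(theta) + T*dpsi/dtheta`` with
  total ankle torque T (spring + gated perturbation pulse);
* **single stance** -- inverted pendulum
  ``theta_dd = (g/L)*sin(theta)`` until the next heel strike at
  ``theta = -alpha``;
* **heel-strike collision** -- inelastic impact that scales the angular
  velocity by ``cos(2*alpha)`` (kinetic energy by ``cos^2(2*alpha)``),
  resets ``theta`` to ``+alpha`` and swaps the legs.

Integration is adaptive Runge-Kutta with root-localised events (see
:mod:`anklewalker._kernel`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum, IntEnum
from typing import TYPE_CHECKING, Optional, Sequence

import numpy as np
import pandas as pd

from . import _kernel
from .geometry import (
    ankle_angle,
    double_stance_end_angle,
    dpsi_dtheta,
    extension_cap_angle,
    line_angle_phi,
)
from .params import WalkerParams

if TYPE_CHECKING:  # pragma: no cover
    from .entrainment import PulseTrain, StrideRecord

__all__ = [
    "Phase",
    "Leg",
    "Termination",
    "HybridState",
    "NumericsConfig",
    "StepResult",
    "Trajectory",
    "EnergyAudit",
    "accel_double_stance",
    "accel_double_stance_newton_euler",
    "accel_single_stance",
    "collision_map",
    "grf_trailing",
    "grf_leading",
    "grf_single_stance",
    "simulate_step",
    "simulate_walk",
    "energy_audit",
]


class Phase(Enum):
    DOUBLE_STANCE = "double_stance"
    SINGLE_STANCE = "single_stance"


class Leg(IntEnum):
    """Leg parity; the trailing leg alternates every step."""

    LEG_A = 0
    LEG_B = 1

    def other(self) -> "Leg":
        return Leg(1 - self.value)


class Termination(Enum):
    COMPLETED = "completed"
    FALL_BACK = "fall_back"
    FLY_OFF = "fly_off"
    LINKAGE_SINGULARITY = "linkage_singularity"
    MAX_ITERATIONS = "max_iterations"


_STATUS = {
    _kernel.COMPLETED: Termination.COMPLETED,
    _kernel.FALL_BACK: Termination.FALL_BACK,
    _kernel.FLY_OFF: Termination.FLY_OFF,
    _kernel.LINKAGE_SINGULARITY: Termination.LINKAGE_SINGULARITY,
    _kernel.MAXITER: Termination.MAX_ITERATIONS,
}


@dataclass(frozen=True)
class HybridState:
    """Instantaneous dynamic state of the walker."""

    theta: float
    theta_dot: float
    phase: Phase = Phase.DOUBLE_STANCE
    t: float = 0.0
    step_index: int = 0
    trailing_leg: Leg = Leg.LEG_A


@dataclass(frozen=True)
class NumericsConfig:
    """Integrator settings.

    ``tol`` is the per-step error norm bound of the adaptive
    Dormand-Prince 5(4) stepper; events are localised on the dense
    interpolant to machine precision in the event function.
    ``strict_grf`` turns the fly-off monitors (leading-heel and
    single-stance ground reaction forces crossing zero) from flags
    into terminating events reported as FLY_OFF.
    """

    tol: float = 1e-11
    eps_cap: float = 0.01
    max_samples: int = 300_000
    strict_grf: bool = False


@dataclass(frozen=True)
class StepResult:
    """Per-step summary."""

    duration: float
    double_stance_duration: float
    toe_off_time: float
    heel_strike_time: float
    pre_collision_speed: float
    post_collision_speed: float
    ankle_work: float
    pulse_work: float
    min_grf_leading: float
    min_grf_single_stance: float
    termination: Termination
    start_time: float = 0.0
    start_theta_dot: float = math.nan


@dataclass
class Trajectory:
    """Dense time series of one or more steps (event-refined samples)."""

    t: np.ndarray
    theta: np.ndarray
    theta_dot: np.ndarray
    phase: np.ndarray  # 0 = double stance, 2 = single stance
    psi: np.ndarray
    torque_spring: np.ndarray
    torque_pulse: np.ndarray
    F_A: np.ndarray
    F_B: np.ndarray
    f_ss: np.ndarray
    KE: np.ndarray
    PE: np.ndarray
    work_in: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "theta": self.theta,
                "theta_dot": self.theta_dot,
                "phase": self.phase,
                "psi": self.psi,
                "torque_spring": self.torque_spring,
                "torque_pulse": self.torque_pulse,
                "F_A": self.F_A,
                "F_B": self.F_B,
                "f_ss": self.f_ss,
                "KE": self.KE,
                "PE": self.PE,
                "work_in": self.work_in,
            }
        )


# --------------------------------------------------------------------------
# pointwise dynamics
# --------------------------------------------------------------------------


def accel_double_stance(
    state: HybridState, total_ankle_torque: float, params: WalkerParams
) -> float:
    """Double-stance angular acceleration, generalized-force form [rad/s^2].

    ``theta_dd = [m*g*L*sin(theta) + T*dpsi/dtheta] / (m*L^2)`` where T
    is the total (spring + pulse) trailing-ankle torque.  This form is
    energy-consistent by construction and equals the Newton-Euler form
    (:func:`accel_double_stance_newton_euler`) identically.
    """
    th = state.theta
    return (
        params.m * params.g * params.L * math.sin(th)
        + total_ankle_torque * dpsi_dtheta(th, params)
    ) / (params.m * params.L**2)


def accel_double_stance_newton_euler(
    state: HybridState, total_ankle_torque: float, params: WalkerParams
) -> float:
    """Double-stance acceleration via the trailing ground reaction force.

    Newton-Euler route: ``theta_dd = [g*sin(theta) -
    (F_A/m)*cos(theta - phi)] / L`` with F_A from
    :func:`grf_trailing`.  Used as an internal-consistency cross-check
    of :func:`accel_double_stance`.
    """
    th = state.theta
    FA = grf_trailing(th, params, total_ankle_torque)
    phi = line_angle_phi(th, params)
    return (
        params.g * math.sin(th) - FA / params.m * math.cos(th - phi)
    ) / params.L


def accel_single_stance(state: HybridState, params: WalkerParams) -> float:
    """Single-stance (inverted pendulum) angular acceleration [rad/s^2]."""
    return params.g / params.L * math.sin(state.theta)


def collision_map(theta_dot_pre: float, params: WalkerParams) -> tuple[float, float]:
    """Inelastic heel-strike impact map.

    The collision redirects the mass velocity along the new stance leg,
    scaling speed by ``cos(2*alpha)`` (kinetic energy by
    ``cos^2(2*alpha)``) and resetting ``theta`` to ``+alpha``.
    Returns ``(theta_post, theta_dot_post)``.
    """
    return params.alpha, math.cos(2 * params.alpha) * theta_dot_pre


def grf_trailing(
    theta: float, params: WalkerParams, total_ankle_torque: float
) -> float:
    """Trailing-toe ground reaction force magnitude F_A [N].

    The massless trailing foot is a two-force member: the ankle torque
    must be balanced by the moment of F_A (applied at the toe A,
    directed at the point mass C) about the ankle D, giving
    ``F_A = T / (l*sin(angle DAC))``.
    """
    if total_ankle_torque == 0.0:
        return 0.0  # two-force member transmits nothing without ankle torque
    l, L = params.l, params.L
    ankle_angle(theta, params)  # range/singularity validation
    a = params.toe_offset
    ac2 = a * a + L * L - 2 * a * L * math.sin(theta)
    ac = math.sqrt(ac2)
    # interior angle of triangle ADC at the toe A
    cos_dac = (l * l + ac2 - L * L) / (2 * l * ac)
    sin_dac = math.sqrt(max(1.0 - cos_dac * cos_dac, 0.0))
    if l * sin_dac < 1e-12:
        raise ZeroDivisionError("GRF moment arm vanishes (linkage singular)")
    return total_ankle_torque / (l * sin_dac)


def grf_leading(
    theta: float,
    theta_dot: float,
    params: WalkerParams,
    total_ankle_torque: float,
) -> float:
    """Leading-heel ground reaction force magnitude F_B [N].

    ``F_B = m*g*cos(theta) - m*L*theta_dot^2 - F_A*sin(phi - theta)``,
    directed from the contact B toward the mass C.  Negative values mean
    the leading foot would lift off (fly-off condition); callers report
    them, this function does not raise.
    """
    FA = grf_trailing(theta, params, total_ankle_torque)
    phi = line_angle_phi(theta, params)
    return (
        params.m * params.g * math.cos(theta)
        - params.m * params.L * theta_dot**2
        - FA * math.sin(phi - theta)
    )


def grf_single_stance(
    theta: float, theta_dot: float, params: WalkerParams
) -> float:
    """Single-stance ground reaction force magnitude f [N].

    ``f = m*(g*cos(theta) - L*theta_dot^2)``; over a step its minimum
    occurs at the end of single stance (``theta = -alpha``), so the sign
    of ``f(-alpha)`` decides fly-off.
    """
    return params.m * (
        params.g * math.cos(theta) - params.L * theta_dot**2
    )


# --------------------------------------------------------------------------
# step / walk simulation
# --------------------------------------------------------------------------


def _kernel_args(params: WalkerParams, numerics: NumericsConfig):
    return (
        params.m,
        params.L,
        params.l,
        params.g,
        params.alpha,
        params.mu,
        params.k,
        params.toe_offset,
        double_stance_end_angle(params),
        extension_cap_angle(params, numerics.eps_cap),
    )


def _pulse_args(pulse: Optional["PulseTrain"]):
    if pulse is None:
        return 0.0, 1.0, 10.0, 0.0, _kernel.TRUNCATE_AT_MU
    return (
        pulse.amplitude,
        pulse.width,
        pulse.period,
        pulse.offset,
        int(pulse.gating_policy),
    )


def simulate_step(
    initial: HybridState,
    pulse: Optional["PulseTrain"],
    params: WalkerParams,
    numerics: NumericsConfig | None = None,
) -> tuple[StepResult, Trajectory, HybridState]:
    """Integrate one full step and return its summary, dense trajectory and the next initial state.

    ``initial`` must be a post-collision state (double stance at
    ``theta = alpha``).  The pulse train (if any) contributes only while
    its designated leg is the trailing leg.
    """
    numerics = numerics or NumericsConfig()
    if initial.phase is not Phase.DOUBLE_STANCE:
        raise ValueError("simulate_step starts from a post-collision double-stance state")
    if not math.isclose(initial.theta, params.alpha, rel_tol=0, abs_tol=1e-9):
        raise ValueError(
            f"post-collision state must have theta = alpha ({params.alpha:.6g}), "
            f"got {initial.theta:.6g}"
        )
    n = numerics.max_samples
    rec = [np.empty(n) for _ in range(5)]
    A, width, period, offset, policy = _pulse_args(pulse)
    active = pulse is not None and initial.trailing_leg == pulse.perturbed_leg
    (
        status,
        t_toe,
        t_heel,
        _thd_toe,
        thd_pre,
        thd_post,
        pulse_work,
        min_FB,
        min_f,
        nrec,
    ) = _kernel.sim_step(
        initial.t,
        params.alpha,
        initial.theta_dot,
        active,
        A,
        width,
        period,
        offset,
        policy,
        *_kernel_args(params, numerics),
        numerics.tol,
        rec[0],
        rec[1],
        rec[2],
        rec[3],
        rec[4],
        0,
    )
    termination = _STATUS[status]
    if termination is Termination.COMPLETED and numerics.strict_grf and (
        min_FB < 0 or min_f < 0
    ):
        termination = Termination.FLY_OFF

    traj = _postprocess(
        [r[:nrec] for r in rec], params, initial.theta_dot
    )
    psi_toe = (
        ankle_angle(traj.theta[traj.phase == 0][-1], params)
        if np.any(traj.phase == 0)
        else params.psi0
    )
    ankle_work = 0.5 * params.k * (
        (params.mu - params.psi0) ** 2
        - (params.mu - min(psi_toe, params.mu)) ** 2
    )
    result = StepResult(
        duration=(t_heel - initial.t) if math.isfinite(t_heel) else math.nan,
        double_stance_duration=(t_toe - initial.t) if math.isfinite(t_toe) else math.nan,
        toe_off_time=t_toe,
        heel_strike_time=t_heel,
        pre_collision_speed=abs(thd_pre) * params.L if math.isfinite(thd_pre) else math.nan,
        post_collision_speed=abs(thd_post) * params.L if math.isfinite(thd_post) else math.nan,
        ankle_work=ankle_work,
        pulse_work=pulse_work,
        min_grf_leading=min_FB,
        min_grf_single_stance=min_f if math.isfinite(min_f) and min_f < 1e299 else math.nan,
        termination=termination,
        start_time=initial.t,
        start_theta_dot=initial.theta_dot,
    )
    nxt = HybridState(
        theta=params.alpha,
        theta_dot=thd_post,
        phase=Phase.DOUBLE_STANCE,
        t=t_heel,
        step_index=initial.step_index + 1,
        trailing_leg=initial.trailing_leg.other(),
    )
    return result, traj, nxt


def _postprocess(rec: Sequence[np.ndarray], params: WalkerParams, thd0: float) -> Trajectory:
    t, th, thd, ph, tp = rec
    m, L, g, k, mu = params.m, params.L, params.g, params.k, params.mu
    ds = ph == 0.0
    psi = np.full_like(th, np.nan)
    if np.any(ds):
        a = params.toe_offset
        l = params.l
        ac2 = a * a + L * L - 2 * a * L * np.sin(th[ds])
        c = np.clip((l * l + L * L - ac2) / (2 * l * L), -1.0, 1.0)
        psi[ds] = np.arccos(c)
    T_spring = np.where(ds & (psi <= mu), k * (mu - psi), 0.0)
    T_total = T_spring + tp
    F_A = np.full_like(th, np.nan)
    F_B = np.full_like(th, np.nan)
    f_ss = np.full_like(th, np.nan)
    for i in np.flatnonzero(ds):
        F_A[i] = grf_trailing(th[i], params, T_total[i])
        phi = line_angle_phi(th[i], params)
        F_B[i] = (
            m * g * math.cos(th[i]) - m * L * thd[i] ** 2 - F_A[i] * math.sin(phi - th[i])
        )
    ss = ~ds
    f_ss[ss] = m * (g * np.cos(th[ss]) - L * thd[ss] ** 2)
    KE = 0.5 * m * L * L * thd**2
    PE = m * g * L * np.cos(th)
    # energy injected: released spring potential plus pulse work (trapezoid in psi)
    Vs0 = 0.5 * k * (mu - params.psi0) ** 2
    Vs = np.where(ds & (psi <= mu), 0.5 * k * (mu - psi) ** 2, 0.0)
    spring_in = np.where(ds, Vs0 - Vs, Vs0)
    pulse_in = np.zeros_like(th)
    if np.any(tp > 0):
        dpsi_steps = np.nan_to_num(np.diff(psi, prepend=psi[0]))
        incr = 0.5 * (tp + np.roll(tp, 1)) * dpsi_steps
        incr[0] = 0.0
        incr[~ds] = 0.0
        pulse_in = np.cumsum(np.maximum(incr, 0.0))
    work_in = spring_in + pulse_in
    return Trajectory(
        t=t,
        theta=th,
        theta_dot=thd,
        phase=ph.astype(int),
        psi=psi,
        torque_spring=T_spring,
        torque_pulse=tp,
        F_A=F_A,
        F_B=F_B,
        f_ss=f_ss,
        KE=KE,
        PE=PE,
        work_in=work_in,
    )


def simulate_walk(
    initial: HybridState,
    n_steps: int,
    pulse: Optional["PulseTrain"],
    params: WalkerParams,
    numerics: NumericsConfig | None = None,
) -> tuple[list[StepResult], list["StrideRecord"]]:
    """Chain up to ``n_steps`` steps, aggregating consecutive step pairs into strides.

    Stops early (returning partial results) on any non-COMPLETED step.
    A stride starts at a heel strike of the reference leg -- the
    perturbed leg when a pulse is present, else the first trailing leg.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    numerics = numerics or NumericsConfig()
    if initial.phase is not Phase.DOUBLE_STANCE or not math.isclose(
        initial.theta, params.alpha, rel_tol=0, abs_tol=1e-9
    ):
        raise ValueError("simulate_walk starts from a post-collision double-stance state")

    A, width, period, offset, policy = _pulse_args(pulse)
    parity = (
        int(pulse.perturbed_leg)
        if pulse is not None
        else int(initial.trailing_leg)
    )
    # kernel parity is relative to the first step's trailing leg
    perturbed_parity = (parity - int(initial.trailing_leg)) % 2
    out = np.empty((n_steps, 10))
    n = _kernel.sim_walk(
        n_steps,
        initial.theta_dot,
        perturbed_parity,
        A,
        width,
        period,
        offset,
        policy,
        *_kernel_args(params, numerics),
        numerics.tol,
        out,
    )
    steps: list[StepResult] = []
    for i in range(n):
        row = out[i]
        term = _STATUS[int(row[0])]
        steps.append(
            StepResult(
                duration=row[3] - row[1] if math.isfinite(row[3]) else math.nan,
                double_stance_duration=row[2] - row[1] if math.isfinite(row[2]) else math.nan,
                toe_off_time=row[2],
                heel_strike_time=row[3],
                pre_collision_speed=abs(row[5]) * params.L if math.isfinite(row[5]) else math.nan,
                post_collision_speed=abs(row[6]) * params.L if math.isfinite(row[6]) else math.nan,
                ankle_work=0.5 * params.k * (params.mu - params.psi0) ** 2
                if term is not Termination.FALL_BACK
                else math.nan,
                pulse_work=row[7],
                min_grf_leading=row[8],
                min_grf_single_stance=row[9] if row[9] < 1e299 else math.nan,
                termination=term,
                start_time=row[1],
                start_theta_dot=row[4],
            )
        )
    from .entrainment import build_stride_records

    strides = build_stride_records(steps, pulse, perturbed_parity)
    return steps, strides


@dataclass(frozen=True)
class EnergyAudit:
    """Per-phase energy-balance residuals of one step [J]."""

    double_stance_residual: float
    single_stance_residual: float
    collision_ke_ratio_error: float


def energy_audit(
    trajectory: Trajectory,
    params: WalkerParams,
    step: StepResult,
) -> EnergyAudit:
    """Check the work-energy balance of a completed step.

    * double stance: ``dKE + dPE`` must equal the work released by the
      ankle spring plus the pulse work;
    * single stance: ``dKE + dPE`` must vanish (conservative pendulum);
    * collision: the kinetic-energy ratio must be exactly
      ``cos^2(2*alpha)``.
    """
    ds = trajectory.phase == 0
    ss = ~ds
    if not (np.any(ds) and np.any(ss)):
        raise ValueError("energy audit needs a complete step trajectory")
    i0, i1 = np.flatnonzero(ds)[[0, -1]]
    j0, j1 = np.flatnonzero(ss)[[0, -1]]
    E = trajectory.KE + trajectory.PE
    res_ds = (E[i1] - E[i0]) - (step.ankle_work + step.pulse_work)
    res_ss = E[j1] - E[j0]
    ratio = (step.post_collision_speed / step.pre_collision_speed) ** 2
    return EnergyAudit(
        double_stance_residual=float(res_ds),
        single_stance_residual=float(res_ss),
        collision_ke_ratio_error=float(ratio - math.cos(2 * params.alpha) ** 2),
    )
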