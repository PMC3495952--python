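"""Closed-form step-to-step (Poincare) analysis of the unperturbed gait.

Sampling the state at each heel strike reduces the hybrid dynamics to a
one-dimensional map on the post-collision angular velocity.  Because
the ankle-spring work per step is the fixed amount
``W = k*(mu - psi0)^2 / 2`` while the collision removes kinetic energy
in proportion to the square of speed, the map has the closed form

    f(x) = -cos(2*alpha) * sqrt(x^2 + c),   c = k*(mu - psi0)^2/(m*L^2),

whose unique forward-progressing fixed point is the period-one gait.
The map derivative at the fixed point -- the Floquet multiplier -- is
``cos^2(2*alpha)``: collisional energy dissipation is what makes the
gait asymptotically stable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dynamics import (
    HybridState,
    NumericsConfig,
    Termination,
    simulate_step,
)
from .geometry import ankle_angle, double_stance_end_angle
from .params import WalkerParams

__all__ = [
    "StepMapResult",
    "GaitDomainError",
    "step_map",
    "fixed_point",
    "floquet_multiplier_analytic",
    "floquet_multiplier_numeric",
    "critical_stiffness",
    "gait_existence_check",
    "flyoff_stiffness",
    "spring_constant_c",
]


class GaitDomainError(ValueError):
    """Initial condition (or parameter set) outside the domain of the gait."""


@dataclass(frozen=True)
class StepMapResult:
    """Summary of the period-one gait and its feasibility."""

    fixed_point_theta_dot: float
    pre_collision_speed: float
    floquet_analytic: float
    floquet_numeric: float
    step_period: float
    average_speed: float
    k_critical: float
    feasible: bool
    min_grf_leading: float
    min_grf_single_stance: float = math.nan
    failure_reasons: tuple[str, ...] = ()


def spring_constant_c(params: WalkerParams) -> float:
    """Map constant c = k*(mu - psi0)^2 / (m*L^2) = 2W/(m*L^2) [rad^2/s^2]."""
    return params.k * (params.mu - params.psi0) ** 2 / (params.m * params.L**2)


def _vault_margin(theta_dot_0: float, params: WalkerParams) -> float:
    """Minimum of theta_dot^2 along the step started at (alpha, theta_dot_0).

    Uses the exact energy integrals of both phases: during double stance
    the total energy ``KE + m*g*L*cos(theta) + k*(mu-psi)^2/2`` is
    conserved; during single stance the pendulum energy is conserved and
    the slowest point is the apex theta = 0 (or theta_f if theta_f < 0).
    Non-positive margin means the walker cannot vault over (fall-back).
    """
    m, L, g, k, mu = params.m, params.L, params.g, params.k, params.mu
    theta_f = double_stance_end_angle(params)
    ths = np.linspace(params.alpha, theta_f, 201)
    psis = np.array([ankle_angle(t, params) for t in ths])
    U = m * g * L * np.cos(ths) + 0.5 * k * (mu - psis) ** 2
    E = 0.5 * m * L * L * theta_dot_0**2 + U[0]
    thd2_ds = 2.0 * (E - U) / (m * L * L)
    margin = float(thd2_ds.min())
    thd2_f = float(thd2_ds[-1])
    apex = 0.0 if theta_f > 0 else theta_f
    thd2_apex = thd2_f - 2 * g / L * (math.cos(apex) - math.cos(theta_f))
    return min(margin, thd2_apex)


def step_map(theta_dot_0: float, params: WalkerParams) -> float:
    """Closed-form return map: post-collision velocity after one step.

    ``f(x) = -cos(2*alpha)*sqrt(x^2 + c)`` for a forward-progressing
    start ``x < 0`` with enough energy to vault over the apex.

    Raises
    ------
    GaitDomainError
        If ``x >= 0`` or the vault-over condition fails (the walker
        falls back before the next heel strike).
    """
    if theta_dot_0 >= 0:
        raise GaitDomainError("forward progression requires theta_dot_0 < 0")
    if _vault_margin(theta_dot_0, params) <= 0:
        raise GaitDomainError(
            "insufficient kinetic energy to vault over the apex (fall-back)"
        )
    c = spring_constant_c(params)
    return -math.cos(2 * params.alpha) * math.sqrt(theta_dot_0**2 + c)


def fixed_point(params: WalkerParams) -> tuple[float, float]:
    """Period-one gait fixed point: (post-collision theta_dot*, pre-collision speed v_C).

    Energy balance (spring work per step = collision loss) gives
    ``v_C = (mu - psi0)*sqrt(k/m)/sin(2*alpha)`` and
    ``theta_dot* = -cos(2*alpha)*v_C/L`` (negative root: forward
    progression).
    """
    vC = (
        (params.mu - params.psi0)
        * math.sqrt(params.k / params.m)
        / math.sin(2 * params.alpha)
    )
    thd_star = -math.cos(2 * params.alpha) * vC / params.L
    if _vault_margin(thd_star, params) <= 0:
        raise GaitDomainError(
            "no feasible period-one gait: vault-over fails at the analytic fixed point "
            f"(k={params.k:.6g} <= k_C={critical_stiffness(params):.6g}?)"
        )
    return thd_star, vC


def floquet_multiplier_analytic(params: WalkerParams) -> float:
    """Derivative of the step-to-step map at its fixed point: cos^2(2*alpha).

    Differentiating ``f(x) = -cos(2*alpha)*sqrt(x^2 + c)`` at the fixed
    point gives exactly ``cos^2(2*alpha)`` independent of k: the
    stability margin is set solely by the collisional energy loss.  In
    (0, 1) for 0 < alpha < pi/4; approaches 1 (marginal stability) in
    the rolling limit alpha -> 0.
    """
    return math.cos(2 * params.alpha) ** 2


def floquet_multiplier_numeric(
    params: WalkerParams,
    offset_fraction: float = 0.005,
    numerics: NumericsConfig | None = None,
) -> float:
    """Floquet multiplier from central differences of the *simulated* return map.

    Simulates one full step from ``theta_dot*(1 +/- h)`` and forms
    ``[f(x*(1+h)) - f(x*(1-h))] / (2*x*h)``.  Validates the event-driven
    integration against the analytic value cos^2(2*alpha).
    """
    numerics = numerics or NumericsConfig()
    thd_star, _ = fixed_point(params)
    h = offset_fraction

    def ret(x: float) -> float:
        res, _, nxt = simulate_step(
            HybridState(theta=params.alpha, theta_dot=x), None, params, numerics
        )
        if res.termination is not Termination.COMPLETED:
            raise GaitDomainError(f"return-map simulation failed: {res.termination}")
        return nxt.theta_dot

    f_hi = ret(thd_star * (1 + h))
    f_lo = ret(thd_star * (1 - h))
    return (f_hi - f_lo) / (2 * thd_star * h)


def critical_stiffness(params: WalkerParams) -> float:
    """Marginal ("just-vault-over") ankle stiffness k_C [N*m/rad].

    At the margin the kinetic energy of the period-one gait vanishes at
    the apex theta = 0; the work-energy principle gives
    ``k_C = 2*m*g*L*(1 - cos(alpha))*sin^2(2*alpha) / (mu - psi0)^2``.
    Valid when the spring releases fully before the apex
    (``theta_f > 0``); checked and refused otherwise.
    """
    theta_f = double_stance_end_angle(params)
    if theta_f <= 0:
        raise GaitDomainError(
            "closed-form k_C assumes full spring release before the apex "
            f"(theta_f > 0); got theta_f={theta_f:.6g}"
        )
    return (
        2
        * params.m
        * params.g
        * params.L
        * (1 - math.cos(params.alpha))
        * math.sin(2 * params.alpha) ** 2
        / (params.mu - params.psi0) ** 2
    )


def gait_existence_check(
    params: WalkerParams, numerics: NumericsConfig | None = None
) -> StepMapResult:
    """Existence and feasibility of the period-one gait.

    Feasible iff (1) ``k > k_C`` (vault-over) and (2) the ground
    reaction forces stay positive along the simulated period-one step
    (no fly-off).  Fills the simulated step period, the average speed
    ``2*L*sin(alpha)/tau_0`` and the minimum leading-heel force.
    """
    numerics = numerics or NumericsConfig()
    k_C = critical_stiffness(params)
    reasons: list[str] = []
    if params.k <= k_C:
        reasons.append(
            f"vault-over fails: k={params.k:.6g} <= k_C={k_C:.6g} N*m/rad"
        )
        return StepMapResult(
            fixed_point_theta_dot=math.nan,
            pre_collision_speed=math.nan,
            floquet_analytic=math.cos(2 * params.alpha) ** 2,
            floquet_numeric=math.nan,
            step_period=math.nan,
            average_speed=math.nan,
            k_critical=k_C,
            feasible=False,
            min_grf_leading=math.nan,
            failure_reasons=tuple(reasons),
        )
    thd_star, vC = fixed_point(params)
    res, _, nxt = simulate_step(
        HybridState(theta=params.alpha, theta_dot=thd_star), None, params, numerics
    )
    if res.termination is not Termination.COMPLETED:
        reasons.append(f"period-one step terminated: {res.termination.value}")
    if res.min_grf_leading <= 0:
        reasons.append(
            f"fly-off during double stance: min F_B = {res.min_grf_leading:.4g} N"
        )
    if res.min_grf_single_stance <= 0:
        reasons.append(
            f"fly-off during single stance: min f = {res.min_grf_single_stance:.4g} N"
        )
    tau0 = res.duration
    return StepMapResult(
        fixed_point_theta_dot=thd_star,
        pre_collision_speed=vC,
        floquet_analytic=math.cos(2 * params.alpha) ** 2,
        floquet_numeric=floquet_multiplier_numeric(params, numerics=numerics)
        if not reasons
        else math.nan,
        step_period=tau0,
        average_speed=params.step_length / tau0,
        k_critical=k_C,
        feasible=not reasons,
        min_grf_leading=res.min_grf_leading,
        min_grf_single_stance=res.min_grf_single_stance,
        failure_reasons=tuple(reasons),
    )


def flyoff_stiffness(
    params: WalkerParams,
    k_tol: float = 0.1,
    numerics: NumericsConfig | None = None,
) -> float:
    """Upper ("just-fly-off") stiffness limit, by bisection on k [N*m/rad].

    With overly large k the leading foot is lifted during double stance
    (F_B < 0 on the period-one gait).  Finds the k at which the minimum
    leading-heel force crosses zero, to within ``k_tol``.
    """
    numerics = numerics or NumericsConfig()

    def min_fb(k: float) -> float:
        p = params.with_(k=k)
        thd_star, _ = fixed_point(p)
        res, _, _ = simulate_step(
            HybridState(theta=p.alpha, theta_dot=thd_star), None, p, numerics
        )
        return res.min_grf_leading

    k_lo = params.k
    if min_fb(k_lo) <= 0:
        raise GaitDomainError("baseline stiffness already causes fly-off")
    k_hi = k_lo * 2
    for _ in range(40):
        if min_fb(k_hi) <= 0:
            break
        k_lo, k_hi = k_hi, k_hi * 2
    else:
        raise GaitDomainError("no fly-off stiffness found below 2^40 * k")
    while k_hi - k_lo > k_tol:
        mid = 0.5 * (k_lo + k_hi)
        if min_fb(mid) > 0:
            k_lo = mid
        else:
            k_hi = mid
    return 0.5 * (k_lo + k_hi)
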