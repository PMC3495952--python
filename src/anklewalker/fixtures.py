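"""Canonical constants recomputed from first principles.

Every constant used across the test suite and documentation is
regenerated here by an *independent* brute-force oracle -- circle-circle
intersection for the linkage, bisection for angles and stiffness
thresholds, quadrature for work integrals -- rather than by the analytic
formulas under test.  The oracles deliberately avoid the package's
geometry/poincare closed forms so that agreement is evidence, not
tautology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .dynamics import HybridState, NumericsConfig, Termination, simulate_step
from .params import WalkerParams

__all__ = ["Fixtures", "make_fixtures", "psi_oracle"]


def psi_oracle(theta: float, params: WalkerParams) -> float:
    """Ankle angle by explicit circle-circle intersection (no law of cosines).

    Intersects the circle of radius l around the toe A with the circle
    of radius L around the mass C, picks the heel-lift branch, and
    measures the angle at the ankle D between the rays D->A and D->C.
    """
    a = 2 * params.L * math.sin(params.alpha) - params.l
    A = np.array([-a, 0.0])
    C = np.array([-params.L * math.sin(theta), params.L * math.cos(theta)])
    d = np.linalg.norm(C - A)
    l, L = params.l, params.L
    if d >= l + L:
        raise ValueError("no intersection: linkage singular")
    u = (l * l - L * L + d * d) / (2 * d)
    h = math.sqrt(max(l * l - u * u, 0.0))
    e = (C - A) / d
    n = np.array([-e[1], e[0]])  # +90 degree rotation: heel-lift side
    D = A + u * e + h * n
    v1 = A - D
    v2 = C - D
    cosang = float(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return math.acos(max(-1.0, min(1.0, cosang)))


@dataclass(frozen=True)
class Fixtures:
    """Independently recomputed canonical constants (standard parameters)."""

    a: float  # toe offset [m]
    psi0: float  # ankle angle at double-stance onset [rad]
    theta_f: float  # hip angle at toe-off [rad]
    spring_work: float  # ankle work per step W [J]
    c: float  # step-map constant 2W/(m L^2) [rad^2/s^2]
    v_C: float  # period-one pre-collision speed [m/s]
    theta_dot_star: float  # period-one post-collision angular velocity [rad/s]
    k_C: float  # just-vault-over stiffness [N*m/rad]
    pulse_amplitude: float  # 10% of peak spring torque [N*m]


def _vault_completes(k: float, base: WalkerParams, numerics: NumericsConfig) -> bool:
    """Does the period-one gait of stiffness k complete a step? (simulation oracle)"""
    p = base.with_(k=k)
    # fixed point from the energy balance, solved numerically:
    # 0.5*m*vC^2*(1 - cos^2 2a) = W(k)
    W = quad(lambda psi: k * (p.mu - psi), p.psi0, p.mu)[0]
    loss = 1 - math.cos(2 * p.alpha) ** 2
    vC = math.sqrt(2 * W / (p.m * loss))
    thd0 = -math.cos(2 * p.alpha) * vC / p.L
    res, _, _ = simulate_step(
        HybridState(theta=p.alpha, theta_dot=thd0), None, p, numerics
    )
    return res.termination is Termination.COMPLETED


def make_fixtures(params: WalkerParams | None = None) -> Fixtures:
    """Recompute the canonical constants with independent oracles."""
    p = params or WalkerParams()
    numerics = NumericsConfig()
    a = 2 * p.L * math.sin(p.alpha) - p.l
    psi0 = psi_oracle(p.alpha, p)
    theta_lo = brentq(
        lambda th: a * a + p.L * p.L - 2 * a * p.L * math.sin(th) - (p.l + p.L) ** 2,
        -p.alpha,
        p.alpha,
    )
    theta_f = brentq(
        lambda th: psi_oracle(th, p) - p.mu, theta_lo + 1e-9, p.alpha
    )
    W = quad(lambda psi: p.k * (p.mu - psi), psi0, p.mu)[0]
    c = 2 * W / (p.m * p.L**2)
    loss = 1 - math.cos(2 * p.alpha) ** 2
    v_C = math.sqrt(2 * W / (p.m * loss))
    thd_star = -math.cos(2 * p.alpha) * v_C / p.L
    # k_C oracle: bisection on simulated step completion
    k_lo, k_hi = 10.0, p.k
    assert not _vault_completes(k_lo, p, numerics)
    assert _vault_completes(k_hi, p, numerics)
    while k_hi - k_lo > 1e-4:
        mid = 0.5 * (k_lo + k_hi)
        if _vault_completes(mid, p, numerics):
            k_hi = mid
        else:
            k_lo = mid
    return Fixtures(
        a=a,
        psi0=psi0,
        theta_f=theta_f,
        spring_work=W,
        c=c,
        v_C=v_C,
        theta_dot_star=thd_star,
        k_C=0.5 * (k_lo + k_hi),
        pulse_amplitude=0.1 * p.k * (p.mu - psi0),
    )
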