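"""Double-stance four-bar-linkage kinematics.

During double stance the model is a four-bar linkage: ground, trailing
foot (toe A to ankle D, length ``l``), trailing leg (ankle D to point
mass C, length ``L``) and leading leg (point mass C to leading contact
B, length ``L``).  A single generalized coordinate -- the leading-leg
hip angle ``theta`` -- determines the whole configuration.

Coordinate convention (shared by all modules): the leading heel/ankle
contact B is the origin of each step, +x is the direction of travel and
+y is up.  ``theta`` is the angle of leg BC from the vertical, positive
while the mass is behind B; a step runs from ``theta = +alpha`` down to
``theta = -alpha`` with ``theta_dot < 0``.  The mass sits at
``C = (-L*sin(theta), L*cos(theta))`` and the trailing toe at
``A = (-a, 0)`` with toe offset ``a = 2*L*sin(alpha) - l``.

The ankle angle ``psi`` is the interior angle of triangle ADC at the
ankle D, positive toward plantar flexion; at double-stance onset (flat
trailing foot) ``psi = pi/2 - alpha``, and double stance ends when
``psi`` reaches the maximal plantar-flexion angle ``mu``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import WalkerParams

__all__ = [
    "LinkageState",
    "LinkageSingularityError",
    "toe_offset",
    "ankle_angle",
    "linkage_state",
    "line_angle_phi",
    "dpsi_dtheta",
    "double_stance_end_angle",
    "singular_theta",
    "extension_cap_angle",
    "ankle_spring_torque",
]


class LinkageSingularityError(ValueError):
    """The four-bar linkage is at (or past) its singular configuration.

    The singularity occurs when the trailing foot and leg align,
    ``|AC| = l + L`` i.e. ``psi = pi``; beyond it the triangle ADC
    cannot close.
    """


@dataclass(frozen=True)
class LinkageState:
    """Four-bar configuration at a given hip angle.

    Attributes
    ----------
    theta : float
        Hip angle of the leading leg from vertical [rad].
    psi : float
        Trailing-ankle angle (interior angle of ADC at D) [rad].
    phi : float
        Angle of the line from trailing toe A to mass C above the
        horizontal [rad].
    D : tuple[float, float]
        Planar coordinates of the trailing ankle [m].
    AC : float
        Distance from trailing toe A to the point mass C [m].
    dpsi_dtheta : float
        Derivative of psi with respect to theta (dimensionless,
        negative on the double-stance range).
    """

    theta: float
    psi: float
    phi: float
    D: tuple[float, float]
    AC: float
    dpsi_dtheta: float


def toe_offset(params: WalkerParams) -> float:
    """Horizontal distance from the leading heel back to the trailing toe [m].

    The previous stance foot lies flat with its ankle at the old contact
    point, 2*L*sin(alpha) behind the new one, and its toe l ahead of
    that, so ``a = 2*L*sin(alpha) - l``.
    """
    a = 2 * params.L * math.sin(params.alpha) - params.l
    if a <= 0:
        raise ValueError("toe offset non-positive: foot longer than the step")
    return a


def _ac_squared(theta: float, params: WalkerParams) -> float:
    a, L = params.toe_offset, params.L
    return a * a + L * L - 2 * a * L * math.sin(theta)


def ankle_angle(theta: float, params: WalkerParams) -> float:
    """Trailing-ankle angle psi at hip angle theta [rad].

    From the law of cosines in triangle ADC with ``|AD| = l``,
    ``|DC| = L`` and ``AC^2 = a^2 + L^2 - 2*a*L*sin(theta)``:
    ``psi = arccos[(l^2 + L^2 - AC^2) / (2*l*L)]``.  The arccos branch
    is the one continuous with the flat-foot configuration at
    ``theta = alpha`` (heel lifting, ankle above ground).

    Raises
    ------
    LinkageSingularityError
        If ``AC >= l + L`` (psi would reach pi); this happens for theta
        below :func:`singular_theta`.
    """
    l, L = params.l, params.L
    ac2 = _ac_squared(theta, params)
    c = (l * l + L * L - ac2) / (2 * l * L)
    if c <= -1.0:
        raise LinkageSingularityError(
            f"linkage singular at theta={theta:.6g}: AC={math.sqrt(ac2):.6g} "
            f">= l + L = {l + L:.6g}"
        )
    return math.acos(min(c, 1.0))


def line_angle_phi(theta: float, params: WalkerParams) -> float:
    """Angle of the line from trailing toe A to the mass C above horizontal [rad]."""
    a, L = params.toe_offset, params.L
    return math.atan2(L * math.cos(theta), a - L * math.sin(theta))


def dpsi_dtheta(theta: float, params: WalkerParams) -> float:
    """Derivative of the ankle angle with respect to the hip angle.

    Differentiating the two expressions for AC^2 (law of cosines at D
    and at the contact line) gives
    ``dpsi/dtheta = -a*cos(theta) / (l*sin(psi))``, negative on the
    double-stance range: plantar flexion increases as the body advances.
    """
    psi = ankle_angle(theta, params)
    s = math.sin(psi)
    if s < 1e-12:
        raise LinkageSingularityError(f"dpsi/dtheta singular: psi={psi:.6g} near pi")
    return -params.toe_offset * math.cos(theta) / (params.l * s)


def _ankle_position(theta: float, params: WalkerParams) -> tuple[float, float]:
    """Trailing-ankle coordinates: intersection of circles around A (radius l) and C (radius L).

    Of the two intersections, take the one continuous with the flat-foot
    configuration (positive cross product of A->C with A->D, i.e. the
    heel-lift branch with the ankle at non-negative height).
    """
    a, l, L = params.toe_offset, params.l, params.L
    ax, ay = -a, 0.0
    cx, cy = -L * math.sin(theta), L * math.cos(theta)
    dx, dy = cx - ax, cy - ay
    d2 = dx * dx + dy * dy
    d = math.sqrt(d2)
    if d >= l + L:
        raise LinkageSingularityError(f"linkage singular at theta={theta:.6g}")
    # foot of perpendicular from the intersection chord onto line AC
    u = (l * l - L * L + d2) / (2 * d)
    h2 = l * l - u * u
    h = math.sqrt(max(h2, 0.0))
    px, py = ax + u * dx / d, ay + u * dy / d
    # left-of-AC branch: rotate the unit chord direction by +90 degrees
    return (px - h * dy / d, py + h * dx / d)


def linkage_state(theta: float, params: WalkerParams) -> LinkageState:
    """Full four-bar configuration at hip angle theta."""
    return LinkageState(
        theta=theta,
        psi=ankle_angle(theta, params),
        phi=line_angle_phi(theta, params),
        D=_ankle_position(theta, params),
        AC=math.sqrt(_ac_squared(theta, params)),
        dpsi_dtheta=dpsi_dtheta(theta, params),
    )


def double_stance_end_angle(params: WalkerParams) -> float:
    """Hip angle theta_f at which the ankle angle reaches mu (toe-off).

    Equating the two law-of-cosines forms of AC^2 at psi = mu gives
    ``sin(theta_f) = (a^2 - l^2 + 2*l*L*cos(mu)) / (2*a*L)``.
    """
    a, l, L, mu = params.toe_offset, params.l, params.L, params.mu
    s = (a * a - l * l + 2 * l * L * math.cos(mu)) / (2 * a * L)
    if not -1.0 <= s <= 1.0:
        raise ValueError(
            f"no double-stance end angle: sin(theta_f)={s:.6g} outside [-1, 1]"
        )
    theta_f = math.asin(s)
    if not -params.alpha < theta_f < params.alpha:
        raise ValueError(
            f"double-stance end angle theta_f={theta_f:.6g} outside (-alpha, alpha)"
        )
    return theta_f


def singular_theta(params: WalkerParams) -> float:
    """Hip angle below which the linkage is singular (AC = l + L, psi = pi)."""
    a, l, L = params.toe_offset, params.l, params.L
    s = (a * a + L * L - (l + L) ** 2) / (2 * a * L)
    if s < -1.0:
        return -math.inf  # linkage never singular on the step range
    return math.asin(min(s, 1.0))


def extension_cap_angle(params: WalkerParams, eps_cap: float = 0.01) -> float:
    """Hip angle at which psi = pi - eps_cap (forced toe-off cap for extended double stance)."""
    a, l, L = params.toe_offset, params.l, params.L
    s = (a * a - l * l + 2 * l * L * math.cos(math.pi - eps_cap)) / (2 * a * L)
    if not -1.0 <= s <= 1.0:
        raise ValueError("extension cap angle does not exist for these parameters")
    return math.asin(s)


def ankle_spring_torque(psi, params: WalkerParams):
    """Plantar ankle torque of the trailing-leg spring, T = k*(mu - psi) for psi <= mu, else 0.

    The spring is cocked to deflection ``mu - psi`` and releases during
    double stance; once psi reaches mu the released spring does not pull
    back.  Accepts scalars or arrays.
    """
    psi = np.asarray(psi, dtype=float)
    T = np.where(psi <= params.mu, params.k * (params.mu - psi), 0.0)
    return float(T) if T.ndim == 0 else T


def geometry_table(params: WalkerParams, thetas) -> "np.ndarray":
    """Tabulate (theta, psi, phi, dpsi_dtheta, AC) over a grid of hip angles."""
    rows = []
    for th in np.asarray(thetas, dtype=float):
        rows.append(
            (
                th,
                ankle_angle(th, params),
                line_angle_phi(th, params),
                dpsi_dtheta(th, params),
                math.sqrt(_ac_squared(th, params)),
            )
        )
    return np.array(rows)
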