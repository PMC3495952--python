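"""Morphological and actuation constants of the walking model.

The model is a point mass ``m`` on rigid massless legs of length ``L``
(hip to ankle), with feet of length ``l`` (ankle to toe).  The trailing
ankle is actuated by a pre-loaded ("cocked") torsional spring of
stiffness ``k`` that releases during double stance and goes slack once
the ankle angle reaches the maximal plantar-flexion angle ``mu``.  The
inter-leg angle is reset to ``2*alpha`` at every heel strike.

Default values approximate adult human morphology and a peak plantar
flexion torque of 17% of body weight times leg length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Any, Mapping


@dataclass(frozen=True)
class WalkerParams:
    """Constant parameters of the ankle-actuated walker (SI units).

    Attributes
    ----------
    m : float
        Body mass [kg] (point mass at the hip).
    L : float
        Leg length, hip to ankle [m].
    l : float
        Foot length, ankle to toe [m].
    g : float
        Gravitational acceleration [m/s^2].
    alpha : float
        Half the inter-leg angle at heel strike [rad].  The stance-leg
        hip angle runs from ``+alpha`` to ``-alpha`` over one step.
    mu : float
        Maximal plantar-flexion angle of the ankle [rad]; the spring
        torque vanishes when the ankle angle reaches ``mu``.
    k : float
        Ankle actuation (torsional spring) stiffness [N*m/rad].
    """

    m: float = 80.0
    L: float = 1.0
    l: float = 0.2
    g: float = 9.81
    alpha: float = math.pi / 6
    mu: float = 2.576
    k: float = 87.3

    def __post_init__(self) -> None:
        for name in ("m", "L", "l", "g", "alpha", "mu", "k"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be a finite positive number, got {v!r}")
        if not self.alpha < math.pi / 2:
            raise ValueError(f"alpha must lie in (0, pi/2), got {self.alpha}")
        if not self.l < 2 * self.L * math.sin(self.alpha):
            raise ValueError(
                "foot too long for the step: need l < 2*L*sin(alpha) so the "
                "trailing toe lies behind the leading heel "
                f"(l={self.l}, 2*L*sin(alpha)={2 * self.L * math.sin(self.alpha):.6g})"
            )
        if not self.mu > math.pi / 2 - self.alpha:
            raise ValueError(
                "spring not cocked at double-stance onset: need "
                f"mu > pi/2 - alpha = {math.pi / 2 - self.alpha:.6g}, got mu={self.mu}"
            )
        if not self.mu < math.pi:
            raise ValueError(f"mu must be < pi (non-degenerate linkage), got {self.mu}")
        a = self.toe_offset
        if not 0 < a < self.l + self.L:
            raise ValueError(f"derived toe offset a={a:.6g} outside (0, l+L)")

    @property
    def toe_offset(self) -> float:
        """Horizontal distance a = 2*L*sin(alpha) - l from leading heel back to trailing toe [m]."""
        return 2 * self.L * math.sin(self.alpha) - self.l

    @property
    def step_length(self) -> float:
        """Distance travelled per step, 2*L*sin(alpha) [m]."""
        return 2 * self.L * math.sin(self.alpha)

    @property
    def psi0(self) -> float:
        """Ankle angle at double-stance onset (trailing foot flat): pi/2 - alpha [rad]."""
        return math.pi / 2 - self.alpha

    @property
    def peak_spring_torque(self) -> float:
        """Spring torque at double-stance onset, k*(mu - psi0) [N*m]."""
        return self.k * (self.mu - self.psi0)

    def with_(self, **changes: Any) -> "WalkerParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **changes)

    @classmethod
    def from_mapping(cls, block: Mapping[str, Any] | None) -> "WalkerParams":
        """Build parameters from a config mapping; omitted fields keep defaults."""
        block = dict(block or {})
        known = {"m", "L", "l", "g", "alpha", "mu", "k"}
        unknown = set(block) - known
        if unknown:
            raise ValueError(f"unknown model parameter(s): {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in block.items()})


def calibrated_stiffness(
    params: WalkerParams, torque_fraction: float = 0.17
) -> float:
    """Stiffness that sets the peak (double-stance-onset) spring torque.

    Human gait data put the peak plantar-flexion torque near 17% of body
    weight times leg length.  The spring is maximally deflected at
    double-stance onset, where the ankle angle is ``psi0``, so the
    matching stiffness is ``torque_fraction*m*g*L / (mu - psi0)``.
    """
    target = torque_fraction * params.m * params.g * params.L
    return target / (params.mu - params.psi0)
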