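"""Closed-form single-rigid-body fall over a wall edge.

The body is idealized as a uniform parallelepiped of mass ``m`` and height
``l`` translating horizontally at speed ``v_i`` until its lower end strikes
a fixed edge (a wall top).  The problem splits into two phases.

Impact phase — conservation of angular momentum about the impact point P,

    m v_i b = I omega + m v_f b,

with Newton's restitution at the contact point, v_Pf = e v_Pi (and v_Pi =
v_i since pre-impact motion is translational), and omega = (v_f + v_Pf)/b,
yields the post-impact centre-of-mass speed

    v_f = v_i (m b^2 - e I) / (m b^2 + I),

where ``b`` is the CoM-to-P distance and I = m l^2 / 12 the central
inertia of a slender body.

Ballistic phase — the CoM flies as a projectile,

    s_x = v_0x t,      s_y = -(1/2) g t^2 + s_0y,

with v_0x = v_f, while the body rotates at the constant post-impact rate
omega; the accumulated rotation at landing is upsilon = omega t.

Coordinates: origin at the impact point, x horizontal along travel, y up.
All internal computation is unrounded; the report layer in
:mod:`forensicbiomech.scenarios` reproduces display rounding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DomainError

__all__ = [
    "GRAVITY",
    "RigidBodySpec",
    "BallisticLanding",
    "FallPrediction",
    "post_impact_velocity",
    "post_impact_angular_velocity",
    "ballistic_range_at",
    "rotation_at_landing",
    "predict_fall",
    "sample_trajectory",
]

#: Standard gravity, m/s^2.
GRAVITY = 9.81


@dataclass(frozen=True)
class RigidBodySpec:
    """Rigid parallelepiped body: mass m (kg), height l (m), CoM-to-impact
    distance b (m), central inertia I (kg m^2; slender-body m l^2/12 when
    omitted)."""

    m: float
    l: float
    b: float | None = None
    I: float | None = None

    def __post_init__(self):
        if self.m <= 0 or self.l <= 0:
            raise DomainError("mass and height must be strictly positive")
        if self.b is None:
            object.__setattr__(self, "b", self.l / 2)
        # b = l/2 for a uniform body struck at its end; composite bodies with
        # an off-centre CoM may have b up to l
        if self.b <= 0 or self.b > self.l + 1e-12:
            raise DomainError("impact arm b must satisfy 0 < b <= l for an end impact")
        if self.I is None:
            object.__setattr__(self, "I", self.m * self.l**2 / 12)
        if self.I < 0:
            raise DomainError("inertia must be non-negative")


def _check_impact_inputs(v_i: float, e: float) -> None:
    if v_i < 0:
        raise DomainError("pre-impact speed must be non-negative")
    if not 0 <= e <= 1:
        raise DomainError("coefficient of restitution must lie in [0, 1]")


def post_impact_velocity(body: RigidBodySpec, v_i: float, e: float) -> float:
    """Post-impact CoM speed v_f = v_i (m b^2 - e I)/(m b^2 + I)."""
    _check_impact_inputs(v_i, e)
    mb2 = body.m * body.b**2
    return v_i * (mb2 - e * body.I) / (mb2 + body.I)


def post_impact_angular_velocity(body: RigidBodySpec, v_i: float, e: float) -> float:
    """Post-impact angular speed omega = (v_f + e v_i)/b, with unrounded v_f."""
    _check_impact_inputs(v_i, e)
    if body.b == 0:  # pragma: no cover - excluded by RigidBodySpec validation
        raise DomainError("singular geometry: b = 0")
    v_f = post_impact_velocity(body, v_i, e)
    return (v_f + e * v_i) / body.b


@dataclass(frozen=True)
class BallisticLanding:
    """Horizontal range and flight time of the ballistic phase."""

    s_x: float
    t: float


def ballistic_range_at(
    s_y_target: float, v_0x: float, s_0y: float, g: float = GRAVITY
) -> BallisticLanding:
    """Range and time at which the CoM parabola reaches ordinate ``s_y_target``.

    s_x = v_0x sqrt(2 (s_0y - s_y_target) / g);  t = s_x / v_0x.
    """
    if s_y_target >= s_0y:
        raise DomainError("target ordinate must lie below the initial ordinate")
    if v_0x <= 0:
        raise DomainError("initial horizontal speed must be positive")
    if g <= 0:
        raise DomainError("gravity must be positive")
    t = math.sqrt(2 * (s_0y - s_y_target) / g)
    return BallisticLanding(s_x=v_0x * t, t=t)


def rotation_at_landing(omega: float, t: float) -> tuple[float, float]:
    """Accumulated rotation upsilon = omega t, returned as (radians, degrees)."""
    if t < 0:
        raise DomainError("time must be non-negative")
    upsilon = omega * t
    return upsilon, math.degrees(upsilon)


@dataclass(frozen=True)
class FallPrediction:
    """Composite two-phase prediction (all values unrounded)."""

    v_f: float  # post-impact CoM speed, m/s
    omega: float  # post-impact angular speed, rad/s
    s_x: float  # horizontal range at landing, m
    t: float  # flight time, s
    upsilon: float  # accumulated rotation at landing, rad
    upsilon_deg: float  # ditto, degrees


def predict_fall(
    body: RigidBodySpec,
    v_i: float,
    e: float,
    s_y_target: float,
    s_0y: float | None = None,
    g: float = GRAVITY,
) -> FallPrediction:
    """Run both phases: wall-edge impact, then ballistic flight to the target
    ordinate.  ``s_0y`` defaults to ``body.b`` (CoM starts one impact arm
    above the impact point)."""
    if s_0y is None:
        s_0y = body.b
    v_f = post_impact_velocity(body, v_i, e)
    omega = post_impact_angular_velocity(body, v_i, e)
    if v_i == 0 or v_f == 0:
        # No horizontal motion: the body does not clear the edge, nothing to
        # predict downstream of the impact.
        return FallPrediction(v_f=v_f, omega=omega, s_x=0.0, t=0.0, upsilon=0.0, upsilon_deg=0.0)
    landing = ballistic_range_at(s_y_target, v_f, s_0y, g)
    upsilon, upsilon_deg = rotation_at_landing(omega, landing.t)
    return FallPrediction(
        v_f=v_f, omega=omega, s_x=landing.s_x, t=landing.t,
        upsilon=upsilon, upsilon_deg=upsilon_deg,
    )


def sample_trajectory(
    prediction: FallPrediction,
    s_0y: float,
    g: float = GRAVITY,
    n: int = 100,
) -> np.ndarray:
    """Sample the ballistic phase on ``n`` time points.

    Returns an array of shape (n, 4) with columns (t, s_x, s_y, upsilon)."""
    if n < 2:
        raise DomainError("need at least two sample points")
    t = np.linspace(0.0, prediction.t, n)
    s_x = prediction.v_f * t
    s_y = -0.5 * g * t**2 + s_0y
    upsilon = prediction.omega * t
    return np.column_stack([t, s_x, s_y, upsilon])
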