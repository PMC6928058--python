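"""Free-body-diagram lever model of the calf-to-talus force chain.

When a tire presses on the calf, the tibia acts as a lever hinged at the
ankle joint O (the curvature centre of the tibia–talus mating surface).
Torque equilibrium of the tibia about O,

    F * b - f * h = 0,

relates the calf force ``F`` (moment arm ``b``) to the contact force ``f``
at the tibia–talus interface (moment arm ``h``), so f = F * (b/h): the
mechanism amplifies the applied force by b/h.  Dividing ``f`` by the small
tibia–talus contact patch yields the compressive stress on the talus neck,
which is how a pressure too low to mark the calf can still fracture the
talus.

Units contract: pressures in MPa, areas in mm^2, forces in N — chosen so
MPa x mm^2 = N with no conversion factors.  All chained computations are
unrounded; display rounding belongs to the report layer.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DomainError, SingularMechanismError

__all__ = [
    "LeverMechanism",
    "ContactPatch",
    "TireSpec",
    "InjuryChainResult",
    "amplification_factor",
    "talus_force",
    "pressure_to_force",
    "contact_stress",
    "tire_outer_diameter",
    "calf_injury_chain",
]

MM_PER_INCH = 25.4


@dataclass(frozen=True)
class LeverMechanism:
    """Ankle lever: moment arm ``b`` of the calf force and ``h`` of the
    tibia–talus interface force, both about the ankle hinge O, in metres."""

    b: float
    h: float

    def __post_init__(self):
        if self.b <= 0 or self.h <= 0:
            raise DomainError("lever arms b and h must be strictly positive")


@dataclass(frozen=True)
class ContactPatch:
    """Rectangular contact patch, dimensions in millimetres."""

    width: float
    height: float

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise DomainError("patch dimensions must be strictly positive")

    @property
    def area(self) -> float:
        """Patch area in mm^2."""
        return self.width * self.height


@dataclass(frozen=True)
class TireSpec:
    """Tire size code ``width/aspect/rim``: section width in mm, aspect
    ratio as % of width, rim diameter in inches."""

    section_width: float
    aspect_ratio: float
    rim_diameter: float

    def __post_init__(self):
        if self.section_width <= 0 or self.aspect_ratio <= 0 or self.rim_diameter <= 0:
            raise DomainError("tire dimensions must be strictly positive")
        if self.aspect_ratio > 100:
            raise DomainError("aspect ratio cannot exceed 100% of section width")

    @classmethod
    def from_code(cls, code: str) -> "TireSpec":
        """Parse a ``215/55/17`` (or ``215/55R17``) style size code."""
        parts = code.replace("R", "/").replace("r", "/").split("/")
        if len(parts) != 3:
            raise DomainError(f"cannot parse tire code {code!r}")
        return cls(float(parts[0]), float(parts[1]), float(parts[2]))


def amplification_factor(mech: LeverMechanism) -> float:
    """Force amplification b/h of the ankle lever (dimensionless)."""
    if mech.h == 0:  # pragma: no cover - excluded by LeverMechanism validation
        raise SingularMechanismError("interface arm h is zero")
    return mech.b / mech.h


def talus_force(F: float, mech: LeverMechanism) -> float:
    """Force f on the talus neck from calf force F: f = F*b/h (N).

    Satisfies the torque balance F*b - f*h = 0 exactly.
    """
    if F < 0:
        raise DomainError("calf force must be non-negative")
    return F * amplification_factor(mech)


def pressure_to_force(p: float, patch: ContactPatch) -> float:
    """Resultant force (N) of a uniform pressure p (MPa) on a patch (mm^2)."""
    if p < 0:
        raise DomainError("pressure must be non-negative")
    return p * patch.area


def contact_stress(force: float, patch: ContactPatch) -> float:
    """Mean compressive stress (MPa) of a force (N) on a patch (mm^2)."""
    if force < 0:
        raise DomainError("force must be non-negative")
    if patch.area == 0:  # pragma: no cover - excluded by ContactPatch validation
        raise SingularMechanismError("degenerate contact patch of zero area")
    return force / patch.area


def tire_outer_diameter(spec: TireSpec) -> float:
    """Overall tire diameter in mm, rounded to the nearest millimetre.

    rim (in -> mm) plus two sidewall heights, each aspect_ratio% of the
    section width.
    """
    exact = spec.rim_diameter * MM_PER_INCH + 2 * (spec.aspect_ratio / 100) * spec.section_width
    return float(round(exact))


@dataclass(frozen=True)
class InjuryChainResult:
    """Unrounded results of the calf-to-talus chain."""

    calf_force: float  # N
    talus_force: float  # N
    talus_stress: float  # MPa


def calf_injury_chain(
    p: float,
    calf_patch: ContactPatch,
    mech: LeverMechanism,
    talus_patch: ContactPatch,
) -> InjuryChainResult:
    """Full chain: pressure on the calf -> calf force -> amplified talus
    force -> stress on the talus neck, with no intermediate rounding."""
    F = pressure_to_force(p, calf_patch)
    f = talus_force(F, mech)
    return InjuryChainResult(
        calf_force=F, talus_force=f, talus_stress=contact_stress(f, talus_patch)
    )
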