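"""Anthropometric mannequin construction from segment-proportion tables.

A human body is modelled as nine rigid segments (head+neck+trunk, and left/
right upper arm, forearm+hand, thigh, lower leg+foot) whose lengths are fixed
fractions of stature and whose masses are fixed fractions of total body mass,
after the classical stature/mass-fraction anthropometric models.  Compound
segments (e.g. forearm+hand) are realized constituent by constituent, each
constituent rounded to the table's printed precision (3 decimals for metres,
2 for kilograms) before summation — the convention the source tables
themselves follow.  Rounding is half-down on exact decimal arithmetic, the
single rule that reproduces the largest number of published table cells;
the handful of published cells no rule can reproduce are treated as typos
(see docs/methods.md).

Segment inertia uses the uniform slender-rod model, I = m l^2 / 12 about the
segment centroid, with the centroid at the segment midpoint.

The module also answers the geometric reach question that arises in
workplace-accident analysis: can a fingertip, at the end of an outstretched
arm, reach a device at a given distance from the shoulder?
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_DOWN
from functools import lru_cache
from importlib import resources
from pathlib import Path

from .errors import DomainError, InvalidTableError, StructuralError

__all__ = [
    "SEGMENT_NAMES",
    "WIDTH_NAMES",
    "SegmentFractions",
    "ProportionTable",
    "Segment",
    "Mannequin",
    "ReachabilityResult",
    "load_table",
    "builtin_tables",
    "build_mannequin",
    "arm_reach",
    "reachability_check",
]

#: Canonical names of the nine body segments, trunk first.
SEGMENT_NAMES = (
    "head_neck_trunk",
    "left_upper_arm",
    "left_forearm_hand",
    "left_thigh",
    "left_lower_leg_foot",
    "right_upper_arm",
    "right_forearm_hand",
    "right_thigh",
    "right_lower_leg_foot",
)

#: Body widths carried alongside the segment lengths, as % of stature.
WIDTH_NAMES = ("shoulder_width", "hip_bone_width", "foot_length", "foot_breadth")


def _round_half_down(value: Decimal, ndigits: int) -> float:
    """Round an exact decimal value half-down to ``ndigits`` decimals."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(value.quantize(quantum, rounding=ROUND_HALF_DOWN))


@dataclass(frozen=True)
class SegmentFractions:
    """Constituent fractions of one (possibly compound) body segment.

    ``length_components`` are % of stature; ``mass_components`` are % of
    total body mass, or ``None`` for a geometry-only table.
    """

    length_components: tuple[float, ...]
    mass_components: tuple[float, ...] | None = None

    def __post_init__(self):
        if not self.length_components or any(c <= 0 for c in self.length_components):
            raise InvalidTableError("length fractions must be strictly positive")
        if self.mass_components is not None and (
            not self.mass_components or any(c <= 0 for c in self.mass_components)
        ):
            raise InvalidTableError("mass fractions must be strictly positive")

    @property
    def length_fraction(self) -> float:
        """Total segment length as % of stature."""
        return float(sum(Decimal(str(c)) for c in self.length_components))

    @property
    def mass_fraction(self) -> float | None:
        """Total segment mass as % of body mass, or None if geometry-only."""
        if self.mass_components is None:
            return None
        return float(sum(Decimal(str(c)) for c in self.mass_components))


@dataclass(frozen=True)
class ProportionTable:
    """Per-segment length/mass fractions plus body widths (% of stature)."""

    entries: dict[str, SegmentFractions]
    widths: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        unknown = set(self.entries) - set(SEGMENT_NAMES)
        if unknown:
            raise InvalidTableError(f"unknown segments in table: {sorted(unknown)}")
        missing = set(SEGMENT_NAMES) - set(self.entries)
        if missing:
            raise InvalidTableError(f"table lacks segments: {sorted(missing)}")
        if any(w <= 0 for w in self.widths.values()):
            raise InvalidTableError("widths must be strictly positive")
        if self.has_masses:
            if any(e.mass_components is None for e in self.entries.values()):
                raise InvalidTableError(
                    "mass-bearing tables must give a mass fraction for every segment"
                )
            total = sum(e.mass_fraction for e in self.entries.values())
            if abs(total - 100.0) > 0.1:
                raise InvalidTableError(
                    f"segment mass fractions sum to {total}, expected 100.0 +/- 0.1"
                )

    @property
    def has_masses(self) -> bool:
        """True when at least one segment carries a mass fraction."""
        return any(e.mass_components is not None for e in self.entries.values())


def _parse_table(text: str, source: str = "<string>") -> ProportionTable:
    entries: dict[str, SegmentFractions] = {}
    widths: dict[str, float] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tokens = line.split()
        try:
            kind = tokens[0]
            if kind == "segment":
                name = tokens[1]
                if tokens[2] != "length":
                    raise ValueError("expected 'length' after segment name")
                rest = tokens[3:]
                length: list[float] = []
                mass: list[float] | None = None
                target = length
                for tok in rest:
                    if tok == "mass":
                        mass = []
                        target = mass
                    else:
                        target.append(float(tok))
                entries[name] = SegmentFractions(
                    tuple(length), tuple(mass) if mass is not None else None
                )
            elif kind == "width":
                widths[tokens[1]] = float(tokens[2])
            else:
                raise ValueError(f"unknown directive {kind!r}")
        except (IndexError, ValueError) as exc:
            raise InvalidTableError(f"{source}:{lineno}: cannot parse {raw!r}: {exc}") from exc
    return ProportionTable(entries=entries, widths=widths)


def load_table(path: str | Path) -> ProportionTable:
    """Load a proportion table from the simple key/value text format.

    The format is line oriented: ``segment <name> length <f...> [mass <g...>]``
    and ``width <name> <fraction>``; ``#`` starts a comment.
    """
    path = Path(path)
    return _parse_table(path.read_text(), source=str(path))


@lru_cache(maxsize=None)
def builtin_tables() -> dict[str, ProportionTable]:
    """Return the two built-in tables keyed ``table_1_6m`` and ``table_1_75m``.

    Both share identical length fractions; only ``table_1_75m`` carries mass
    fractions.  The keys record the statures the tables were originally used
    at (a 1.6 m geometry-only subject and a 1.75 m / 75 kg subject); either
    table can be applied to any stature.
    """
    pkg = resources.files(__package__) / "data"
    return {
        "table_1_6m": _parse_table(
            (pkg / "proportions_geometry.txt").read_text(), "proportions_geometry.txt"
        ),
        "table_1_75m": _parse_table(
            (pkg / "proportions_full.txt").read_text(), "proportions_full.txt"
        ),
    }


@dataclass(frozen=True)
class Segment:
    """One realized rigid body segment.

    ``mass`` is 0 for geometry-only builds; ``inertia_com`` is the slender-rod
    central inertia m l^2/12 (0 when massless).
    """

    name: str
    length: float
    mass: float = 0.0
    inertia_com: float = 0.0

    def __post_init__(self):
        if self.length < 0 or self.mass < 0:
            raise DomainError("segment length and mass must be non-negative")


@dataclass(frozen=True)
class Mannequin:
    """A realized mannequin: segments in metres/kilograms plus body widths."""

    stature: float
    total_mass: float
    segments: tuple[Segment, ...]
    widths: dict[str, float] = field(default_factory=dict)

    def segment(self, name: str) -> Segment:
        for seg in self.segments:
            if seg.name == name:
                return seg
        raise StructuralError(f"mannequin has no segment {name!r}")

    @property
    def has_masses(self) -> bool:
        """True for a mass-bearing (dynamics-capable) build."""
        return self.total_mass > 0

    def to_report(self) -> dict:
        """Flat JSON-serializable report: per-segment name/length/mass/inertia."""
        return {
            "stature_m": self.stature,
            "total_mass_kg": self.total_mass,
            "segments": [
                {
                    "name": s.name,
                    "length_m": s.length,
                    "mass_kg": s.mass,
                    "inertia_com_kg_m2": s.inertia_com,
                }
                for s in self.segments
            ],
            "widths_m": dict(self.widths),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_report(), **kwargs)


def build_mannequin(
    stature: float,
    total_mass: float | None = None,
    table: ProportionTable | None = None,
    *,
    rounded: bool = True,
) -> Mannequin:
    """Realize a mannequin of given stature (and optionally mass) from a table.

    Each constituent fraction is converted to metres (or kilograms) and
    rounded to the table's printed precision — 3 decimals for lengths, 2 for
    masses — before constituents are summed into the compound segment, the
    convention of the published tables.  Pass ``rounded=False`` for exact
    (unrounded) realization, e.g. to verify scale equivariance.

    Parameters
    ----------
    stature : float
        Body height in metres; must be positive.
    total_mass : float, optional
        Body mass in kilograms.  Omit for a geometry-only build (mass and
        inertia fields are then zero).  Requires a mass-bearing table.
    table : ProportionTable, optional
        Defaults to the built-in mass-bearing table.
    """
    if stature <= 0:
        raise DomainError("stature must be positive")
    if total_mass is not None and total_mass <= 0:
        raise DomainError("total_mass must be positive when supplied")
    if table is None:
        table = builtin_tables()["table_1_75m"]
    if total_mass is not None and not table.has_masses:
        raise InvalidTableError("geometry-only table cannot realize masses")

    dec_stature = Decimal(str(stature))
    dec_mass = Decimal(str(total_mass)) if total_mass is not None else None

    segments = []
    for name in SEGMENT_NAMES:
        fr = table.entries[name]
        if rounded:
            length = float(
                sum(
                    Decimal(str(_round_half_down(Decimal(str(c)) * dec_stature / 100, 3)))
                    for c in fr.length_components
                )
            )
        else:
            length = sum(c for c in fr.length_components) * stature / 100
        mass = 0.0
        if dec_mass is not None:
            comps = fr.mass_components
            if comps is None:  # pragma: no cover - table validation excludes this
                raise InvalidTableError(f"segment {name!r} lacks a mass fraction")
            if rounded:
                mass = float(
                    sum(
                        Decimal(str(_round_half_down(Decimal(str(c)) * dec_mass / 100, 2)))
                        for c in comps
                    )
                )
            else:
                mass = sum(comps) * total_mass / 100
        inertia = mass * length**2 / 12
        segments.append(Segment(name=name, length=length, mass=mass, inertia_com=inertia))

    widths = {}
    for wname, wfrac in table.widths.items():
        if rounded:
            widths[wname] = _round_half_down(Decimal(str(wfrac)) * dec_stature / 100, 3)
        else:
            widths[wname] = wfrac * stature / 100

    return Mannequin(
        stature=stature,
        total_mass=float(total_mass) if total_mass is not None else 0.0,
        segments=tuple(segments),
        widths=widths,
    )


def arm_reach(mannequin: Mannequin, side: str = "left") -> float:
    """Shoulder-to-fingertip reach: upper-arm length + forearm+hand length."""
    if side not in ("left", "right"):
        raise DomainError(f"side must be 'left' or 'right', got {side!r}")
    upper = mannequin.segment(f"{side}_upper_arm")
    fore = mannequin.segment(f"{side}_forearm_hand")
    return upper.length + fore.length


@dataclass(frozen=True)
class ReachabilityResult:
    """Verdict of a reach check.  ``margin`` = target distance − reach;
    positive margin means the target is out of range by that much."""

    reachable: bool
    margin: float


def reachability_check(reach: float, target_distance: float) -> ReachabilityResult:
    """Can a fingertip at ``reach`` metres touch a target at ``target_distance``?"""
    if reach < 0 or target_distance < 0:
        raise DomainError("reach and target distance must be non-negative")
    return ReachabilityResult(
        reachable=reach >= target_distance, margin=target_distance - reach
    )
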