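"""Executable case scenarios, parameter sweeps, and report generation.

Three reference scenarios ship with the toolkit, mirroring the worked
court cases the models were built for:

- ``finishing-oven``  a 1.6 m worker with one arm trapped in a roller
  line; can the free arm reach an emergency device 1.1 m from the
  shoulder?
- ``pedestrian-hit``  a car tire (215/55/17) pressing on a pedestrian's
  calf with seated-buttock pressure (0.03 MPa); what stress reaches the
  talus neck through the ankle lever (b = 0.129 m, h = 0.018 m)?
- ``wall-fall``       a 75 kg, 1.75 m man falling over a low wall with a
  3 m drop; closed-form rigid-body reconstruction plus the multibody
  simulator at walking speeds 0.5-2 m/s.

Reports are pure functions of their configuration (no timestamps), so
re-running a case yields identical JSON.  ``paper_rounding`` switches the
report layer to the display precision of the original worked chains
(intermediate values re-rounded before reuse); computation is always
unrounded internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

from . import anthropometry, lever_mechanics, multibody_fall, rigid_fall
from .errors import DomainError

__all__ = [
    "CASE_IDS",
    "CaseConfig",
    "SweepSpec",
    "paper_case",
    "run_case",
    "generate_sweep",
]

CASE_IDS = ("finishing-oven", "pedestrian-hit", "wall-fall")

_DEFAULTS: dict[str, dict[str, Any]] = {
    "finishing-oven": {
        "stature": 1.6,
        "device_distance": 1.1,
        "side": "left",
        "table": "table_1_6m",
    },
    "pedestrian-hit": {
        "pressure": 0.03,  # MPa, seated-buttock reference
        "seat_weight": 600.0,  # N, trunk+arms+head on a chair
        "seat_patch": (100.0, 200.0),  # mm
        "calf_patch": (70.0, 70.0),  # mm
        "lever_b": 0.129,  # m
        "lever_h": 0.018,  # m
        "talus_patch": (5.0, 12.0),  # mm
        "tire": "215/55/17",
    },
    "wall-fall": {
        "mass": 75.0,
        "stature": 1.75,
        "impact_arm": 0.875,  # m, CoM to impact point
        "restitution": 0.5,
        "speed": 0.5,  # m/s
        "s_0y": 0.875,  # m, initial CoM ordinate above the impact point
        "s_y_target": -3.0,  # m, final CoM ordinate
        "gravity": 9.81,
        # multibody block
        "multibody": False,
        "headings": multibody_fall.HEADINGS,
        "speed_grid": (0.5, 1.0, 1.5, 2.0),
        "restitution_wall": 0.5,
        "restitution_ground": 0.2,
        "friction": 0.8,
        "friction_wall": 0.2,
        "wall_height": multibody_fall.Environment().wall_height,
        "wall_thickness": multibody_fall.Environment().wall_thickness,
        "drop": 3.0,
        "step": 0.01,
        # the slowest scenario (backing into the wall at 0.5 m/s) drapes
        # over the parapet and needs ~19 s of simulated time to quiesce
        "max_time": 25.0,
    },
}

#: physical sanity bounds for sweepable parameters
_SANITY_BOUNDS: dict[str, tuple[float, float]] = {
    "stature": (1.2, 2.2),
    "mass": (40.0, 150.0),
    "speed": (0.0, 5.0),
    "restitution": (0.0, 1.0),
    "restitution_wall": (0.0, 1.0),
    "restitution_ground": (0.0, 1.0),
    "lever_b": (0.01, 0.5),
    "lever_h": (0.001, 0.1),
    "pressure": (0.0, 1.0),
    "device_distance": (0.0, 3.0),
    "wall_height": (0.2, 1.5),
    "friction": (0.0, 2.0),
    "friction_wall": (0.0, 2.0),
}


@dataclass(frozen=True)
class CaseConfig:
    """One executable scenario: case id, parameter block, report options."""

    case_id: str
    params: dict[str, Any] = field(default_factory=dict)
    paper_rounding: bool = False

    def __post_init__(self):
        if self.case_id not in CASE_IDS:
            raise DomainError(f"unknown case id {self.case_id!r}; expected one of {CASE_IDS}")


def paper_case(case_id: str, paper_rounding: bool = False) -> CaseConfig:
    """The reference configuration of a case, with every default parameter
    set to the originally documented value."""
    if case_id not in CASE_IDS:
        raise DomainError(f"unknown case id {case_id!r}; expected one of {CASE_IDS}")
    return CaseConfig(
        case_id=case_id, params=dict(_DEFAULTS[case_id]), paper_rounding=paper_rounding
    )


def _r(value: float, ndigits: int, enabled: bool) -> float:
    return round(value, ndigits) if enabled else value


def _run_finishing_oven(p: dict, rounding: bool) -> dict:
    tables = anthropometry.builtin_tables()
    table = tables[p["table"]] if isinstance(p["table"], str) else p["table"]
    mannequin = anthropometry.build_mannequin(p["stature"], None, table)
    reach = anthropometry.arm_reach(mannequin, p["side"])
    check = anthropometry.reachability_check(reach, p["device_distance"])
    return {
        "stature_m": p["stature"],
        "side": p["side"],
        "arm_reach_m": _r(reach, 3, rounding),
        "device_distance_m": p["device_distance"],
        "reachable": check.reachable,
        "margin_m": _r(check.margin, 3, rounding),
        "mannequin": mannequin.to_report(),
    }


def _run_pedestrian_hit(p: dict, rounding: bool) -> dict:
    mech = lever_mechanics.LeverMechanism(b=p["lever_b"], h=p["lever_h"])
    calf = lever_mechanics.ContactPatch(*p["calf_patch"])
    talus = lever_mechanics.ContactPatch(*p["talus_patch"])
    seat = lever_mechanics.ContactPatch(*p["seat_patch"])
    tire = lever_mechanics.TireSpec.from_code(p["tire"])

    seat_pressure = lever_mechanics.contact_stress(p["seat_weight"], seat)
    chain = lever_mechanics.calf_injury_chain(p["pressure"], calf, mech, talus)
    amp = lever_mechanics.amplification_factor(mech)
    return {
        "tire": p["tire"],
        "tire_outer_diameter_mm": lever_mechanics.tire_outer_diameter(tire),
        "seat_reference_pressure_MPa": _r(seat_pressure, 2, rounding),
        "applied_pressure_MPa": p["pressure"],
        "calf_patch_area_mm2": calf.area,
        "amplification_factor": _r(amp, 2, rounding),
        "calf_force_N": _r(chain.calf_force, 0, rounding),
        "talus_force_N": _r(chain.talus_force, 0, rounding),
        "talus_patch_area_mm2": talus.area,
        "talus_stress_MPa": _r(chain.talus_stress, 1, rounding),
    }


def _run_wall_fall_analytic(p: dict, rounding: bool) -> dict:
    body = rigid_fall.RigidBodySpec(m=p["mass"], l=p["stature"], b=p["impact_arm"])
    pred = rigid_fall.predict_fall(
        body,
        v_i=p["speed"],
        e=p["restitution"],
        s_y_target=p["s_y_target"],
        s_0y=p["s_0y"],
        g=p["gravity"],
    )
    if rounding:
        # the worked chain re-rounds intermediates before reusing them
        v_f = round(pred.v_f, 2)
        omega = round(pred.omega, 3)
        s_x = round(pred.s_x, 2)
        t = round(pred.t, 1)
        upsilon = round(omega * t, 2)
        upsilon_deg = round(float(np.degrees(omega * t)), 1)
    else:
        v_f, omega, s_x, t = pred.v_f, pred.omega, pred.s_x, pred.t
        upsilon, upsilon_deg = pred.upsilon, pred.upsilon_deg
    return {
        "v_f_m_s": v_f,
        "omega_rad_s": omega,
        "s_x_m": s_x,
        "t_s": t,
        "upsilon_rad": upsilon,
        "upsilon_deg": upsilon_deg,
    }


def _run_wall_fall_multibody(p: dict) -> dict:
    mannequin = anthropometry.build_mannequin(
        p["stature"], p["mass"], anthropometry.builtin_tables()["table_1_75m"]
    )
    am = multibody_fall.build_articulated_mannequin(mannequin)
    env = multibody_fall.Environment(
        wall_height=p["wall_height"], wall_thickness=p["wall_thickness"], drop=p["drop"]
    )
    contact = multibody_fall.ContactProperties(
        restitution_wall=p["restitution_wall"],
        restitution_ground=p["restitution_ground"],
        friction_coefficient=p["friction"],
        friction_wall=p.get("friction_wall"),
    )
    config = multibody_fall.SimulationConfig(step=p["step"], max_time=p["max_time"])
    out: dict[str, Any] = {}
    for heading in p["headings"]:
        sweep = multibody_fall.minimum_fall_speed(
            am, env, contact, heading, speeds=p["speed_grid"], config=config
        )
        out[heading] = {
            "minimum_fall_speed_m_s": sweep.minimum_speed,
            "outcomes": {
                f"{s:g}": {
                    "fell": o.fell,
                    "final_trunk_orientation_deg": round(o.final_trunk_orientation, 1),
                    "head_to_wall_distance_m": round(o.head_to_wall_distance, 3),
                    "face_up": o.face_up,
                }
                for s, o in sweep.outcomes.items()
            },
            "failures": dict(sweep.failures),
        }
    return out


def run_case(config: CaseConfig) -> dict:
    """Execute a case and return its structured report.

    The report carries every intermediate quantity of the worked chain for
    that case.  It is a pure function of the configuration."""
    p = {**_DEFAULTS[config.case_id], **config.params}
    report: dict[str, Any] = {"case_id": config.case_id, "paper_rounding": config.paper_rounding}
    if config.case_id == "finishing-oven":
        report["results"] = _run_finishing_oven(p, config.paper_rounding)
    elif config.case_id == "pedestrian-hit":
        report["results"] = _run_pedestrian_hit(p, config.paper_rounding)
    else:
        report["results"] = {"analytic": _run_wall_fall_analytic(p, config.paper_rounding)}
        if p.get("multibody"):
            report["results"]["multibody"] = _run_wall_fall_multibody(p)
    return report


@dataclass(frozen=True)
class SweepSpec:
    """Randomized parameter sweep: uniform samples within ranges.

    Reproducible per configuration: sample ``i`` is drawn from a
    counter-based generator keyed by ``(seed, i)``, so any single config
    can be regenerated in isolation.
    """

    case_id: str
    ranges: dict[str, tuple[float, float]]
    n: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.case_id not in CASE_IDS:
            raise DomainError(f"unknown case id {self.case_id!r}")
        if self.n <= 0:
            raise DomainError("sample count must be positive")
        for name, (lo, hi) in self.ranges.items():
            if hi <= lo:
                raise DomainError(f"empty range for {name!r}: ({lo}, {hi})")
            if name in _SANITY_BOUNDS:
                blo, bhi = _SANITY_BOUNDS[name]
                if lo < blo or hi > bhi:
                    raise DomainError(
                        f"range for {name!r} exceeds sanity bounds [{blo}, {bhi}]"
                    )


def generate_sweep(spec: SweepSpec) -> list[CaseConfig]:
    """Materialize the sweep into a list of case configurations."""
    configs = []
    names = sorted(spec.ranges)
    for i in range(spec.n):
        rng = np.random.Generator(np.random.Philox(key=[spec.seed, i]))
        params = dict(_DEFAULTS[spec.case_id])
        for name in names:
            lo, hi = spec.ranges[name]
            params[name] = float(rng.uniform(lo, hi))
        configs.append(CaseConfig(case_id=spec.case_id, params=params))
    return configs
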