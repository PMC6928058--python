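"""Shared fixtures: the reference mannequin and the five-scenario battery.

The full-scenario simulations are by far the most expensive part of the
suite, so they run once per session and are shared between the multibody
unit tests and the acceptance tests.
"""

import numpy as np
import pytest

from forensicbiomech import anthropometry, multibody_fall as mf, rigid_fall as rf
from forensicbiomech._planar import (
    Box,
    ContactSettings,
    LinkSpec,
    PlanarLinkage,
    StepSettings,
    Terrain,
    simulate_linkage,
)

#: the five documented walking-scenario runs: (heading, speed)
SCENARIO_KEYS = (
    ("toward-wall-facing-wall", 0.5),
    ("toward-wall-facing-wall", 2.0),
    ("toward-wall-back-first", 0.5),
    ("toward-wall-back-first", 2.0),
    ("on-wall-back-to-void", 0.5),
)


@pytest.fixture(scope="session")
def mannequin():
    return anthropometry.build_mannequin(
        1.75, 75.0, anthropometry.builtin_tables()["table_1_75m"]
    )


@pytest.fixture(scope="session")
def articulated(mannequin):
    return mf.build_articulated_mannequin(mannequin)


@pytest.fixture(scope="session")
def battery(articulated):
    """All five documented scenario runs with the default environment."""
    env = mf.Environment()
    contact = mf.ContactProperties()
    out = {}
    for heading, speed in SCENARIO_KEYS:
        out[(heading, speed)] = mf.simulate(
            articulated,
            env,
            contact,
            mf.InitialCondition(heading, speed),
            mf.SimulationConfig(max_time=25.0),
        )
    return out


def locked_rod_impact(v_i: float, e: float):
    """Single-contact wall impact of the locked composite body.

    Returns (simulated v_f, simulated omega, analytic v_f, analytic omega).
    """
    man = anthropometry.build_mannequin(
        1.75, 75.0, anthropometry.builtin_tables()["table_1_75m"]
    )
    locked = mf.lock_joints(mf.build_articulated_mannequin(man))
    link = LinkSpec(
        name="body",
        length=locked.l,
        mass=locked.m,
        inertia=locked.I,
        terms=(),
        ang_indices=(2,),
        ang_offset=0.0,
        s_bounds=(-locked.b, locked.l - locked.b),
        radius=0.0,
    )
    lk = PlanarLinkage([link], nq=3, free_base=True, gravity=0.0)
    q0 = np.array([-0.05, 0.0, np.pi / 2])  # upright, bottom tip b below CoM
    v0 = np.array([v_i, 0.0, 0.0])
    # small box so only the tip can touch its vertical face
    terrain = Terrain(
        solids=[Box("wall", "wall", 0.0, 1.0, -locked.b - 0.05, -locked.b + 0.02)]
    )
    cs = ContactSettings(restitution={"wall": e}, friction=0.0)
    rec = simulate_linkage(lk, terrain, cs, q0, v0, StepSettings(step=0.01, max_time=0.5))
    qd = np.asarray(rec.qdot)
    hits = np.where(np.abs(qd[:, 0] - v_i) > 1e-9)[0]
    assert len(hits), "no impact occurred"
    i = hits[0]
    body = rf.RigidBodySpec(m=locked.m, l=locked.l, b=locked.b, I=locked.I)
    return (
        qd[i, 0],
        -qd[i, 2],
        rf.post_impact_velocity(body, v_i, e),
        rf.post_impact_angular_velocity(body, v_i, e),
    )
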