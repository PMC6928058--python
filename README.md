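# forensic-biomech

A forensic-biomechanics toolkit for accident reconstruction in legal
disputes. It re-implements, as tested reusable models, three quantitative
analyses originally developed for court cases:

1. **Anthropometry** — build a segment-proportion mannequin of a person
   from stature (and optionally mass) and answer reachability questions
   ("could the trapped worker's free arm reach the emergency device
   1.1 m away?").
2. **Lever mechanics** — the tibia–talus ankle lever: a force applied to
   the calf (for example by a car tire) is amplified by the ratio of its
   moment arms onto the small tibia–talus contact patch, producing bone-level
   contact stresses ("0.03 MPa on the calf becomes 17.6 MPa on the talus
   neck").
3. **Fall reconstruction** — a man falls over a low wall with a 3 m drop:
   * a **closed-form rigid-body model** (locked-joint impact against the
     wall edge with Newton restitution, then ballistic flight of the centre
     of mass with superimposed rotation), and
   * a **planar 9-segment multibody simulator** (articulated mannequin with
     torsional joint springs/dampers, impulse-based wall/ground contact with
     restitution and Coulomb friction) that classifies the fall outcome —
     did the person go over, which way did the trunk rotate, where did the
     head land, face up or face down — as a function of walking speed and
     approach direction.

Full model derivations, parameter tables, and known limitations are in
[docs/methods.md](docs/methods.md).

## Quick start (Python)

Ankle-lever chain — the pedestrian-hit analysis:

```python
from forensicbiomech import lever_mechanics as lm

chain = lm.calf_injury_chain(
    pressure=0.03,                       # MPa on the calf
    calf_patch=lm.ContactPatch(70, 70),  # mm
    mech=lm.LeverMechanism(b=0.129, h=0.018),
    talus_patch=lm.ContactPatch(5, 12),  # mm
)
print(round(chain.talus_stress, 1))      # 17.6 MPa
```

Closed-form fall over a wall — 75 kg, 1.75 m, arriving at 0.5 m/s:

```python
from forensicbiomech import rigid_fall as rf

body = rf.RigidBodySpec(m=75, l=1.75, b=0.875)   # I defaults to m·l²/12
pred = rf.predict_fall(body, v_i=0.5, e=0.5, s_y_target=-3.0)
# pred.v_f = 0.3125 m/s, pred.omega = 0.6429 rad/s,
# pred.s_x = 0.2777 m, pred.t = 0.8887 s, pred.upsilon_deg = 32.7°
```

Multibody fall classification:

```python
from forensicbiomech import anthropometry, multibody_fall as mf

man = anthropometry.build_mannequin(
    1.75, 75.0, anthropometry.builtin_tables()["table_1_75m"]
)
am = mf.build_articulated_mannequin(man)
rec = mf.simulate(
    am, mf.Environment(), mf.ContactProperties(),
    mf.InitialCondition("on-wall-back-to-void", 0.5),
    mf.SimulationConfig(max_time=25.0),
)
out = mf.classify_outcome(rec)
# out.fell = True, out.final_trunk_orientation ≈ -90°,
# out.head_to_wall_distance ≈ 2.5 m, out.face_up = True
```

## Quick start (CLI)

The `forensic-biomech` command (or `python -m forensicbiomech.cli`) runs
each case and prints a JSON report. `--paper-rounding` reproduces the
display precision of the original case reports (computation is always
unrounded internally).

```
$ forensic-biomech case2-lever --paper-rounding
{
  "case_id": "pedestrian-hit",
  "paper_rounding": true,
  "results": {
    "tire": "215/55/17",
    "tire_outer_diameter_mm": 668.0,
    "seat_reference_pressure_MPa": 0.03,
    "applied_pressure_MPa": 0.03,
    "calf_patch_area_mm2": 4900.0,
    "amplification_factor": 7.17,
    "calf_force_N": 147.0,
    "talus_force_N": 1054.0,
    "talus_patch_area_mm2": 60.0,
    "talus_stress_MPa": 17.6
  }
}
```

Other subcommands:

```
forensic-biomech case1-reach --stature 1.6 --distance 1.1
forensic-biomech case3-analytic --paper-rounding
forensic-biomech case3-multibody --heading on-wall-back-to-void --speed 0.5 --csv traj.csv
forensic-biomech sweep --case wall-fall --param speed 0.5 2.0 --n 20 --seed 1 --run
```

Sweeps are reproducible: sample `i` of seed `s` is drawn from a
counter-based generator keyed by `(s, i)`, so any single configuration can
be regenerated in isolation.

## Reproduction

Run the full test suite (the multibody property battery takes a few
minutes on one CPU):

```
python -m pytest -q tests/
```

`tests/test_acceptance.py` contains one test per documented acceptance
criterion: the three closed-form worked chains with sub-second runtime
budgets, and five physical properties of the multibody simulator
(locked-joint impact agrees with the closed-form impact equations within
2%; ballistic-flight angular momentum drifts < 1e-4 per second; no
mechanical-energy gain across contacts; the five documented scenario
outcomes; step-halving changes the final orientation by < 5°).

The headline numeric targets can be regenerated as JSON:

```
python scripts/acceptance.py --seed 0 --out acceptance.json
```

## Package layout

| Module | Contents |
| --- | --- |
| `forensicbiomech.anthropometry` | proportion tables, mannequin builder, arm reach, reachability |
| `forensicbiomech.lever_mechanics` | ankle lever, contact patches, tire geometry, injury force chain |
| `forensicbiomech.rigid_fall` | locked-body impact + ballistic flight, closed form |
| `forensicbiomech.multibody_fall` | planar 9-segment articulated fall simulator and outcome classifier |
| `forensicbiomech.scenarios` | case configurations, reports, randomized parameter sweeps |
| `forensicbiomech.integrate` | fixed-step Kutta–Merson integrator |

## License and intended use

These are simplified planar engineering models built for transparent,
reproducible reasoning about specific accident scenarios. They are not a
substitute for case-specific expert analysis; see the limitations section
of [docs/methods.md](docs/methods.md).
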