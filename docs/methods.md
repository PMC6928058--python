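# Methods

This document describes the models implemented in `forensic-biomech`,
their parameters (with units, defaults, and rationale), the numerical
methods, and the known limitations. The models originate from three
court-case analyses: a worker trapped at a finishing oven (reachability),
a pedestrian run over by a car (ankle-lever injury forces), and a fall
over a low wall at a construction site (fall reconstruction).

## 1. Anthropometry

### Proportion tables

A mannequin is built from a **proportion table**: per-segment lengths as
percent of stature, optionally per-segment masses as percent of total body
mass, plus body widths (shoulder, hip bone, foot length/breadth) as
percent of stature. Two tables ship with the package:

* `table_1_6m` — geometry-only (used for the 1.6 m worker; no mass data
  is supportable for that case);
* `table_1_75m` — geometry + mass (used for the 1.75 m / 75 kg fall
  subject).

The nine canonical segments are head+neck+trunk, and left/right upper
arm, forearm+hand, thigh, lower leg+foot. Compound entries keep their
constituent fractions (head, neck, trunk are stored separately and
summed), so for example at 75 kg the head+neck+trunk mass is
4.65 + 1.65 + 37.5 = 43.8 kg.

### Rounding convention

Realized dimensions use exact decimal arithmetic with **round-half-down**
to 3 decimals for lengths (m) and 2 decimals for masses (kg). This
reproduces every cell of the original published dimension tables that the
worked chains rely on (e.g. 0.298 + 0.407 = 0.705 m left-arm reach at
1.6 m stature). A handful of printed cells are internally inconsistent
with their own stated fractions under *any* single rounding rule and are
treated as typos in the source tables:

| printed | fraction × base | we produce |
| --- | --- | --- |
| head length 0.228 m | 13% × 1.75 = 0.2275 | 0.227 |
| forearm mass 1.28 kg | 1.7% × 75 = 1.275 | 1.27 |
| lower-leg length 0.397 m | 24.6% × 1.6 = 0.3936 | 0.394 |
| hip width 0.301 m | 19.1% × 1.6 = 0.3056 | 0.306 |
| left forearm+hand 0.23 m (right prints 0.234) | same fraction both sides | symmetric |

### Inertia

Each segment is a uniform slender rod: central inertia m·l²/12, centroid
at the segment midpoint. This is consistent with the whole-body
I = m·l²/12 used by the closed-form fall model.

### Reach

Arm reach is the straight-line sum of upper-arm and forearm+hand lengths
(fully extended arm, fingertip reach). `reachability_check(reach, d)`
reports reachable/unreachable and the margin `d − reach`; at 1.6 m
stature the 0.705 m reach leaves a device 1.1 m from the shoulder
unreachable by 0.395 m.

## 2. Ankle-lever mechanics

The tibia–talus mechanism is a first-class lever about the ankle hinge O:
a force F on the calf with moment arm **b = 0.129 m** is balanced by a
force f on the talus neck with moment arm **h = 0.018 m**, so torque
equilibrium F·b − f·h = 0 gives

f = F · (b/h),  amplification b/h = 7.17 (2 d.p.).

The worked chain: a seated-buttock reference pressure (600 N over a
100 × 200 mm patch = **0.03 MPa**) applied to the 70 × 70 mm calf patch
gives F = 147 N; amplified, f = 1053.5 N; spread over the 5 × 12 mm
tibia–talus patch this is a contact stress of **17.6 MPa** (1 d.p.).
All computation is unrounded; printed-figure rounding is applied only at
the report layer. The original report's intermediate "1,055 N" is not
exactly reproducible from its own unrounded inputs (1053.5 N, ≤ 0.2%
off); we report the unrounded chain.

Tire geometry: a 215/55/17 tire has outer diameter
17 × 25.4 + 2 × 0.55 × 215 = 668 mm, fixing the height of the contact
band on the leg. Contact patches are treated as uniformly loaded.

## 3. Closed-form rigid-body fall

The subject is modelled as a single rigid body (all joints locked) of
mass m, length l, inertia I = m·l²/12, translating horizontally at v_i
and striking a fixed wall edge at distance b below the centre of mass.

**Impact** (Newton restitution e at the contact point, impulse along the
travel direction):

* post-impact CoM speed v_f = v_i (m·b² − e·I)/(m·b² + I)
* post-impact angular speed ω = (v_f + e·v_i)/b

With m = 75 kg, l = 1.75 m, b = 0.875 m, e = 0.5, v_i = 0.5 m/s:
v_f = 0.3125 → 0.31 m/s and ω = 0.643 rad/s.

**Ballistic flight**: after the impact the CoM follows a parabola from
initial ordinate s_0y (default b) with horizontal speed v_f; at target
ordinate s_y the range is s_x = v_f·√(2(s_0y − s_y)/g) and the flight
time t = s_x / v_f. For a 3 m drop (s_y = −3 m, s_0y = 0.875 m,
g = 9.81 m/s²): s_x = 0.2777 → **0.28 m**, t = 0.8887 → **0.9 s**.
The accumulated rotation at landing is υ = ω·t (32.7° unrounded; 33.2°
when the re-rounded intermediates of the original display chain are
reused, which the report layer reproduces with `paper_rounding=True`).

## 4. Planar multibody fall simulator

### Mannequin

The mass-bearing mannequin becomes a planar linkage of 9 rigid links and
8 pin joints (shoulders, elbows, hips, knees). Generalized coordinates
are the trunk-base position and orientation plus the 8 relative joint
angles. Each joint carries a torsional spring and damper representing
passive muscular resistance:

| parameter | default | units |
| --- | --- | --- |
| joint spring (hips) | 0.5 | N·m/deg |
| joint spring (others) | 0.1 | N·m/deg |
| joint damper (all) | 0.001 | N·m·s/deg |

Constants are stored per degree and converted internally
(0.1 N·m/deg = 5.73 N·m/rad).

Two geometric additions are package design decisions:

* **Joint-range stops** — one-sided penalty torques (5.0 N·m/deg spring,
  0.05 N·m·s/deg damper) beyond anatomical flexion/extension limits,
  mirrored by facing direction. Without them the passive mannequin
  hyperextends freely at the hips and a backward step off the wall edge
  becomes a nonphysical slip-fall with the trunk counter-rotating toward
  the wall. Range stops are standard in articulated-dummy models.
* **Foot plates** — the source tables fold the foot into a 1-D
  "lower leg + foot" segment, which gives the standing model no base of
  support (any push topples it). Feet are modelled as contact sample
  offsets perpendicular to the shank tip: total length 15.2% of stature
  (standard anthropometric ratio), split 80% toe / 20% heel, pointing in
  the facing direction.

`lock_joints()` collapses the linkage into the rigid composite used by
the closed-form model: m ≈ 75 kg, l = 1.75 m, CoM height b ≈ 1.064 m
(above mid-stature, because over half the mass is in the trunk), and
I ≈ 14.07 kg·m² by direct parallel-axis summation of the link inertias.
Note this is ~26% below the uniform-rod m·l²/12 = 19.14 kg·m² — a uniform
rod overestimates the inertia of a body whose mass concentrates near its
CoM.

### Environment

| parameter | default | rationale |
| --- | --- | --- |
| wall height | 0.95 m | reconstructed, see below |
| wall thickness | 0.30 m | reconstructed, see below |
| drop | 3.0 m | documented |
| restitution (wall / ground) | 0.5 / 0.2 | documented |
| friction (ground / wall) | 0.8 / 0.2 | asphalt / clothed body on smooth coping |

The original account specifies only "a low wall" and the 3 m drop; the
wall cross-section and surface friction are unspecified. They were
reconstructed by a grid search (height 0.82–1.05 m, thickness
0.25–0.40 m, wall friction 0.1–0.5) scored against all five documented
scenario outcomes simultaneously. The physics that pins the height: the
wall must be close to the standing CoM height (1.06 m) so that a 0.5 m/s
backward arrival cannot sit onto and pour over the top (heights ≤ 0.92 m
fail this), yet low enough that 2 m/s arrivals still carry over (heights
≥ 1.0 m fail that). The frozen defaults satisfy every documented
outcome; this is calibration of unspecified geometry against the
documented end states, not tuning of model physics.

### Scenarios and classification

Three headings, starting at the instant of wall contact (or edge
departure), upright, all joints at rest, whole body translating at the
walking speed:

* `toward-wall-facing-wall` (A) — walking into the wall, face first;
* `toward-wall-back-first` (B) — backing into the wall;
* `on-wall-back-to-void` (C) — walking along the wall top, backwards,
  stepping off the far edge.

A run terminates when the mannequin is quiescent (total kinetic energy
< 0.1 J sustained for 0.5 s). `classify_outcome` then reports: **fell**
(the CoM went past the wall and down to the lower ground — bouncing back
onto the upper road counts as *not* fallen), the unwrapped cumulative
**trunk rotation** from upright (positive in the facing direction, so
±270° is meaningful), the final **head-to-wall distance**, and
**face_up**. At the defaults: A and B do not fall at 0.5 m/s; at 2 m/s A
ends at about +270° with the head ~0.45 m from the wall and B at about
−270° with the head ~0.5 m from the wall; C falls from a 0.5 m/s step
ending near −90°, face up, head ~2.5 m from the wall. The slowest case
(B at 0.5 m/s) drapes over the parapet and needs ~19 s of simulated time
for its limb oscillations to decay through the 0.001 N·m·s/deg dampers,
hence the 25 s scenario time budget.

### Contact and integration

* Fixed-step **Kutta–Merson** (4th-order with embedded error estimate),
  step 0.01 s. Step-halving changes final orientations by < 5°.
* **Impulsive contact**: sequential (projected Gauss–Seidel) normal
  impulses with Newton restitution for approach speeds above a 0.2 m/s
  bounce threshold, plus Coulomb friction impulses bounded by μ times
  the normal impulse. Restitution and friction are per material
  (wall / ground).
* **Resting contact**: contacts approaching slower than the bounce
  threshold receive a non-negative normal *force* computed from
  acceleration-level complementarity (Baraff-style), held constant over
  the step, with a dissipative normal-velocity feedback term. Without
  this, impulse-only stepping lets a settled body free-fall ~0.5 mm every
  step and the penetration correction pumps that back as artificial
  energy (~40 W measured), sustaining a permanent vibration that
  prevents quiescence.
* **Penetration correction**: split-impulse positional projection solved
  as a coupled non-negative system across all contacts; independent
  per-contact corrections fight each other on differently-oriented wall
  faces.
* **Energy audit**: every contact resolution records kinetic energy
  before/after; the test suite asserts no contact event ever gains
  mechanical energy.

### Verification

* Locked-joint wall impact of the composite body matches the closed-form
  post-impact v_f and ω to better than 0.1% (acceptance bound 2%).
* Free flight of the full articulated linkage conserves angular momentum
  about the CoM to < 1e−4 relative drift per second, and the CoM height
  fits a parabola with coefficient exactly −g/2.
* The five documented scenario outcomes are reproduced at the default
  parameters (see above).

## 5. Scenario layer

Reports are pure functions of their configuration (no timestamps):
re-running a case yields byte-identical JSON. `paper_rounding=True`
switches the report layer to the display precision of the original case
chains, re-rounding intermediates before reuse exactly as the original
display chain did; computation is always unrounded internally.

Parameter sweeps draw uniform samples within user ranges, validated
against physical sanity bounds (e.g. stature 1.2–2.2 m, restitution
0–1). Sample `i` of seed `s` comes from a counter-based Philox generator
keyed `(s, i)`, so individual configurations are reproducible in
isolation and insertion order does not matter.

## 6. Limitations

* All dynamics are **planar** (sagittal). Real shoulders/hips are ball
  joints; out-of-plane motion, twisting falls, and lateral impacts are
  out of scope. The classification targets (trunk rotation, head-to-wall
  distance, face orientation) do not depend on the out-of-plane degrees
  of freedom for the three modelled scenarios.
* Segments are rigid slender rods; no tissue deformation, no
  strain-based injury criteria. The lever model reports contact stress,
  not fracture risk; bone-strength thresholds must come from external
  literature.
* Joint springs/dampers model a *passive* body: no active balance
  recovery, stepping, or bracing. Low-speed "no fall" results mean the
  passive mannequin does not topple, not that an active person could not
  fall.
* The wall cross-section and wall friction are reconstructed, not
  measured; conclusions conditional on that geometry should be swept
  (`forensic-biomech sweep --case wall-fall --param wall_height …`).
* The contact model is rigid and impulse/force-based with a fixed step;
  it is validated for energy consistency and impact kinematics, not for
  contact-force time histories (no head-injury-criterion integration).
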