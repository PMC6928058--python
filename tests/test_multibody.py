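"""Tests for the planar 9-segment articulated fall simulator.

The expensive full-scenario simulations run once in the session-scoped
``battery`` fixture (see ``conftest.py``) and are shared between the
reproduction, energy, and classification tests as well as the
acceptance suite, keeping the whole battery within a few minutes.
"""

import numpy as np
import pytest

from conftest import SCENARIO_KEYS, locked_rod_impact
from forensicbiomech import anthropometry, multibody_fall as mf
from forensicbiomech._planar import StepSettings, simulate_linkage
from forensicbiomech.errors import DomainError, NotTerminatedError

SCENARIOS = set(SCENARIO_KEYS)


class TestBuildArticulatedMannequin:
    def test_topology(self, articulated):
        assert articulated.n_links == 9
        assert articulated.n_joints == 8
        assert set(articulated.joints) == set(mf.JOINT_NAMES)

    def test_total_mass(self, articulated):
        assert sum(s.mass for s in articulated.mannequin.segments) == pytest.approx(
            75.0, abs=0.1
        )

    def test_hip_springs_stiffer(self, articulated):
        for name, props in articulated.joints.items():
            expected = 0.5 if "hip" in name else 0.1
            assert props.spring_constant == expected
            assert props.damper_constant == 0.001
            assert props.rest_angle == 0.0

    def test_per_degree_units_converted(self):
        # 0.1 N m/deg must act as 0.1/DEG = 5.7296 N m/rad internally
        assert 0.1 / mf.DEG == pytest.approx(5.7296, abs=1e-3)

    def test_custom_joint_properties(self, mannequin):
        am = mf.build_articulated_mannequin(
            mannequin, {n: mf.JointProperties(0.2, 0.01) for n in mf.JOINT_NAMES}
        )
        assert am.joints["left_hip"].spring_constant == 0.2

    def test_negative_constants_rejected(self):
        with pytest.raises(DomainError):
            mf.JointProperties(spring_constant=-0.1)
        with pytest.raises(DomainError):
            mf.JointProperties(damper_constant=-1.0)

    def test_massless_mannequin_rejected(self):
        geo = anthropometry.build_mannequin(
            1.6, None, anthropometry.builtin_tables()["table_1_6m"]
        )
        with pytest.raises(mf.MissingMassError):
            mf.build_articulated_mannequin(geo)


class TestEnvironmentAndSettings:
    def test_default_geometry(self):
        env = mf.Environment()
        assert env.wall_height == 0.95
        assert env.wall_thickness == 0.30
        assert env.drop == 3.0
        assert env.lower_ground_y == pytest.approx(-2.05)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(DomainError):
            mf.Environment(wall_height=-1.0)
        with pytest.raises(DomainError):
            mf.Environment(wall_height=2.0, drop=1.0)

    def test_contact_validation(self):
        with pytest.raises(DomainError):
            mf.ContactProperties(restitution_wall=1.5)
        with pytest.raises(DomainError):
            mf.ContactProperties(friction_coefficient=-0.1)

    def test_heading_validation(self):
        with pytest.raises(DomainError):
            mf.InitialCondition("sideways", 0.5)

    def test_config_validation(self):
        with pytest.raises(DomainError):
            mf.SimulationConfig(step=0.0)


class TestLockJoints:
    def test_composite_against_direct_summation(self, mannequin, articulated):
        # oracle: stack the standing pose from raw segment lengths (no
        # engine kinematics) and sum masses/inertias by parallel axis
        locked = mf.lock_joints(articulated)
        seg = mannequin.segment
        le = seg("left_lower_leg_foot").length
        lt = seg("left_thigh").length
        ltr = seg("head_neck_trunk").length
        shoulder = le + lt + ltr - mf.HEAD_NECK_FRACTION_OF_TRUNK * ltr
        heights = {"head_neck_trunk": le + lt + ltr / 2}
        for side in ("left", "right"):
            lua = seg(f"{side}_upper_arm").length
            lfa = seg(f"{side}_forearm_hand").length
            heights[f"{side}_upper_arm"] = shoulder - lua / 2
            heights[f"{side}_forearm_hand"] = shoulder - lua - lfa / 2
            heights[f"{side}_thigh"] = le + lt / 2
            heights[f"{side}_lower_leg_foot"] = le / 2
        masses = {s.name: s.mass for s in mannequin.segments}
        total = sum(masses.values())
        com_y = sum(masses[n] * heights[n] for n in masses) / total
        inertia = sum(
            seg(n).inertia_com + masses[n] * (heights[n] - com_y) ** 2 for n in masses
        )
        assert locked.m == pytest.approx(total, rel=1e-9)
        assert locked.l == pytest.approx(1.75, rel=0.01)
        assert locked.b == pytest.approx(com_y, rel=1e-6)
        assert locked.I == pytest.approx(inertia, rel=1e-6)

    def test_com_height_above_half_stature(self, articulated):
        # most of the mass is in the trunk, so the composite CoM sits high
        locked = mf.lock_joints(articulated)
        assert locked.l / 2 < locked.b < locked.l

    def test_locked_mass_matches_mannequin(self, articulated):
        locked = mf.lock_joints(articulated)
        assert locked.m == pytest.approx(
            sum(s.mass for s in articulated.mannequin.segments)
        )


class TestLockedJointImpactOracle:
    """Criterion (i): locked-joint impact matches the closed-form
    post-impact velocity and angular velocity within 2%."""

    @pytest.mark.parametrize("v_i,e", [(0.5, 0.5), (2.0, 0.5), (1.0, 0.8)])
    def test_post_impact_state(self, v_i, e):
        v_sim, om_sim, v_ref, om_ref = locked_rod_impact(v_i, e)
        assert v_sim == pytest.approx(v_ref, rel=0.02)
        assert om_sim == pytest.approx(om_ref, rel=0.02)


@pytest.fixture(scope="module")
def flight(articulated):
    """Ballistic tumble of the full linkage with no terrain."""
    lk = mf._linkage_from(articulated, 9.81)
    # disable joint springs/dampers and range stops: pure free flight
    lk.spring[:] = 0.0
    lk.damper[:] = 0.0
    lk.limit_spring[:] = 0.0
    lk.limit_damper[:] = 0.0
    q0 = np.zeros(lk.nq)
    q0[1] = 50.0
    q0[2] = 1.0
    q0[3:] = [0.3, -0.5, 0.2, 0.6, -0.2, 0.4, -0.3, 0.1]
    v0 = np.concatenate([[1.0, 0.5, 2.0], np.full(8, 0.5)])
    rec = simulate_linkage(lk, None, None, q0, v0, StepSettings(step=0.01, max_time=1.0))
    return lk, rec


class TestFlightConservation:
    """Criterion (ii): ballistic flight conserves angular momentum and the
    CoM accelerates at exactly g."""

    def test_angular_momentum_drift(self, flight):
        lk, rec = flight
        q, qd = np.asarray(rec.q), np.asarray(rec.qdot)
        L0 = lk.angular_momentum_about_com(q[0], qd[0])
        L1 = lk.angular_momentum_about_com(q[-1], qd[-1])
        drift_per_s = abs(L1 - L0) / abs(L0) / (rec.times[-1] - rec.times[0])
        assert drift_per_s < 1e-4

    def test_com_acceleration_is_gravity(self, flight):
        lk, rec = flight
        t = np.asarray(rec.times)
        com = np.array([lk.system_com(qq) for qq in np.asarray(rec.q)])
        # quadratic fit of CoM height: coefficient of t^2 is -g/2
        coef = np.polyfit(t, com[:, 1], 2)
        assert coef[0] == pytest.approx(-9.81 / 2, rel=1e-6)
        # horizontal CoM speed constant
        vx = np.gradient(com[:, 0], t)
        assert np.allclose(vx, vx[0], atol=1e-9)


class TestEnergyAcrossContacts:
    """Criterion (iii): no mechanical-energy gain across any contact."""

    @pytest.mark.parametrize("key", sorted(SCENARIOS))
    def test_no_gain_in_scenario(self, battery, key):
        rec = battery[key]
        audit = np.asarray(rec.energy_audit)
        assert len(audit) > 0
        gains = audit[:, 2] - audit[:, 1]
        assert gains.max() <= 1e-9

    def test_joint_oscillation_decays(self, articulated):
        # dampers > 0: free oscillation amplitude is non-increasing
        lk = mf._linkage_from(articulated, 0.0)
        q0 = np.zeros(lk.nq)
        q0[3] = 0.4  # deflect one shoulder, no gravity, no contact
        rec = simulate_linkage(
            lk, None, None, q0, np.zeros(lk.nq), StepSettings(step=0.01, max_time=4.0)
        )
        ke = np.asarray(rec.kinetic_energy)
        t = np.asarray(rec.times)
        early = ke[(t > 0.0) & (t < 2.0)].max()
        late = ke[t >= 2.0].max()
        assert late < early


class TestScenarioReproduction:
    """Criterion (iv): the five documented scenario outcomes."""

    def test_a_low_speed_no_fall(self, battery):
        out = mf.classify_outcome(battery[("toward-wall-facing-wall", 0.5)])
        assert out.fell is False

    def test_b_low_speed_no_fall(self, battery):
        out = mf.classify_outcome(battery[("toward-wall-back-first", 0.5)])
        assert out.fell is False

    def test_a_high_speed_falls_forward(self, battery):
        out = mf.classify_outcome(battery[("toward-wall-facing-wall", 2.0)])
        assert out.fell is True
        assert out.final_trunk_orientation > 180.0
        assert out.head_to_wall_distance < 1.0

    def test_b_high_speed_falls_backward(self, battery):
        out = mf.classify_outcome(battery[("toward-wall-back-first", 2.0)])
        assert out.fell is True
        assert out.final_trunk_orientation < -180.0
        assert out.head_to_wall_distance < 1.0

    def test_c_falls_supine_head_away(self, battery):
        out = mf.classify_outcome(battery[("on-wall-back-to-void", 0.5)])
        assert out.fell is True
        assert out.final_trunk_orientation == pytest.approx(-90.0, abs=30.0)
        assert out.head_to_wall_distance >= 1.0
        assert out.face_up is True

    def test_every_scenario_records_contact_events(self, battery):
        for rec in battery.values():
            assert len(rec.events) > 0


class TestStepHalving:
    """Criterion (v): halving the step changes the final orientation < 5 deg."""

    def test_scenario_c_converged(self, articulated, battery):
        fine = mf.simulate(
            articulated,
            mf.Environment(),
            mf.ContactProperties(),
            mf.InitialCondition("on-wall-back-to-void", 0.5),
            mf.SimulationConfig(step=0.005, max_time=25.0),
        )
        coarse = battery[("on-wall-back-to-void", 0.5)]
        d = abs(
            mf.classify_outcome(fine).final_trunk_orientation
            - mf.classify_outcome(coarse).final_trunk_orientation
        )
        assert d < 5.0


class TestClassifyOutcome:
    def test_unterminated_raises(self, articulated):
        rec = mf.simulate(
            articulated,
            mf.Environment(),
            mf.ContactProperties(),
            mf.InitialCondition("toward-wall-facing-wall", 2.0),
            mf.SimulationConfig(max_time=0.5),  # far too short to settle
        )
        assert rec.terminated is False
        with pytest.raises(NotTerminatedError):
            mf.classify_outcome(rec)


class TestMinimumFallSpeed:
    def test_scenario_a_low_speed_insufficient(self, articulated):
        res = mf.minimum_fall_speed(
            articulated,
            mf.Environment(),
            mf.ContactProperties(),
            "toward-wall-facing-wall",
            speeds=(0.5, 2.0),
            config=mf.SimulationConfig(max_time=25.0),
        )
        assert res.minimum_speed == 2.0
        assert res.outcomes[0.5].fell is False

    def test_scenario_c_falls_at_lowest(self, articulated):
        res = mf.minimum_fall_speed(
            articulated,
            mf.Environment(),
            mf.ContactProperties(),
            "on-wall-back-to-void",
            speeds=(0.5,),
            config=mf.SimulationConfig(max_time=25.0),
        )
        assert res.minimum_speed == 0.5

    def test_unclearable_wall_returns_none(self, articulated):
        res = mf.minimum_fall_speed(
            articulated,
            mf.Environment(wall_height=30.0, drop=33.0),
            mf.ContactProperties(),
            "toward-wall-facing-wall",
            speeds=(2.0,),
            config=mf.SimulationConfig(max_time=25.0),
        )
        assert res.minimum_speed is None


class TestTrajectoryRecord:
    def test_csv_export(self, battery, tmp_path):
        rec = battery[("on-wall-back-to-void", 0.5)]
        path = tmp_path / "traj.csv"
        rec.to_csv(path)
        text = path.read_text().splitlines()
        assert text[0].startswith("time_s")
        assert "head_neck_trunk_x_m" in text[0]
        assert len(text) == len(rec.times) + 1

    def test_monotone_time(self, battery):
        for rec in battery.values():
            assert np.all(np.diff(np.asarray(rec.times)) > 0)
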