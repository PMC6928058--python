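"""Tests for anthropometric mannequin construction and reach analysis."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from forensicbiomech import anthropometry as am
from forensicbiomech.errors import DomainError, InvalidTableError, StructuralError


@pytest.fixture(scope="module")
def tables():
    return am.builtin_tables()


@pytest.fixture(scope="module")
def man_160(tables):
    return am.build_mannequin(1.6, None, tables["table_1_6m"])


@pytest.fixture(scope="module")
def man_175(tables):
    return am.build_mannequin(1.75, 75.0, tables["table_1_75m"])


class TestBuiltinTables:
    def test_keys(self, tables):
        assert set(tables) == {"table_1_6m", "table_1_75m"}

    def test_thigh_length_fraction(self, tables):
        assert tables["table_1_6m"].entries["left_thigh"].length_fraction == 24.5

    def test_trunk_mass_fraction(self, tables):
        assert tables["table_1_75m"].entries["head_neck_trunk"].mass_fraction == 58.4

    def test_mass_fractions_sum_to_100(self, tables):
        total = sum(
            e.mass_fraction for e in tables["table_1_75m"].entries.values()
        )
        assert total == pytest.approx(100.0, abs=1e-9)

    def test_length_fractions_identical_between_tables(self, tables):
        t1, t2 = tables["table_1_6m"], tables["table_1_75m"]
        for name in am.SEGMENT_NAMES:
            assert (
                t1.entries[name].length_components == t2.entries[name].length_components
            )

    def test_geometry_table_has_no_masses(self, tables):
        assert not tables["table_1_6m"].has_masses
        assert tables["table_1_75m"].has_masses


class TestTableValidation:
    def test_missing_segment_rejected(self):
        with pytest.raises(InvalidTableError):
            am.ProportionTable(entries={})

    def test_unknown_segment_rejected(self, tables):
        entries = dict(tables["table_1_6m"].entries)
        entries["tail"] = am.SegmentFractions((1.0,))
        with pytest.raises(InvalidTableError):
            am.ProportionTable(entries=entries)

    def test_non_positive_fraction_rejected(self):
        with pytest.raises(InvalidTableError):
            am.SegmentFractions((0.0,))

    def test_bad_mass_sum_rejected(self, tables):
        entries = dict(tables["table_1_75m"].entries)
        entries["head_neck_trunk"] = am.SegmentFractions(
            entries["head_neck_trunk"].length_components, (10.0,)
        )
        with pytest.raises(InvalidTableError):
            am.ProportionTable(entries=entries)

    def test_parse_error_carries_location(self, tmp_path):
        bad = tmp_path / "bad.txt"
        bad.write_text("segment left_thigh width 24.5\n")
        with pytest.raises(InvalidTableError, match="bad.txt:1"):
            am.load_table(bad)


class TestLoadTable:
    def test_round_trip_text_format(self, tmp_path, tables):
        path = tmp_path / "table.txt"
        lines = []
        for name, fr in tables["table_1_75m"].entries.items():
            parts = [f"segment {name} length"] + [str(c) for c in fr.length_components]
            parts += ["mass"] + [str(c) for c in fr.mass_components]
            lines.append(" ".join(parts))
        for wname, w in tables["table_1_75m"].widths.items():
            lines.append(f"width {wname} {w}")
        path.write_text("\n".join(lines))
        loaded = am.load_table(path)
        assert loaded == tables["table_1_75m"]

    def test_comments_and_blank_lines_ignored(self, tmp_path, tables):
        path = tmp_path / "table.txt"
        body = "\n# comment only\n\n".join(
            "segment {} length {}".format(
                name, " ".join(str(c) for c in fr.length_components)
            )
            for name, fr in tables["table_1_6m"].entries.items()
        )
        path.write_text(body)
        loaded = am.load_table(path)
        for name in am.SEGMENT_NAMES:
            assert (
                loaded.entries[name].length_components
                == tables["table_1_6m"].entries[name].length_components
            )


class TestBuildMannequin:
    def test_trunk_mass_43_8(self, man_175):
        # 4.65 + 1.65 + 37.5, each component rounded to 2 decimals
        assert man_175.segment("head_neck_trunk").mass == pytest.approx(43.8)

    def test_left_upper_arm_length_160(self, man_160):
        assert man_160.segment("left_upper_arm").length == pytest.approx(0.298)

    def test_left_forearm_hand_length_160(self, man_160):
        # 0.234 + 0.173 (the published 0.23 left cell is a typo)
        assert man_160.segment("left_forearm_hand").length == pytest.approx(0.407)

    def test_unit_stature_lengths_equal_fractions(self, tables):
        man = am.build_mannequin(1.0, 1.0, tables["table_1_75m"], rounded=False)
        for name in am.SEGMENT_NAMES:
            frac = tables["table_1_75m"].entries[name].length_fraction
            assert man.segment(name).length == pytest.approx(frac / 100)

    def test_segment_masses_sum_to_total(self, man_175):
        assert sum(s.mass for s in man_175.segments) == pytest.approx(75.0, abs=0.1)

    def test_stature_recovered_from_leg_chain(self, man_175):
        total = (
            man_175.segment("head_neck_trunk").length
            + man_175.segment("left_thigh").length
            + man_175.segment("left_lower_leg_foot").length
        )
        assert total == pytest.approx(1.75, rel=0.01)

    def test_inertia_is_slender_rod(self, man_175):
        seg = man_175.segment("left_thigh")
        assert seg.inertia_com == pytest.approx(seg.mass * seg.length**2 / 12)

    def test_geometry_only_build_has_zero_masses(self, man_160):
        assert not man_160.has_masses
        assert all(s.mass == 0.0 and s.inertia_com == 0.0 for s in man_160.segments)

    def test_mass_with_geometry_table_rejected(self, tables):
        with pytest.raises(InvalidTableError):
            am.build_mannequin(1.6, 70.0, tables["table_1_6m"])

    def test_non_positive_inputs_rejected(self, tables):
        with pytest.raises(DomainError):
            am.build_mannequin(0.0, None, tables["table_1_6m"])
        with pytest.raises(DomainError):
            am.build_mannequin(1.75, -1.0, tables["table_1_75m"])

    def test_default_table_is_mass_bearing(self):
        man = am.build_mannequin(1.75, 75.0)
        assert man.segment("head_neck_trunk").mass == pytest.approx(43.8)

    def test_widths_realized(self, man_160):
        assert man_160.widths["shoulder_width"] == pytest.approx(0.414)

    def test_report_round_trips_through_json(self, man_175):
        import json

        report = json.loads(man_175.to_json())
        assert report["total_mass_kg"] == 75.0
        assert len(report["segments"]) == 9

    @given(
        stature=st.floats(min_value=1.2, max_value=2.2),
        k=st.floats(min_value=0.5, max_value=2.0),
    )
    @settings(max_examples=25, deadline=None)
    def test_scale_equivariance_unrounded(self, stature, k):
        t = am.builtin_tables()["table_1_75m"]
        base = am.build_mannequin(stature, 75.0, t, rounded=False)
        scaled = am.build_mannequin(stature * k, 75.0, t, rounded=False)
        for name in am.SEGMENT_NAMES:
            assert scaled.segment(name).length == pytest.approx(
                base.segment(name).length * k, rel=1e-9
            )

    @given(total_mass=st.floats(min_value=40.0, max_value=150.0))
    @settings(max_examples=25, deadline=None)
    def test_mass_conservation_any_total(self, total_mass):
        t = am.builtin_tables()["table_1_75m"]
        man = am.build_mannequin(1.75, total_mass, t)
        assert sum(s.mass for s in man.segments) == pytest.approx(
            total_mass, abs=0.1
        )


class TestArmReach:
    def test_paper_reach_160(self, man_160):
        assert am.arm_reach(man_160, "left") == pytest.approx(0.705)

    def test_reach_right_175(self, man_175):
        # 0.325 + 0.444 from the mass-bearing table at 1.75 m
        assert am.arm_reach(man_175, "right") == pytest.approx(0.769)

    def test_unit_mannequin_reach_unrounded(self, tables):
        man = am.build_mannequin(1.0, None, tables["table_1_6m"], rounded=False)
        assert am.arm_reach(man, "left") == pytest.approx(0.44)

    def test_side_symmetry(self, man_160, man_175):
        for man in (man_160, man_175):
            assert am.arm_reach(man, "left") == pytest.approx(
                am.arm_reach(man, "right"), abs=1e-12
            )

    def test_bad_side_rejected(self, man_160):
        with pytest.raises(DomainError):
            am.arm_reach(man_160, "middle")

    def test_missing_segment_is_structural_error(self, man_160):
        broken = am.Mannequin(
            stature=1.6,
            total_mass=0.0,
            segments=tuple(s for s in man_160.segments if "upper_arm" not in s.name),
        )
        with pytest.raises(StructuralError):
            am.arm_reach(broken, "left")


class TestReachability:
    def test_paper_verdict_unreachable(self):
        res = am.reachability_check(0.705, 1.1)
        assert not res.reachable
        assert res.margin == pytest.approx(0.395)

    def test_boundary_is_reachable(self):
        res = am.reachability_check(1.1, 1.1)
        assert res.reachable
        assert res.margin == pytest.approx(0.0)

    def test_longer_reach_is_reachable(self):
        assert am.reachability_check(2.0, 1.1).reachable

    def test_negative_inputs_rejected(self):
        with pytest.raises(DomainError):
            am.reachability_check(-0.1, 1.0)
        with pytest.raises(DomainError):
            am.reachability_check(0.1, -1.0)

    @given(
        reach=st.floats(min_value=0, max_value=3),
        dist=st.floats(min_value=0, max_value=3),
    )
    @settings(max_examples=50, deadline=None)
    def test_verdict_matches_margin_sign(self, reach, dist):
        res = am.reachability_check(reach, dist)
        assert res.reachable == (res.margin <= 0)
        assert math.isclose(res.margin, dist - reach, abs_tol=1e-12)
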