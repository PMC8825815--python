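"""REBA / RULA / OWAS: bins, embedded tables, dual-transcription checks, risk bands."""

import hashlib
import itertools
from importlib import resources

import numpy as np
import pytest

import reference_tables as ref
from conftest import make_angle_frame
from ergopose.errors import ValidationError
from ergopose.scales import (
    OwasCode,
    RebaInput,
    RiskLevel,
    RulaInput,
    owas_code,
    owas_score,
    reba_action_levels,
    reba_score,
    risk_level,
    rula_action_levels,
    rula_score,
)
from ergopose.scales import _tables as tables

# Frozen digests of the packaged table CSVs: any edit must be deliberate.
_CSV_SHA256 = {
    "owas_categories.csv": "e6b9db11c0e8891c0bb418592fa87c44171b98c86995ab1b8a2a31e7a5046d94",
    "reba_table_a.csv": "f55092a6443c78c63516aa7ee0c0a6df317b086e210ce6ef7acb56b0546d04b3",
    "reba_table_b.csv": "15370e6820930f1dc7328fbdd918963af9ba195b9becb28628ab0eaee8d48944",
    "reba_table_c.csv": "819484ff5df8c9ad5588d74e87a11dd1ce8f9fb306f9e653a2524290646ef96d",
    "rula_table_a.csv": "8f8e3874c9dd52fc5cd4a6c4dec8f4015b1e3b8ad91eac025fdf218e074f8417",
    "rula_table_b.csv": "fecaa1e4f5e6e3dacea36018923ee03ac60857063d7b76f0140417ef254a864b",
    "rula_table_c.csv": "24b15cbbb8111299510c349bb11b4e9962871a820734485e2ad8aa7dc80887b3",
}


@pytest.mark.parametrize("name, digest", sorted(_CSV_SHA256.items()))
def test_packaged_csv_checksums(name, digest):
    data = resources.files("ergopose.scales").joinpath(f"tables/{name}").read_bytes()
    assert hashlib.sha256(data).hexdigest() == digest


@pytest.mark.parametrize("packaged, reference", [
    (tables.REBA_TABLE_A, ref.reba_table_a()),
    (tables.REBA_TABLE_B, ref.reba_table_b()),
    (tables.REBA_TABLE_C, ref.reba_table_c()),
    (tables.RULA_TABLE_A, ref.rula_table_a()),
    (tables.RULA_TABLE_B, ref.rula_table_b()),
    (tables.RULA_TABLE_C, ref.rula_table_c()),
    (tables.OWAS_CATEGORIES, ref.owas_categories()),
], ids=["reba_a", "reba_b", "reba_c", "rula_a", "rula_b", "rula_c", "owas"])
def test_dual_transcription_equality(packaged, reference):
    """Every packaged table equals the independently laid-out transcription."""
    np.testing.assert_array_equal(packaged, reference)


@pytest.mark.parametrize("table", [tables.REBA_TABLE_A, tables.REBA_TABLE_B, tables.REBA_TABLE_C],
                         ids=["table_a", "table_b", "table_c"])
def test_reba_tables_monotone_in_every_axis(table):
    """Raising any single REBA input level never lowers the table output."""
    for axis in range(table.ndim):
        assert (np.diff(table, axis=axis) >= 0).all()


class TestRebaActionLevels:
    def test_neutral_frame_levels(self, neutral_frame):
        levels = reba_action_levels(neutral_frame)
        assert (levels.trunk_level, levels.neck_level, levels.legs_level) == (1, 1, 1)
        # elbow flexion 0 is outside the 60-100 deg band, hence lower arm level 2
        assert (levels.upper_arm_level, levels.lower_arm_level, levels.wrist_level) == (1, 2, 1)

    @pytest.mark.parametrize("trunk, expected", [(0, 1), (20, 2), (20.5, 3), (60, 3), (61, 4)])
    def test_trunk_bin_boundaries(self, trunk, expected):
        assert reba_action_levels(make_angle_frame(trunk=trunk)).trunk_level == expected

    @pytest.mark.parametrize("knee, expected", [(0, 1), (30, 1), (45, 2), (60, 2), (61, 3)])
    def test_leg_increments(self, knee, expected):
        assert reba_action_levels(make_angle_frame(knee=knee)).legs_level == expected

    @pytest.mark.parametrize("shoulder, expected", [(0, 1), (20, 1), (45, 2), (90, 3), (91, 4)])
    def test_upper_arm_bins(self, shoulder, expected):
        assert reba_action_levels(make_angle_frame(shoulder=shoulder)).upper_arm_level == expected

    @pytest.mark.parametrize("elbow, expected", [(0, 2), (59.9, 2), (60, 1), (100, 1), (101, 2)])
    def test_lower_arm_band(self, elbow, expected):
        assert reba_action_levels(make_angle_frame(elbow=elbow)).lower_arm_level == expected

    def test_wrist_level_always_one(self):
        for flex in ({}, {"trunk": 90, "elbow": 170}):
            assert reba_action_levels(make_angle_frame(**flex)).wrist_level == 1

    def test_invalid_joint_gets_neutral_level_with_warning(self):
        frame = make_angle_frame(trunk=80, valid={"trunk": False})
        levels = reba_action_levels(frame)
        assert levels.trunk_level == 1
        assert any("trunk" in w for w in levels.warnings)


class TestRebaScore:
    def test_all_ones_corner(self):
        res = reba_score(RebaInput(lower_arm_level=1))
        assert (res.score_a, res.score_b, res.score_c, res.total) == (1, 1, 1, 1)
        assert res.risk_level is RiskLevel.NEGLIGIBLE

    def test_total_adds_activity_to_score_c(self):
        res = reba_score(RebaInput(trunk_level=4, neck_level=2, legs_level=3,
                                   upper_arm_level=4, activity_score=1))
        assert res.total == res.score_c + 1
        assert res.score_a == 7 and res.score_b == 5

    def test_out_of_range_level_names_field(self):
        with pytest.raises(ValidationError, match="trunk_level"):
            RebaInput(trunk_level=6)

    def test_exhaustive_sweep_matches_reference_tables_and_range(self):
        ref_a, ref_b, ref_c = ref.reba_table_a(), ref.reba_table_b(), ref.reba_table_c()
        for trunk, neck, legs, ua, la, wr in itertools.product(
            range(1, 6), range(1, 4), range(1, 5), range(1, 7), range(1, 3), range(1, 4)
        ):
            res = reba_score(RebaInput(trunk_level=trunk, neck_level=neck, legs_level=legs,
                                       upper_arm_level=ua, lower_arm_level=la, wrist_level=wr))
            assert res.score_a == ref_a[trunk - 1, neck - 1, legs - 1]
            assert res.score_b == ref_b[ua - 1, la - 1, wr - 1]
            assert res.score_c == ref_c[res.score_a - 1, res.score_b - 1]
            assert 1 <= res.total <= 15

    def test_modifier_extremes_stay_in_range(self):
        res = reba_score(RebaInput(trunk_level=5, neck_level=3, legs_level=4,
                                   upper_arm_level=6, lower_arm_level=2, wrist_level=3,
                                   load_score=3, coupling_score=3, activity_score=3))
        assert res.total == 15
        assert res.risk_level is RiskLevel.VERY_HIGH


class TestRulaActionLevels:
    def test_neutral_frame_levels(self, neutral_frame):
        levels = rula_action_levels(neutral_frame)
        assert (levels.upper_arm_level, levels.neck_level, levels.trunk_level,
                levels.legs_level) == (1, 1, 1, 1)
        assert levels.wrist_level == 1

    @pytest.mark.parametrize("shoulder, expected", [(20, 1), (45, 2), (90, 3), (91, 4)])
    def test_upper_arm_boundary(self, shoulder, expected):
        assert rula_action_levels(make_angle_frame(shoulder=shoulder)).upper_arm_level == expected

    @pytest.mark.parametrize("neck, expected", [(0, 1), (10, 1), (15, 2), (20, 2), (21, 3)])
    def test_neck_bins(self, neck, expected):
        assert rula_action_levels(make_angle_frame(neck=neck)).neck_level == expected


class TestRulaScore:
    def test_all_ones_corner(self):
        res = rula_score(RulaInput(lower_arm_level=1))
        assert res.grand_score == 1
        assert res.action_level == 1
        assert res.risk_level is RiskLevel.LOW

    def test_action_level_follows_grand_score(self):
        expected = {1: 1, 2: 1, 3: 2, 4: 2, 5: 3, 6: 3, 7: 4}
        seen = set()
        for ua, la, trunk in itertools.product(range(1, 7), range(1, 4), range(1, 7)):
            res = rula_score(RulaInput(upper_arm_level=ua, lower_arm_level=la,
                                       trunk_level=trunk))
            assert res.action_level == expected[res.grand_score]
            seen.add(res.grand_score)
        assert seen == set(range(1, 8))  # every grand score is reachable

    def test_exhaustive_sweep_matches_reference_tables_and_range(self):
        ref_a, ref_b, ref_c = ref.rula_table_a(), ref.rula_table_b(), ref.rula_table_c()
        for ua, la, wr, tw, neck, trunk, legs in itertools.product(
            range(1, 7), range(1, 4), range(1, 5), range(1, 3),
            range(1, 7), range(1, 7), range(1, 3)
        ):
            res = rula_score(RulaInput(upper_arm_level=ua, lower_arm_level=la, wrist_level=wr,
                                       wrist_twist=tw, neck_level=neck, trunk_level=trunk,
                                       legs_level=legs))
            assert res.score_a == ref_a[ua - 1, la - 1, wr - 1, tw - 1]
            assert res.score_b == ref_b[neck - 1, trunk - 1, legs - 1]
            assert res.grand_score == ref_c[min(res.score_a, 8) - 1, min(res.score_b, 7) - 1]
            assert 1 <= res.grand_score <= 7

    def test_force_additions_saturate_table_c_indices(self):
        res = rula_score(RulaInput(upper_arm_level=6, lower_arm_level=3, wrist_level=4,
                                   wrist_twist=2, neck_level=6, trunk_level=6, legs_level=2,
                                   muscle_use_a=1, force_a=3, muscle_use_b=1, force_b=3))
        assert res.grand_score == 7
        assert res.risk_level is RiskLevel.HIGH


class TestOwas:
    def test_neutral_standing_code(self, neutral_frame):
        code = owas_code(neutral_frame, load_class=1)
        assert (code.back, code.arms, code.legs, code.load_class) == (1, 1, 2, 1)
        assert owas_score(code).action_category == 1

    @pytest.mark.parametrize("trunk, back", [(20, 1), (20.1, 2), (45, 2)])
    def test_back_threshold(self, trunk, back):
        assert owas_code(make_angle_frame(trunk=trunk)).back == back

    def test_arms_above_shoulder_level(self):
        assert owas_code(make_angle_frame(shoulder=120)).arms == 3  # both assumed raised
        assert owas_code(make_angle_frame(shoulder=120), other_shoulder_flexion=30).arms == 2
        assert owas_code(make_angle_frame(shoulder=60)).arms == 1

    def test_legs_coding(self):
        # deep knee bend at standing hip height: squatting, both knees bent
        assert owas_code(make_angle_frame(knee=95, hip_drop_ratio=0.68)).legs == 4
        # deep knee bend with the hip dropped to seat height: sitting
        assert owas_code(make_angle_frame(knee=95, hip_drop_ratio=0.48)).legs == 1
        assert owas_code(make_angle_frame(knee=10)).legs == 2
        assert owas_code(make_angle_frame(knee=45)).legs == 4

    def test_fully_neutral_code_is_category_1(self):
        assert owas_score(OwasCode(1, 1, 1, 1)).action_category == 1

    def test_invalid_load_class_rejected(self, neutral_frame):
        with pytest.raises(ValidationError):
            owas_code(neutral_frame, load_class=4)

    def test_exhaustive_sweep_matches_reference_and_range(self):
        ref_table = ref.owas_categories()
        for back, arms, legs, load in itertools.product(
            range(1, 5), range(1, 4), range(1, 8), range(1, 4)
        ):
            res = owas_score(OwasCode(back, arms, legs, load))
            assert res.action_category == ref_table[back - 1, arms - 1, legs - 1, load - 1]
            assert 1 <= res.action_category <= 4


class TestRiskLevel:
    @pytest.mark.parametrize("scale, score, expected", [
        ("REBA", 1, RiskLevel.NEGLIGIBLE),
        ("REBA", 2, RiskLevel.LOW),
        ("REBA", 3, RiskLevel.LOW),
        ("REBA", 7, RiskLevel.MEDIUM),
        ("REBA", 8, RiskLevel.HIGH),
        ("REBA", 10, RiskLevel.HIGH),
        ("REBA", 11, RiskLevel.VERY_HIGH),
        ("RULA", 1, RiskLevel.LOW),
        ("RULA", 5, RiskLevel.MEDIUM),
        ("RULA", 6, RiskLevel.MEDIUM),
        ("RULA", 7, RiskLevel.HIGH),
        ("OWAS", 1, RiskLevel.NEGLIGIBLE),
        ("OWAS", 2, RiskLevel.LOW),
        ("OWAS", 3, RiskLevel.MEDIUM),
        ("OWAS", 4, RiskLevel.HIGH),
    ])
    def test_band_mapping(self, scale, score, expected):
        assert risk_level(scale, score) is expected

    @pytest.mark.parametrize("scale, hi", [("REBA", 15), ("RULA", 7), ("OWAS", 4)])
    def test_monotone_in_score(self, scale, hi):
        levels = [risk_level(scale, s) for s in range(1, hi + 1)]
        assert all(b >= a for a, b in zip(levels, levels[1:]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            risk_level("REBA", 16)
        with pytest.raises(ValidationError):
            risk_level("OWAS", 0)
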