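"""RULA (Rapid Upper Limb Assessment) scoring.

Table A combines upper arm, lower arm, wrist and wrist twist; Table B neck,
trunk and legs; Table C merges the two (after muscle-use and force additions)
into the 1-7 grand score, which maps onto four action levels.

As with REBA, only sagittal flexion is observable: twist, deviation and
abduction modifiers stay neutral, the wrist posture level is always 1
(no wrist angle in the COCO-18 skeleton) and wrist twist is taken mid-range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ..errors import ValidationError
from ..kinematics import JointAngleFrame
from ._tables import RULA_TABLE_A, RULA_TABLE_B, RULA_TABLE_C
from .risk import RiskLevel, risk_level

_RANGES = {
    "upper_arm_level": (1, 6),
    "lower_arm_level": (1, 3),
    "wrist_level": (1, 4),
    "wrist_twist": (1, 2),
    "neck_level": (1, 6),
    "trunk_level": (1, 6),
    "legs_level": (1, 2),
    "muscle_use_a": (0, 1),
    "muscle_use_b": (0, 1),
    "force_a": (0, 3),
    "force_b": (0, 3),
}


@dataclass
class RulaInput:
    upper_arm_level: int = 1
    lower_arm_level: int = 2
    wrist_level: int = 1
    wrist_twist: int = 1
    neck_level: int = 1
    trunk_level: int = 1
    legs_level: int = 1
    muscle_use_a: int = 0
    force_a: int = 0
    muscle_use_b: int = 0
    force_b: int = 0
    warnings: tuple[str, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        for name, (lo, hi) in _RANGES.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValidationError(f"RULA {name} must be in [{lo}, {hi}], got {v}")


@dataclass(frozen=True)
class RulaResult:
    score_a: int
    score_b: int
    grand_score: int
    action_level: int
    risk_level: RiskLevel


def rula_action_levels(angles: JointAngleFrame) -> RulaInput:
    """Map one frame's flexion angles to RULA posture levels.

    Bin edges are lower-exclusive / upper-inclusive with 0 deg in the lowest
    bin; invalid joints fall back to their neutral level and are listed in
    ``warnings``. Legs are assumed supported (level 1).
    """
    warnings = []

    def flex(joint: str) -> float:
        if angles.valid.get(joint, False):
            return angles.angles[joint]
        warnings.append(f"{joint} invalid; neutral level assumed")
        return 0.0

    shoulder, elbow = flex("shoulder"), flex("elbow")
    neck, trunk = flex("neck"), flex("trunk")

    upper_arm_level = 1 if shoulder <= 20 else 2 if shoulder <= 45 else 3 if shoulder <= 90 else 4
    lower_arm_level = 1 if 60 <= elbow <= 100 else 2
    neck_level = 1 if neck <= 10 else 2 if neck <= 20 else 3
    trunk_level = 1 if trunk == 0 else 2 if trunk <= 20 else 3 if trunk <= 60 else 4
    return RulaInput(
        upper_arm_level=upper_arm_level,
        lower_arm_level=lower_arm_level,
        wrist_level=1,  # wrist angle identically zero
        wrist_twist=1,
        neck_level=neck_level,
        trunk_level=trunk_level,
        legs_level=1,
        warnings=tuple(warnings),
    )


def rula_score(inp: RulaInput) -> RulaResult:
    """Evaluate the RULA tables for one frame's input."""
    score_a = int(RULA_TABLE_A[inp.upper_arm_level - 1, inp.lower_arm_level - 1,
                               inp.wrist_level - 1, inp.wrist_twist - 1])
    score_a += inp.muscle_use_a + inp.force_a
    score_b = int(RULA_TABLE_B[inp.neck_level - 1, inp.trunk_level - 1, inp.legs_level - 1])
    score_b += inp.muscle_use_b + inp.force_b
    grand = int(RULA_TABLE_C[min(score_a, 8) - 1, min(score_b, 7) - 1])
    action_level = 1 if grand <= 2 else 2 if grand <= 4 else 3 if grand <= 6 else 4
    return RulaResult(score_a=score_a, score_b=score_b, grand_score=grand,
                      action_level=action_level, risk_level=risk_level("RULA", grand))
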