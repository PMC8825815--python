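"""REBA (Rapid Entire Body Assessment) scoring.

Score A combines trunk, neck and leg posture levels through Table A plus a
load score; Score B combines upper-arm, lower-arm and wrist levels through
Table B plus a coupling score; Table C merges A and B, and the activity score
is added on top for the final 1-15 total.

Posture levels are derived from sagittal flexion angles only. Modifiers that
need 3D information (twist, side-bend, abduction, shoulder raise, wrist
deviation) are unobservable in a single side view and fixed at neutral; the
wrist level is always 1 because no wrist angle can be measured from the
COCO-18 skeleton.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ..errors import ValidationError
from ..kinematics import JointAngleFrame
from ._tables import REBA_TABLE_A, REBA_TABLE_B, REBA_TABLE_C
from .risk import RiskLevel, risk_level

_RANGES = {
    "trunk_level": (1, 5),
    "neck_level": (1, 3),
    "legs_level": (1, 4),
    "upper_arm_level": (1, 6),
    "lower_arm_level": (1, 2),
    "wrist_level": (1, 3),
    "load_score": (0, 3),
    "coupling_score": (0, 3),
    "activity_score": (0, 3),
}


@dataclass
class RebaInput:
    """Posture levels plus load/coupling/activity modifiers."""

    trunk_level: int = 1
    neck_level: int = 1
    legs_level: int = 1
    upper_arm_level: int = 1
    lower_arm_level: int = 2
    wrist_level: int = 1
    load_score: int = 0
    coupling_score: int = 0
    activity_score: int = 0
    warnings: tuple[str, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        for name, (lo, hi) in _RANGES.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValidationError(f"REBA {name} must be in [{lo}, {hi}], got {v}")


@dataclass(frozen=True)
class RebaResult:
    score_a: int
    score_b: int
    score_c: int
    total: int
    risk_level: RiskLevel


def reba_action_levels(angles: JointAngleFrame) -> RebaInput:
    """Map one frame's flexion angles to REBA posture levels.

    Bin edges are lower-exclusive / upper-inclusive, with 0 deg in the lowest
    bin. An invalid joint falls back to its neutral (0 deg) level and is named
    in ``warnings``. Load, coupling and activity modifiers default to 0 here;
    the pipeline fills them from its configuration.
    """
    warnings = []

    def flex(joint: str) -> float:
        if angles.valid.get(joint, False):
            return angles.angles[joint]
        warnings.append(f"{joint} invalid; neutral level assumed")
        return 0.0

    trunk, neck = flex("trunk"), flex("neck")
    knee, shoulder, elbow = flex("knee"), flex("shoulder"), flex("elbow")

    trunk_level = 1 if trunk == 0 else 2 if trunk <= 20 else 3 if trunk <= 60 else 4
    neck_level = 1 if neck <= 20 else 2
    legs_level = min(4, 1 + (0 if knee <= 30 else 1 if knee <= 60 else 2))
    upper_arm_level = 1 if shoulder <= 20 else 2 if shoulder <= 45 else 3 if shoulder <= 90 else 4
    lower_arm_level = 1 if 60 <= elbow <= 100 else 2
    return RebaInput(
        trunk_level=trunk_level,
        neck_level=neck_level,
        legs_level=legs_level,
        upper_arm_level=upper_arm_level,
        lower_arm_level=lower_arm_level,
        wrist_level=1,  # wrist angle identically zero
        warnings=tuple(warnings),
    )


def reba_score(inp: RebaInput) -> RebaResult:
    """Evaluate the REBA tables for one frame's input."""
    score_a = int(REBA_TABLE_A[inp.trunk_level - 1, inp.neck_level - 1, inp.legs_level - 1])
    score_a += inp.load_score
    score_b = int(REBA_TABLE_B[inp.upper_arm_level - 1, inp.lower_arm_level - 1, inp.wrist_level - 1])
    score_b += inp.coupling_score
    score_c = int(REBA_TABLE_C[score_a - 1, score_b - 1])
    total = score_c + inp.activity_score
    return RebaResult(score_a=score_a, score_b=score_b, score_c=score_c, total=total,
                      risk_level=risk_level("REBA", total))
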