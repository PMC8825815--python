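"""OWAS (Ovako Working Posture Analysing System) coding and scoring.

An OWAS observation is a four-digit code — back (1-4), arms (1-3), legs
(1-7), load (1-3) — looked up in the standard 4x3x7x3 action-category table.

The angle-to-code mapping here is a 2D reconstruction: a single sagittal
view cannot see back twist (codes 3-4), distinguish one arm from the other,
or detect walking/kneeling, so those codes are unreachable. Sitting is
separated from squatting by the hip-drop cue carried on the angle frame
(hip-to-ankle vertical drop over leg-chain length; sitting ~0.5, squat ~0.7).
"""

from __future__ import annotations

from dataclasses import dataclass

from ..errors import ValidationError
from ..kinematics import SEATED_HIP_DROP_RATIO, JointAngleFrame
from ._tables import OWAS_CATEGORIES
from .risk import RiskLevel, risk_level

_RANGES = {"back": (1, 4), "arms": (1, 3), "legs": (1, 7), "load_class": (1, 3)}


@dataclass(frozen=True)
class OwasCode:
    back: int
    arms: int
    legs: int
    load_class: int = 1

    def __post_init__(self) -> None:
        for name, (lo, hi) in _RANGES.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValidationError(f"OWAS {name} must be in [{lo}, {hi}], got {v}")


@dataclass(frozen=True)
class OwasResult:
    action_category: int
    risk_level: RiskLevel


def owas_code(
    angles: JointAngleFrame,
    load_class: int = 1,
    other_shoulder_flexion: float | None = None,
) -> OwasCode:
    """Derive the OWAS posture code from one frame's flexion angles.

    back: 1 (straight) if trunk flexion <= 20 deg, else 2 (bent).
    arms: below/above shoulder level from shoulder flexion (> 90 deg = above);
          the contralateral arm is assumed equal unless
          ``other_shoulder_flexion`` is given.
    legs: 1 (sitting) when the knee is deeply bent and the hip has dropped to
          seated height; 2 (standing, both legs straight) when knee flexion
          <= 30 deg; otherwise 4 (standing/squatting, both knees bent).
    Invalid joints take their neutral reading (0 deg).
    """
    if not 1 <= load_class <= 3:
        raise ValidationError(f"OWAS load_class must be in [1, 3], got {load_class}")

    def flex(joint: str) -> float:
        return angles.angles[joint] if angles.valid.get(joint, False) else 0.0

    trunk, shoulder, knee = flex("trunk"), flex("shoulder"), flex("knee")
    back = 1 if trunk <= 20 else 2

    other = shoulder if other_shoulder_flexion is None else other_shoulder_flexion
    above = (shoulder > 90) + (other > 90)
    arms = 1 if above == 0 else 2 if above == 1 else 3

    seated = (
        knee > 60
        and angles.hip_drop_ratio is not None
        and angles.hip_drop_ratio < SEATED_HIP_DROP_RATIO
    )
    legs = 1 if seated else 2 if knee <= 30 else 4
    return OwasCode(back=back, arms=arms, legs=legs, load_class=load_class)


def owas_score(code: OwasCode) -> OwasResult:
    """Action category (1-4) of a posture code from the standard OWAS table."""
    cat = int(OWAS_CATEGORIES[code.back - 1, code.arms - 1, code.legs - 1, code.load_class - 1])
    return OwasResult(action_category=cat, risk_level=risk_level("OWAS", cat))
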