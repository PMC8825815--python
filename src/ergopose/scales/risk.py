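"""Risk-level bands for the three instruments.

REBA totals 8-10 are High risk and 11+ Very High; RULA grand scores map to
four action levels, with 7 demanding immediate change (High); OWAS action
categories 1-4 map directly onto the four-band ladder.
"""

from __future__ import annotations

from enum import IntEnum

from ..errors import ValidationError


class RiskLevel(IntEnum):
    """Ordered musculoskeletal-disorder risk bands."""

    NEGLIGIBLE = 0
    LOW = 1
    MEDIUM = 2
    HIGH = 3
    VERY_HIGH = 4

    @property
    def label(self) -> str:
        return _LABELS[self]

    def __str__(self) -> str:
        return _LABELS[self]

    @classmethod
    def from_label(cls, label: str) -> "RiskLevel":
        for lvl, text in _LABELS.items():
            if text == label:
                return lvl
        raise ValidationError(f"unknown risk level label {label!r}")


_LABELS = {
    RiskLevel.NEGLIGIBLE: "Negligible",
    RiskLevel.LOW: "Low",
    RiskLevel.MEDIUM: "Medium",
    RiskLevel.HIGH: "High",
    RiskLevel.VERY_HIGH: "VeryHigh",
}

_BANDS = {
    # scale -> list of (max score of band, level); bands are contiguous from the previous max+1
    "REBA": ((1, RiskLevel.NEGLIGIBLE), (3, RiskLevel.LOW), (7, RiskLevel.MEDIUM),
             (10, RiskLevel.HIGH), (15, RiskLevel.VERY_HIGH)),
    "RULA": ((2, RiskLevel.LOW), (6, RiskLevel.MEDIUM), (7, RiskLevel.HIGH)),
    "OWAS": ((1, RiskLevel.NEGLIGIBLE), (2, RiskLevel.LOW), (3, RiskLevel.MEDIUM),
             (4, RiskLevel.HIGH)),
}

_RANGES = {"REBA": (1, 15), "RULA": (1, 7), "OWAS": (1, 4)}


def risk_level(scale: str, score: int) -> RiskLevel:
    """Risk band of a total score under the named scale (REBA, RULA or OWAS)."""
    scale = scale.upper()
    if scale not in _BANDS:
        raise ValidationError(f"unknown scale {scale!r}")
    lo, hi = _RANGES[scale]
    if not lo <= score <= hi:
        raise ValidationError(f"{scale} score must be in [{lo}, {hi}], got {score}")
    for upper, level in _BANDS[scale]:
        if score <= upper:
            return level
    raise AssertionError("unreachable")
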