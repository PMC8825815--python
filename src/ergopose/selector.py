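"""Assessment-scale selection via the three-node decision tree.

Three boolean nodes are evaluated on an operational cycle:

* **repetitive** — the cycle lasts less than 30 s, i.e. fewer than
  30 s x fps frames (strictly; 900 frames at 30 fps is already non-repetitive);
* **upper-limb activity** — the shoulder *or* elbow angle sweeps every REBA
  action-level bin for that joint over the cycle;
* **lower-limb activity** — likewise for the trunk *or* knee.

The branch order is: whole-body activity (upper AND lower) selects REBA;
upper-limb-only activity selects RULA; remaining repetitive work selects
OWAS; otherwise none of the three instruments applies.

For trunk and knee, "every bin" means every *occupiable* bin: the level-1
trunk bin is the single point 0 deg, which real (and noisy) data occupy with
probability zero, so it is merged into its neighbour, leaving three trunk
bins ((0,20], (20,60], >60) and three knee bins ([0,30], (30,60], >60).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .errors import ValidationError
from .kinematics import AngleSeries
from .skeleton import MotionSequence


class ScaleChoice(Enum):
    REBA = "REBA"
    RULA = "RULA"
    OWAS = "OWAS"
    NOT_APPLICABLE = "Not Applicable"

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class DecisionNodes:
    """The three decision booleans; all three are always evaluated."""

    repetitive: bool
    upper_limb: bool
    lower_limb: bool

    def pattern(self) -> tuple[str, str, str]:
        return tuple("Y" if v else "N" for v in (self.repetitive, self.upper_limb, self.lower_limb))


@dataclass(frozen=True)
class SelectorConfig:
    cycle_threshold_s: float = 30.0

    def __post_init__(self) -> None:
        if self.cycle_threshold_s <= 0:
            raise ValidationError("cycle_threshold_s must be > 0")


#: Number of REBA action-level bins the coverage nodes require per joint.
#: Bin index functions follow lower-exclusive / upper-inclusive edges.
_BIN_COUNTS = {"shoulder": 4, "elbow": 2, "trunk": 3, "knee": 3}


def _bin_index(joint: str, angle: float) -> int:
    if joint == "shoulder":
        return 0 if angle <= 20 else 1 if angle <= 45 else 2 if angle <= 90 else 3
    if joint == "elbow":
        return 0 if 60 <= angle <= 100 else 1
    if joint == "trunk":
        return 0 if angle <= 20 else 1 if angle <= 60 else 2
    if joint == "knee":
        return 0 if angle <= 30 else 1 if angle <= 60 else 2
    raise ValidationError(f"coverage undefined for joint {joint!r}")


def occupied_bins(series: AngleSeries, joint: str) -> set[int]:
    """Indices of the action-level bins occupied by at least one valid frame."""
    if joint not in _BIN_COUNTS:
        raise ValidationError(f"coverage undefined for joint {joint!r}")
    return {
        _bin_index(joint, f.angles[joint]) for f in series.frames if f.valid.get(joint, False)
    }


def covers_all_levels(series: AngleSeries, joint: str) -> bool:
    """True iff every action-level bin of the joint is occupied by >= 1 valid frame."""
    return len(occupied_bins(series, joint)) == _BIN_COUNTS[joint]


def is_repetitive(sequence: MotionSequence, config: SelectorConfig | None = None) -> bool:
    """True iff the cycle is shorter than the repetitiveness threshold (strict)."""
    config = config or SelectorConfig()
    return len(sequence) < config.cycle_threshold_s * sequence.fps


def evaluate_nodes(
    sequence: MotionSequence,
    series: AngleSeries,
    config: SelectorConfig | None = None,
) -> DecisionNodes:
    """Evaluate all three decision nodes on a cycle and its angle series."""
    return DecisionNodes(
        repetitive=is_repetitive(sequence, config),
        upper_limb=covers_all_levels(series, "shoulder") or covers_all_levels(series, "elbow"),
        lower_limb=covers_all_levels(series, "trunk") or covers_all_levels(series, "knee"),
    )


def select_scale(nodes: DecisionNodes) -> ScaleChoice:
    """Map the three decision booleans to the selected instrument.

    Whole-body activity takes REBA regardless of repetitiveness; upper-limb
    activity alone takes RULA; remaining repetitive operations take OWAS;
    anything else is outside the three instruments' coverage.
    """
    if nodes.upper_limb and nodes.lower_limb:
        return ScaleChoice.REBA
    if nodes.upper_limb:
        return ScaleChoice.RULA
    if nodes.repetitive:
        return ScaleChoice.OWAS
    return ScaleChoice.NOT_APPLICABLE


def decision_trace(
    sequence: MotionSequence,
    series: AngleSeries,
    config: SelectorConfig | None = None,
) -> dict:
    """Auditable record of the node values and what produced them."""
    config = config or SelectorConfig()
    nodes = evaluate_nodes(sequence, series, config)
    return {
        "repetitive": nodes.repetitive,
        "upper_limb": nodes.upper_limb,
        "lower_limb": nodes.lower_limb,
        "frame_count": len(sequence),
        "fps": sequence.fps,
        "frame_threshold": config.cycle_threshold_s * sequence.fps,
        "bin_occupancy": {
            joint: {"occupied": sorted(occupied_bins(series, joint)), "required": count}
            for joint, count in _BIN_COUNTS.items()
        },
        "selected_scale": select_scale(nodes).value,
    }
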