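"""End-to-end assessment: angles -> scale selection -> per-frame scores -> report.

One call to :func:`assess` turns a keypoint sequence covering a single
operational cycle into a per-frame score trace under the automatically
selected instrument; :func:`high_risk_frames` condenses that trace into a
report of the frames an ergonomist should inspect. "High risk" means the
frame's risk band is High or worse (for REBA, total >= 8); the frames
attaining the maximum score are reported separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .errors import PipelineError, ValidationError
from .kinematics import AngleSeries, compute_angle_series, interpolate_missing
from .scales import (
    RebaInput,
    RiskLevel,
    RulaInput,
    owas_code,
    owas_score,
    reba_action_levels,
    reba_score,
    rula_action_levels,
    rula_score,
)
from .selector import (
    ScaleChoice,
    SelectorConfig,
    decision_trace,
    evaluate_nodes,
    select_scale,
)
from .skeleton import DEFAULT_CONFIDENCE_THRESHOLD, MotionSequence

log = logging.getLogger(__name__)

NOT_APPLICABLE_ADVISORY = "suggest select other method"


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the operator can supply that the video cannot.

    ``load_kg`` maps onto scale-specific classes: REBA load score 0 (< 5 kg),
    1 (5-10 kg), 2 (> 10 kg); OWAS load class 1 (< 10 kg), 2 (10-20 kg),
    3 (> 20 kg); RULA force score 0 (< 2 kg), 1 (2-10 kg), 3 (> 10 kg).
    ``activity_score`` None means automatic: +1 when the cycle is repetitive.
    ``force_scale`` overrides the decision tree's choice.
    """

    side: str = "right"
    confidence_threshold: float = DEFAULT_CONFIDENCE_THRESHOLD
    max_gap: int = 15
    cycle_threshold_s: float = 30.0
    load_kg: float = 0.0
    coupling_score: int = 0
    activity_score: int | None = None
    force_scale: ScaleChoice | None = None

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValidationError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.load_kg < 0:
            raise ValidationError("load_kg must be >= 0")

    @property
    def reba_load_score(self) -> int:
        return 0 if self.load_kg < 5 else 1 if self.load_kg <= 10 else 2

    @property
    def owas_load_class(self) -> int:
        return 1 if self.load_kg < 10 else 2 if self.load_kg <= 20 else 3

    @property
    def rula_force_score(self) -> int:
        return 0 if self.load_kg < 2 else 1 if self.load_kg <= 10 else 3


@dataclass(frozen=True)
class FrameScore:
    frame_index: int
    subscores: dict
    total: int
    risk: RiskLevel


@dataclass
class ScoredSequence:
    """Per-frame totals under one instrument, fixed for the whole cycle."""

    scale: ScaleChoice
    per_frame: list[FrameScore]
    fps: float
    trace: dict = field(default_factory=dict)
    advisory: str | None = None
    source_label: str = ""

    @property
    def cumulative_score(self) -> int:
        """Sum of per-frame totals over the cycle (a whole-cycle exposure figure)."""
        return sum(f.total for f in self.per_frame)


@dataclass
class AssessmentReport:
    """Cycle-level summary: worst posture, high-risk frames, and their share."""

    selected_scale: ScaleChoice
    decision_trace: dict
    total_frames: int
    max_score: int | None
    max_risk_level: RiskLevel | None
    high_risk_frame_indices: list[int]
    high_risk_fraction: float
    highest_score_frame_indices: list[int]
    cumulative_score: int
    source_label: str = ""
    advisory: str | None = None

    @property
    def high_risk_count(self) -> int:
        return len(self.high_risk_frame_indices)


def _score_frame(scale: ScaleChoice, angle_frame, config: PipelineConfig,
                 activity: int) -> FrameScore | None:
    """Score one frame under the selected instrument; None if nothing is scoreable."""
    if not any(angle_frame.valid.get(j, False) for j in angle_frame.valid):
        return None
    if scale is ScaleChoice.REBA:
        levels = reba_action_levels(angle_frame)
        inp = RebaInput(
            trunk_level=levels.trunk_level, neck_level=levels.neck_level,
            legs_level=levels.legs_level, upper_arm_level=levels.upper_arm_level,
            lower_arm_level=levels.lower_arm_level, wrist_level=levels.wrist_level,
            load_score=config.reba_load_score, coupling_score=config.coupling_score,
            activity_score=activity, warnings=levels.warnings,
        )
        res = reba_score(inp)
        sub = {"score_a": res.score_a, "score_b": res.score_b, "score_c": res.score_c,
               "activity_score": activity}
        return FrameScore(angle_frame.frame_index, sub, res.total, res.risk_level)
    if scale is ScaleChoice.RULA:
        levels = rula_action_levels(angle_frame)
        inp = RulaInput(
            upper_arm_level=levels.upper_arm_level, lower_arm_level=levels.lower_arm_level,
            wrist_level=levels.wrist_level, wrist_twist=levels.wrist_twist,
            neck_level=levels.neck_level, trunk_level=levels.trunk_level,
            legs_level=levels.legs_level,
            force_a=config.rula_force_score, force_b=config.rula_force_score,
            warnings=levels.warnings,
        )
        res = rula_score(inp)
        sub = {"score_a": res.score_a, "score_b": res.score_b, "action_level": res.action_level}
        return FrameScore(angle_frame.frame_index, sub, res.grand_score, res.risk_level)
    if scale is ScaleChoice.OWAS:
        code = owas_code(angle_frame, load_class=config.owas_load_class)
        res = owas_score(code)
        sub = {"back": code.back, "arms": code.arms, "legs": code.legs,
               "load_class": code.load_class}
        return FrameScore(angle_frame.frame_index, sub, res.action_category, res.risk_level)
    raise ValidationError(f"cannot score under {scale}")


def compute_angles(sequence: MotionSequence, config: PipelineConfig | None = None) -> AngleSeries:
    """Angle series for a sequence, with short dropout gaps interpolated."""
    config = config or PipelineConfig()
    series = compute_angle_series(sequence, config.side, config.confidence_threshold)
    return interpolate_missing(series, config.max_gap)


def assess(sequence: MotionSequence, config: PipelineConfig | None = None) -> ScoredSequence:
    """Assess one operational cycle end to end.

    Scale selection depends only on the angle series and cycle duration,
    never on the scores. Frames whose five joints are all invalid are not
    scoreable; if no frame is scoreable the assessment fails.
    """
    config = config or PipelineConfig()
    series = compute_angles(sequence, config)
    sel_cfg = SelectorConfig(cycle_threshold_s=config.cycle_threshold_s)
    nodes = evaluate_nodes(sequence, series, sel_cfg)
    trace = decision_trace(sequence, series, sel_cfg)
    scale = config.force_scale or select_scale(nodes)
    if config.force_scale is not None:
        trace["forced_scale"] = config.force_scale.value
    log.info("selected scale %s (nodes %s)", scale, nodes.pattern())

    if not any(any(f.valid.values()) for f in series.frames):
        raise PipelineError("no scoreable frames")

    if scale is ScaleChoice.NOT_APPLICABLE:
        return ScoredSequence(scale=scale, per_frame=[], fps=sequence.fps, trace=trace,
                              advisory=NOT_APPLICABLE_ADVISORY,
                              source_label=sequence.source_label)

    activity = config.activity_score
    if activity is None:
        activity = 1 if nodes.repetitive else 0

    per_frame = []
    for angle_frame in series.frames:
        scored = _score_frame(scale, angle_frame, config, activity)
        if scored is not None:
            per_frame.append(scored)
    if not per_frame:
        raise PipelineError("no scoreable frames")
    return ScoredSequence(scale=scale, per_frame=per_frame, fps=sequence.fps, trace=trace,
                          source_label=sequence.source_label)


def high_risk_frames(scored: ScoredSequence) -> AssessmentReport:
    """Identify the frames whose risk band is High or worse, plus the score maxima."""
    if not scored.per_frame:
        if scored.scale is ScaleChoice.NOT_APPLICABLE:
            return AssessmentReport(
                selected_scale=scored.scale, decision_trace=scored.trace,
                total_frames=0, max_score=None, max_risk_level=None,
                high_risk_frame_indices=[], high_risk_fraction=0.0,
                highest_score_frame_indices=[], cumulative_score=0,
                source_label=scored.source_label, advisory=scored.advisory,
            )
        raise PipelineError("cannot summarise an empty scored sequence")
    totals = [f.total for f in scored.per_frame]
    max_score = max(totals)
    high = [f.frame_index for f in scored.per_frame if f.risk >= RiskLevel.HIGH]
    argmax = [f.frame_index for f in scored.per_frame if f.total == max_score]
    n = len(scored.per_frame)
    return AssessmentReport(
        selected_scale=scored.scale,
        decision_trace=scored.trace,
        total_frames=n,
        max_score=max_score,
        max_risk_level=max(f.risk for f in scored.per_frame),
        high_risk_frame_indices=high,
        high_risk_fraction=len(high) / n,
        highest_score_frame_indices=argmax,
        cumulative_score=scored.cumulative_score,
        source_label=scored.source_label,
        advisory=scored.advisory,
    )


@dataclass
class Summary:
    """Aggregate over several operations' reports."""

    table: pd.DataFrame
    pooled_high_risk_count: int
    pooled_total_frames: int

    @property
    def pooled_high_risk_fraction(self) -> float:
        if self.pooled_total_frames == 0:
            return 0.0
        return self.pooled_high_risk_count / self.pooled_total_frames


def summarize(reports: list[AssessmentReport]) -> Summary:
    """Per-operation rows plus the pooled high-risk fraction (sum / sum)."""
    if not reports:
        raise PipelineError("summarize requires at least one report")
    rows = []
    for r in reports:
        rows.append({
            "operation": r.source_label,
            "scale": r.selected_scale.value,
            "total_frames": r.total_frames,
            "max_score": r.max_score,
            "risk_level": str(r.max_risk_level) if r.max_risk_level is not None else None,
            "high_risk_frames": r.high_risk_count,
            "high_risk_pct": 100.0 * r.high_risk_fraction,
        })
    return Summary(
        table=pd.DataFrame(rows),
        pooled_high_risk_count=sum(r.high_risk_count for r in reports),
        pooled_total_frames=sum(r.total_frames for r in reports),
    )
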