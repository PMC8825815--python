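"""Joint-angle kinematics from 2D keypoints.

Each of the five assessed joints (neck, trunk, knee, shoulder, elbow) is
defined by an ordered triple of keypoints with the joint at the vertex. The
included angle at the vertex b between points a and c is

    A = acos( (a - b) . (c - b) / (|a - b| |c - b|) ) * 180 / pi

and is convention-agnostic: it is invariant under translation, rotation,
reflection and uniform scaling of the image, so the image y-down convention
never leaks into the scores.

Included angles are converted to flexion angles (0 deg = neutral) before the
ergonomic scales consume them. For neck, trunk, knee and elbow the defining
triple is collinear at neutral (included 180 deg), so flexion = 180 - included;
the shoulder triple (hip, shoulder, elbow) is folded at neutral (arm hanging
along the trunk, included 0 deg), so flexion equals the included angle. The
wrist is not observable in the COCO-18 layout and is fixed at 0 deg.

Only a single sagittal view is available, so flexion and extension are not
distinguished: any deviation from neutral reads as flexion.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError
from .skeleton import DEFAULT_CONFIDENCE_THRESHOLD, MotionSequence, SkeletonFrame

log = logging.getLogger(__name__)

#: Ordered (a, vertex, c) keypoint triple defining each joint angle. Names are
#: side-generic; they resolve to ``r_``/``l_`` slots per the chosen body side
#: (``neck`` is unpaired).
JOINT_TRIPLES: dict[str, tuple[str, str, str]] = {
    "neck": ("ear", "neck", "hip"),
    "trunk": ("neck", "hip", "knee"),
    "knee": ("hip", "knee", "ankle"),
    "shoulder": ("hip", "shoulder", "elbow"),
    "elbow": ("shoulder", "elbow", "wrist"),
}

#: The five computed joints, in canonical order.
ANGLE_JOINTS: tuple[str, ...] = ("neck", "trunk", "knee", "shoulder", "elbow")

_UNPAIRED = {"neck", "nose"}

#: Hip drop ratio below which (with a deeply bent knee) the posture is treated
#: as seated rather than squatting. Sitting places the hip roughly one shank
#: length above the ankle (ratio ~0.5 of the leg chain); a deep squat keeps it
#: noticeably higher (~0.7).
SEATED_HIP_DROP_RATIO = 0.6


def _sided(name: str, side: str) -> str:
    if name in _UNPAIRED:
        return name
    return f"{side[0]}_{name}"


def included_angle(p_a, p_b, p_c) -> float:
    """Included angle in degrees at vertex ``p_b``, in [0, 180].

    The acos argument is clamped to [-1, 1]: floating-point dot products of
    near-collinear unit vectors can exceed 1 in magnitude by ~1e-16.

    Raises :class:`ValidationError` if either vector has zero length.
    """
    v_j = np.asarray(p_a, dtype=float) - np.asarray(p_b, dtype=float)
    v_k = np.asarray(p_c, dtype=float) - np.asarray(p_b, dtype=float)
    n_j = math.hypot(*v_j)
    n_k = math.hypot(*v_k)
    if n_j == 0.0 or n_k == 0.0:
        raise ValidationError("included_angle: zero-length vector at vertex")
    cosine = float(np.dot(v_j, v_k)) / (n_j * n_k)
    cosine = max(-1.0, min(1.0, cosine))
    return math.degrees(math.acos(cosine))


def to_flexion(joint: str, included: float) -> float:
    """Convert an included angle to the joint's flexion angle (0 = neutral)."""
    if joint in ("neck", "trunk", "knee", "elbow"):
        return 180.0 - included
    if joint == "shoulder":
        return included
    raise ValidationError(f"unknown joint {joint!r}")


@dataclass
class JointAngleFrame:
    """The five flexion angles of one frame, plus the wrist-at-zero rule.

    ``angles`` holds flexion degrees in [0, 180]; a joint whose defining
    keypoints were missing (or degenerate) is flagged invalid in ``valid`` and
    carries NaN. ``substituted`` lists joints computed with a contralateral
    stand-in keypoint. ``hip_drop_ratio`` is the hip-to-ankle vertical drop
    divided by the leg-chain length (thigh + shank); it is the posture-height
    cue the OWAS leg coding uses to separate sitting from standing, and is
    None when the leg keypoints are unavailable.
    """

    frame_index: int
    side: str
    angles: dict[str, float]
    valid: dict[str, bool]
    substituted: frozenset = frozenset()
    hip_drop_ratio: float | None = None
    interpolated: frozenset = frozenset()

    #: The wrist joint angle is identically zero: the COCO-18 skeleton has no
    #: hand keypoint, so no wrist angle can be measured.
    wrist: float = field(default=0.0, init=False)

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValidationError(f"side must be 'left' or 'right', got {self.side!r}")
        missing = set(ANGLE_JOINTS) - self.angles.keys()
        if missing:
            raise ValidationError(f"angles missing joints: {sorted(missing)}")

    def angle(self, joint: str) -> float:
        """Flexion angle of a *valid* joint; raises if the joint is invalid."""
        if joint == "wrist":
            return 0.0
        if not self.valid.get(joint, False):
            raise ValidationError(f"joint {joint!r} is invalid in frame {self.frame_index}")
        return self.angles[joint]

    @property
    def neck(self) -> float:
        return self.angles["neck"]

    @property
    def trunk(self) -> float:
        return self.angles["trunk"]

    @property
    def knee(self) -> float:
        return self.angles["knee"]

    @property
    def shoulder(self) -> float:
        return self.angles["shoulder"]

    @property
    def elbow(self) -> float:
        return self.angles["elbow"]


@dataclass
class AngleSeries:
    """Per-frame joint angles for a whole sequence, frame-aligned to its source."""

    frames: list[JointAngleFrame]
    fps: float

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def angle_array(self, joint: str) -> np.ndarray:
        """Flexion series for one joint; NaN where the joint is invalid."""
        return np.array(
            [f.angles[joint] if f.valid[joint] else np.nan for f in self.frames], dtype=float
        )

    def valid_mask(self, joint: str) -> np.ndarray:
        return np.array([f.valid[joint] for f in self.frames], dtype=bool)


def compute_joint_angles(
    frame: SkeletonFrame,
    side: str = "right",
    confidence_threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
) -> JointAngleFrame:
    """Compute the five flexion angles of one frame for the chosen body side.

    If a keypoint of the chosen side is missing, the contralateral point
    substitutes and the joint is flagged in ``substituted``; if neither side
    is available (or the triple is geometrically degenerate) the joint is
    flagged invalid. No exception is raised for missing data.
    """
    if side not in ("left", "right"):
        raise ValidationError(f"side must be 'left' or 'right', got {side!r}")
    other = "left" if side == "right" else "right"

    def resolve(name: str) -> tuple[np.ndarray | None, bool]:
        """(point, substituted) for a side-generic keypoint name."""
        primary = _sided(name, side)
        if not frame.is_missing(primary, confidence_threshold):
            return frame.point(primary), False
        if name in _UNPAIRED:
            return None, False
        fallback = _sided(name, other)
        if not frame.is_missing(fallback, confidence_threshold):
            return frame.point(fallback), True
        return None, False

    angles: dict[str, float] = {}
    valid: dict[str, bool] = {}
    substituted: set[str] = set()
    for joint, (a, b, c) in JOINT_TRIPLES.items():
        points = []
        subbed = False
        for name in (a, b, c):
            pt, sub = resolve(name)
            points.append(pt)
            subbed = subbed or sub
        if any(p is None for p in points):
            angles[joint] = float("nan")
            valid[joint] = False
            continue
        try:
            inc = included_angle(*points)
        except ValidationError:
            log.warning("frame %d: degenerate %s triple, joint marked invalid",
                        frame.frame_index, joint)
            angles[joint] = float("nan")
            valid[joint] = False
            continue
        angles[joint] = to_flexion(joint, inc)
        valid[joint] = True
        if subbed:
            substituted.add(joint)

    hip_drop = _hip_drop_ratio(frame, side, other, confidence_threshold)
    return JointAngleFrame(
        frame_index=frame.frame_index,
        side=side,
        angles=angles,
        valid=valid,
        substituted=frozenset(substituted),
        hip_drop_ratio=hip_drop,
    )


def _hip_drop_ratio(frame, side, other, threshold):
    """Hip-to-ankle vertical drop over thigh+shank length; None if unavailable."""
    pts = {}
    for name in ("hip", "knee", "ankle"):
        for s in (side, other):
            key = _sided(name, s)
            if not frame.is_missing(key, threshold):
                pts[name] = frame.point(key)
                break
        else:
            return None
    chain = float(
        np.linalg.norm(pts["hip"] - pts["knee"]) + np.linalg.norm(pts["knee"] - pts["ankle"])
    )
    if chain == 0.0:
        return None
    # image y grows downward, so ankle_y - hip_y is the standing-height drop
    return float(pts["ankle"][1] - pts["hip"][1]) / chain


def compute_angle_series(
    sequence: MotionSequence,
    side: str = "right",
    confidence_threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
) -> AngleSeries:
    """Angle series for every frame of a sequence."""
    return AngleSeries(
        frames=[compute_joint_angles(f, side, confidence_threshold) for f in sequence.frames],
        fps=sequence.fps,
    )


def interpolate_missing(series: AngleSeries, max_gap: int = 15) -> AngleSeries:
    """Fill short invalid runs per joint by linear interpolation.

    Runs of at most ``max_gap`` consecutive invalid frames bounded by valid
    frames on both sides are filled linearly (in frame index); longer runs and
    leading/trailing runs stay invalid — angles are never extrapolated. Filled
    joints are listed in each frame's ``interpolated`` set. The default gap of
    15 frames corresponds to 0.5 s at 30 fps.
    """
    n = len(series.frames)
    out = [replace(f, angles=dict(f.angles), valid=dict(f.valid)) for f in series.frames]
    for joint in ANGLE_JOINTS:
        valid = series.valid_mask(joint)
        values = series.angle_array(joint)
        i = 0
        while i < n:
            if valid[i]:
                i += 1
                continue
            j = i
            while j < n and not valid[j]:
                j += 1
            gap = j - i
            if i > 0 and j < n and gap <= max_gap:
                lo, hi = i - 1, j
                for k in range(i, j):
                    t = (k - lo) / (hi - lo)
                    out[k].angles[joint] = (1 - t) * values[lo] + t * values[hi]
                    out[k].valid[joint] = True
                    out[k].interpolated = out[k].interpolated | {joint}
            i = j
    return AngleSeries(frames=out, fps=series.fps)
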