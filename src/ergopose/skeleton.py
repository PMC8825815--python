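"""Skeleton containers: the COCO-18 keypoint layout and per-frame / per-sequence types.

The pipeline consumes 2D pose-estimation output in the OpenPose COCO 18-keypoint
layout. Coordinates follow the image convention: x grows rightward, y grows
*downward*. A keypoint with confidence below a validity threshold counts as
missing; OpenPose emits ``(0, 0, 0)`` for undetected points, so missingness is
carried by the confidence channel, never by the coordinates themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

#: Canonical COCO-18 keypoint names, in the OpenPose output order.
COCO18_NAMES: tuple[str, ...] = (
    "nose",
    "neck",
    "r_shoulder",
    "r_elbow",
    "r_wrist",
    "l_shoulder",
    "l_elbow",
    "l_wrist",
    "r_hip",
    "r_knee",
    "r_ankle",
    "l_hip",
    "l_knee",
    "l_ankle",
    "r_eye",
    "l_eye",
    "r_ear",
    "l_ear",
)

COCO18_INDEX: dict[str, int] = {name: i for i, name in enumerate(COCO18_NAMES)}

#: BODY_25 slot feeding each COCO-18 slot. BODY_25 inserts mid-hip at slot 8 and
#: appends six foot points (19-24); both are dropped in the down-mapping.
BODY25_TO_COCO18: tuple[int, ...] = (0, 1, 2, 3, 4, 5, 6, 7, 9, 10, 11, 12, 13, 14, 15, 16, 17, 18)

#: Confidence below this flags a keypoint as missing.
DEFAULT_CONFIDENCE_THRESHOLD = 0.1


@dataclass(frozen=True)
class Keypoint2D:
    """A single named 2D landmark with detector confidence in [0, 1]."""

    x: float
    y: float
    confidence: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValidationError(f"confidence must be in [0, 1], got {self.confidence}")

    def is_missing(self, threshold: float = DEFAULT_CONFIDENCE_THRESHOLD) -> bool:
        return self.confidence < threshold


@dataclass
class SkeletonFrame:
    """One frame's 18 keypoints, stored as an (18, 3) array of (x, y, confidence)."""

    frame_index: int
    keypoints: np.ndarray

    def __post_init__(self) -> None:
        self.keypoints = np.asarray(self.keypoints, dtype=float)
        if self.keypoints.shape != (18, 3):
            raise ValidationError(
                f"frame {self.frame_index}: expected (18, 3) keypoint array, "
                f"got shape {self.keypoints.shape}"
            )
        if self.frame_index < 0:
            raise ValidationError(f"frame_index must be >= 0, got {self.frame_index}")
        conf = self.keypoints[:, 2]
        if np.any((conf < 0) | (conf > 1)):
            raise ValidationError(f"frame {self.frame_index}: confidence outside [0, 1]")

    def point(self, name: str) -> np.ndarray:
        """(x, y) of a named keypoint, regardless of validity."""
        return self.keypoints[COCO18_INDEX[name], :2]

    def confidence(self, name: str) -> float:
        return float(self.keypoints[COCO18_INDEX[name], 2])

    def is_missing(self, name: str, threshold: float = DEFAULT_CONFIDENCE_THRESHOLD) -> bool:
        return self.confidence(name) < threshold

    def keypoint(self, name: str) -> Keypoint2D:
        x, y, c = self.keypoints[COCO18_INDEX[name]]
        return Keypoint2D(float(x), float(y), float(c))

    @classmethod
    def all_missing(cls, frame_index: int) -> "SkeletonFrame":
        """A frame in which no keypoint was detected (all confidences 0)."""
        return cls(frame_index=frame_index, keypoints=np.zeros((18, 3)))


@dataclass
class MotionSequence:
    """An ordered keypoint sequence covering one operational cycle."""

    frames: list[SkeletonFrame]
    fps: float
    source_label: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValidationError("MotionSequence requires at least one frame")
        if self.fps <= 0:
            raise ValidationError(f"fps must be > 0, got {self.fps}")
        idx = [f.frame_index for f in self.frames]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValidationError("frame indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    @property
    def duration_s(self) -> float:
        """Cycle duration implied by the frame count and frame rate."""
        return len(self.frames) / self.fps
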