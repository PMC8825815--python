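"""Synthetic sagittal-plane stick-figure sequences (forward kinematics).

This module is the inverse of :mod:`ergopose.kinematics`: it places COCO-18
keypoints so that re-applying the three-point angle definitions recovers the
specified flexion angles exactly (to floating point). Every downstream stage
— I/O round-trips, angle recovery, scale selection, scoring — is therefore
testable without any video or pose-estimation run.

The figure is planar and faces +x; image y grows downward. Segment direction
angles are measured from straight-down (+y), positive toward +x, so with
thigh tilt beta = knee_flexion / 2 the chain is

    hip -> knee        : beta
    knee -> ankle      : beta - knee_flexion          (shank swings back)
    hip -> neck        : beta + 180 - trunk_flexion   (trunk leans forward)
    neck -> ear        : beta + 180 - trunk - neck    (head nods forward)
    shoulder -> elbow  : beta - trunk + shoulder      (arm raises forward)
    elbow -> wrist     : beta - trunk + shoulder + elbow_flexion

The shoulder keypoint is co-located with the neck so that the hip-shoulder
line IS the trunk line, making the shoulder included angle exactly the
arm-to-trunk flexion. Contralateral paired points are the same pose shifted
by a small constant depth offset (synthetic placeholders — a real detector
would see genuinely different contralateral coordinates); eyes and nose are
decorative offsets from the ear and never enter any angle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError
from .skeleton import COCO18_INDEX, MotionSequence, SkeletonFrame

#: Detector confidence assigned to every rendered (non-dropped) keypoint.
SYNTH_CONFIDENCE = 0.9

_FLEXION_FIELDS = ("trunk_flexion", "neck_flexion", "shoulder_flexion", "elbow_flexion", "knee_flexion")


@dataclass(frozen=True)
class PostureSpec:
    """A static posture given as the five flexion angles, degrees, 0 = neutral upright."""

    trunk_flexion: float = 0.0
    neck_flexion: float = 0.0
    shoulder_flexion: float = 0.0
    elbow_flexion: float = 0.0
    knee_flexion: float = 0.0

    def __post_init__(self) -> None:
        for name in _FLEXION_FIELDS:
            v = getattr(self, name)
            if not 0.0 <= v <= 180.0:
                raise ValidationError(f"{name} must be in [0, 180], got {v}")


@dataclass(frozen=True)
class Anthropometry:
    """Segment lengths in pixels; arbitrary but fixed for reproducibility."""

    trunk: float = 180.0
    neck_to_ear: float = 60.0
    upper_arm: float = 110.0
    forearm: float = 100.0
    thigh: float = 150.0
    shank: float = 140.0
    depth_offset: float = 6.0

    def __post_init__(self) -> None:
        for name in ("trunk", "neck_to_ear", "upper_arm", "forearm", "thigh", "shank"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"segment length {name} must be > 0")


@dataclass(frozen=True)
class NoiseSpec:
    """Isotropic Gaussian coordinate noise plus per-keypoint dropout.

    Dropout marks a keypoint missing (confidence 0) rather than perturbing
    it, exercising the missing-data path downstream. Identical seeds yield
    identical sequences.
    """

    coordinate_sd: float = 0.0
    dropout_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coordinate_sd < 0:
            raise ValidationError("coordinate_sd must be >= 0")
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ValidationError("dropout_prob must be in [0, 1]")


@dataclass
class MotionProfile:
    """Keypose-defined joint-angle trajectory over one operational cycle."""

    keyposes: list[tuple[float, PostureSpec]]
    cycle_duration: float
    fps: float = 30.0
    anthropometry: Anthropometry = field(default_factory=Anthropometry)
    label: str = ""

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValidationError("fps must be > 0")
        if self.cycle_duration <= 0:
            raise ValidationError("cycle_duration must be > 0")
        times = [t for t, _ in self.keyposes]
        if not times:
            raise ValidationError("profile requires at least one keypose")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValidationError("keypose times must be strictly increasing")
        if times[0] < 0 or times[-1] > self.cycle_duration:
            raise ValidationError("keypose times must lie within [0, cycle_duration]")

    def pose_at(self, t: float) -> PostureSpec:
        """Linearly interpolated posture at time ``t`` (clamped at the ends)."""
        times = np.array([kt for kt, _ in self.keyposes])
        kwargs = {}
        for name in _FLEXION_FIELDS:
            vals = np.array([getattr(p, name) for _, p in self.keyposes])
            kwargs[name] = float(np.interp(t, times, vals))
        return PostureSpec(**kwargs)


def _dir(angle_deg: float) -> np.ndarray:
    """Unit vector at ``angle_deg`` from straight-down (+y), positive toward +x."""
    r = math.radians(angle_deg)
    return np.array([math.sin(r), math.cos(r)])


def pose_to_keypoints(
    pose: PostureSpec,
    anthropometry: Anthropometry | None = None,
    root_position=(320.0, 400.0),
    frame_index: int = 0,
) -> SkeletonFrame:
    """Render a posture to an 18-slot keypoint frame (sagittal view, right side).

    Construction guarantee: applying :func:`ergopose.kinematics.compute_joint_angles`
    to the output recovers the input flexion angles to floating-point accuracy.
    """
    a = anthropometry or Anthropometry()
    beta = pose.knee_flexion / 2.0  # thigh tilts forward as the knee bends
    t, n = pose.trunk_flexion, pose.neck_flexion
    s, e = pose.shoulder_flexion, pose.elbow_flexion

    hip = np.asarray(root_position, dtype=float)
    knee = hip + a.thigh * _dir(beta)
    ankle = knee + a.shank * _dir(beta - pose.knee_flexion)
    neck = hip + a.trunk * _dir(beta + 180.0 - t)
    ear = neck + a.neck_to_ear * _dir(beta + 180.0 - t - n)
    shoulder = neck.copy()  # co-located: hip->shoulder is the trunk line
    elbow = shoulder + a.upper_arm * _dir(beta - t + s)
    wrist = elbow + a.forearm * _dir(beta - t + s + e)
    # decorative head points, never used in angle triples
    eye = ear + np.array([0.30 * a.neck_to_ear, -0.10 * a.neck_to_ear])
    nose = ear + np.array([0.45 * a.neck_to_ear, 0.05 * a.neck_to_ear])

    kp = np.zeros((18, 3))
    off = np.array([a.depth_offset, 0.0])
    placements = {
        "nose": nose,
        "neck": neck,
        "r_shoulder": shoulder,
        "r_elbow": elbow,
        "r_wrist": wrist,
        "l_shoulder": shoulder + off,
        "l_elbow": elbow + off,
        "l_wrist": wrist + off,
        "r_hip": hip,
        "r_knee": knee,
        "r_ankle": ankle,
        "l_hip": hip + off,
        "l_knee": knee + off,
        "l_ankle": ankle + off,
        "r_eye": eye,
        "l_eye": eye + off,
        "r_ear": ear,
        "l_ear": ear + off,
    }
    for name, xy in placements.items():
        kp[COCO18_INDEX[name], :2] = xy
        kp[COCO18_INDEX[name], 2] = SYNTH_CONFIDENCE
    return SkeletonFrame(frame_index=frame_index, keypoints=kp)


def generate_sequence(profile: MotionProfile, noise: NoiseSpec | None = None) -> MotionSequence:
    """Render a profile to a keypoint sequence; frame count = round(duration * fps)."""
    noise = noise or NoiseSpec()
    n_frames = round(profile.cycle_duration * profile.fps)
    if n_frames < 1:
        raise ValidationError("profile yields zero frames")
    rng = np.random.default_rng(noise.seed)
    frames = []
    for i in range(n_frames):
        t = i / profile.fps
        frame = pose_to_keypoints(profile.pose_at(t), profile.anthropometry, frame_index=i)
        if noise.coordinate_sd > 0:
            frame.keypoints[:, :2] += rng.normal(0.0, noise.coordinate_sd, size=(18, 2))
        if noise.dropout_prob > 0:
            dropped = rng.random(18) < noise.dropout_prob
            frame.keypoints[dropped, 2] = 0.0
        frames.append(frame)
    return MotionSequence(frames=frames, fps=profile.fps, source_label=profile.label or "synthetic")


def _profile(label, duration, fps, fracs_poses) -> MotionProfile:
    keyposes = [(frac * duration, pose) for frac, pose in fracs_poses]
    return MotionProfile(keyposes=keyposes, cycle_duration=duration, fps=fps, label=label)


def squat_preset(cycle_duration: float = 10.0, fps: float = 30.0) -> MotionProfile:
    """A five-keypose squat cycle: stand, descend, deepest, ascend, stand.

    At the deepest keypose the knee flexes to ~95 deg (thighs near parallel to
    the floor) and the trunk to 65 deg, so the generated cycle sweeps every
    occupiable REBA trunk and knee action-level bin. The first and last
    keyposes are equal (cycle closure).
    """
    stand = PostureSpec(trunk_flexion=2, neck_flexion=5, shoulder_flexion=5,
                        elbow_flexion=5, knee_flexion=2)
    mid = PostureSpec(trunk_flexion=30, neck_flexion=10, shoulder_flexion=20,
                      elbow_flexion=15, knee_flexion=45)
    deep = PostureSpec(trunk_flexion=65, neck_flexion=15, shoulder_flexion=35,
                       elbow_flexion=25, knee_flexion=95)
    return _profile("squat", cycle_duration, fps,
                    [(0.0, stand), (0.3, mid), (0.5, deep), (0.7, mid), (1.0, stand)])


#: Scenario presets and the (repetitive, upper_limb, lower_limb) decision
#: pattern their generated sequences produce. Durations under 30 s make the
#: cycle repetitive; joint sweeps are sized to occupy (or avoid) the REBA
#: action-level bins that the coverage nodes inspect.
_SCENARIOS = {
    "assembly_wholebody": ("Y", "Y", "Y"),
    "office_upper": ("Y", "Y", "N"),
    "handling_lift": ("Y", "N", "N"),
    "static_nonrepetitive": ("N", "Y", "N"),
    "idle": ("N", "N", "N"),
}


def scenario_names() -> tuple[str, ...]:
    return tuple(_SCENARIOS)


def scenario_pattern(name: str) -> tuple[str, str, str]:
    """Decision-node pattern a scenario is constructed to produce."""
    if name not in _SCENARIOS:
        raise ValidationError(f"unknown scenario {name!r}; valid: {sorted(_SCENARIOS)}")
    return _SCENARIOS[name]


def scenario_preset(name: str, cycle_duration: float | None = None, fps: float = 30.0) -> MotionProfile:
    """A motion profile engineered to hit one branch of the selection tree."""
    if name not in _SCENARIOS:
        raise ValidationError(f"unknown scenario {name!r}; valid: {sorted(_SCENARIOS)}")
    if name == "assembly_wholebody":
        # whole-body work: shoulder sweeps all four bins, trunk and knee all three
        dur = cycle_duration or 12.0
        rest = PostureSpec(trunk_flexion=5, neck_flexion=5, shoulder_flexion=5,
                           elbow_flexion=10, knee_flexion=5)
        reach = PostureSpec(trunk_flexion=40, neck_flexion=15, shoulder_flexion=60,
                            elbow_flexion=80, knee_flexion=45)
        peak = PostureSpec(trunk_flexion=70, neck_flexion=25, shoulder_flexion=110,
                           elbow_flexion=30, knee_flexion=80)
        poses = [(0.0, rest), (0.35, reach), (0.55, peak), (0.75, reach), (1.0, rest)]
    elif name == "office_upper":
        # desk work: elbow alternates through both forearm bins, lower body still
        dur = cycle_duration or 8.0
        typing = PostureSpec(trunk_flexion=10, neck_flexion=15, shoulder_flexion=15,
                             elbow_flexion=80, knee_flexion=15)
        reach = PostureSpec(trunk_flexion=12, neck_flexion=10, shoulder_flexion=18,
                            elbow_flexion=30, knee_flexion=15)
        poses = [(0.0, typing), (0.5, reach), (1.0, typing)]
    elif name == "handling_lift":
        # stoop lift with hanging arms: trunk bends but stays within two bins
        dur = cycle_duration or 9.0
        stand = PostureSpec(trunk_flexion=5, neck_flexion=5, shoulder_flexion=8,
                            elbow_flexion=20, knee_flexion=10)
        stoop = PostureSpec(trunk_flexion=50, neck_flexion=15, shoulder_flexion=15,
                            elbow_flexion=20, knee_flexion=25)
        poses = [(0.0, stand), (0.5, stoop), (1.0, stand)]
    elif name == "static_nonrepetitive":
        # long slow upper-limb task, trunk and legs near neutral
        dur = cycle_duration or 35.0
        hold = PostureSpec(trunk_flexion=8, neck_flexion=8, shoulder_flexion=12,
                           elbow_flexion=70, knee_flexion=8)
        extend = PostureSpec(trunk_flexion=8, neck_flexion=8, shoulder_flexion=15,
                             elbow_flexion=30, knee_flexion=8)
        poses = [(0.0, hold), (0.5, extend), (1.0, hold)]
    else:  # idle
        dur = cycle_duration or 32.0
        still = PostureSpec(trunk_flexion=3, neck_flexion=3, shoulder_flexion=4,
                            elbow_flexion=5, knee_flexion=3)
        sway = PostureSpec(trunk_flexion=5, neck_flexion=4, shoulder_flexion=6,
                           elbow_flexion=8, knee_flexion=5)
        poses = [(0.0, still), (0.5, sway), (1.0, still)]
    return _profile(name, dur, fps, poses)
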