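# Methods

## Scope and input contract

`ergopose` assesses a single *operational cycle*: a keypoint sequence that
starts and ends at the same working posture, pre-trimmed by the user. Inputs
are 2D keypoints in the OpenPose COCO 18-point layout (per-frame JSON files,
one combined JSON, or a flat CSV), in image coordinates (y grows downward)
with per-point detector confidences. BODY_25 input is accepted and
down-mapped to the 18 slots by dropping the mid-hip and the six foot points.
Running the pose estimator itself, person tracking across identity switches,
and cycle segmentation are out of scope.

A keypoint with confidence below 0.1 counts as missing (OpenPose emits 0 for
undetected points); the threshold is configurable. When a frame contains
several people, the default policy keeps the person whose valid keypoints
span the largest bounding box — in occupational footage the worker dominates
the frame — with ties broken toward the lowest person index so the choice is
deterministic; a fixed-index policy is available.

## Joint angles

Five joints are computed per frame — neck, trunk, knee, shoulder, elbow —
each from an ordered keypoint triple with the joint at the vertex (see the
README for the triples and the acos formula). The acos argument is clamped
to [−1, 1] because dot products of near-collinear unit vectors can exceed 1
by ~1e−16. Included angles are converted to flexion (0° = neutral): for
neck, trunk, knee and elbow the triple is collinear at neutral, so flexion =
180° − included; the shoulder triple is folded at neutral (arm hanging along
the hip–shoulder line), so flexion = included. The wrist angle is fixed at
0° — the skeleton has no hand point.

Angles are computed on one body side (default right, matching a camera
placed on the worker's right; configurable). If a keypoint of that side is
missing the contralateral point substitutes and the joint is flagged
`substituted`; if neither side is available the joint is invalid for that
frame. Invalid runs of at most 15 frames (0.5 s at 30 fps) bounded by valid
frames are filled by linear interpolation; longer, leading and trailing runs
are never extrapolated.

Because the view is a single sagittal projection, flexion and extension are
indistinguishable — all deviation from neutral reads as flexion — and
twist/side-bend/abduction are unobservable. The corresponding instrument
modifiers are fixed at neutral, so extension- and asymmetry-driven score
increments are unreachable by construction.

## Instruments

The REBA, RULA and OWAS lookup tables are transcribed from the published
instruments and shipped as long-format CSVs loaded at import; the test suite
freezes their SHA-256 digests and compares every cell against a second
transcription kept in a deliberately different (sheet-style) layout, which
is the main guard against transposition typos.

Angle-to-level bins use lower-exclusive / upper-inclusive edges with 0° in
the lowest bin, giving deterministic tie-breaks at the printed edges (20°,
45°, 60°, 90°). An invalid joint takes its neutral level and is named in the
result's warnings.

Operator context the video cannot supply defaults to "none": load/force and
coupling scores 0, OWAS load class 1. A `--load-kg` input maps to the
instrument classes (REBA 0/1/2 at <5 / 5–10 / >10 kg; OWAS 1/2/3 at <10 /
10–20 / >20 kg; RULA force 0/1/3 at <2 / 2–10 / >10 kg). The REBA activity
score defaults to +1 when the cycle is repetitive (a defensible proxy for
"repeated small-range actions"), overridable to any 0–3 value.

OWAS coding from 2D angles is this package's construction: back bent above
20° trunk flexion; arms above shoulder level at >90° shoulder flexion (the
unobserved arm assumed equal unless supplied); legs seated when the knee is
bent >60° *and* the hip has dropped below 0.6 of the leg-chain length above
the ankle (sitting ≈ 0.48 with default proportions, deep squat ≈ 0.68),
standing-straight at ≤30° knee flexion, otherwise both-knees-bent.
Twisted-back, kneeling and walking codes are unreachable from a single view.

## Scale selection

The repetitiveness criterion generalises the 900-frame-at-30-fps cutoff to
frame_count < 30 s × fps, strict (900 frames at 30 fps is non-repetitive).
Limb-activity nodes test whether a joint's angle series occupies every
action-level bin: shoulder 4 bins, elbow 2 (forearm in/out of 60–100°),
trunk and knee 3 each. The trunk's literal level-1 bin is the single point
0°, which noisy data occupy with probability zero, so it is merged into the
(0, 20] bin; the knee uses the three leg-increment bins ([0,30], (30,60],
>60). One frame in a bin counts as occupancy. The branch order — whole-body
→ REBA, upper-only → RULA, remaining repetitive → OWAS, else not applicable
— reproduces all fifteen published operation patterns; lower-limb-only
activity routes to OWAS when repetitive and to "not applicable" otherwise.
The JSON report carries a decision trace (node values, frame threshold, bin
occupancy) for audit.

## High-risk reporting

A frame is high-risk when its risk band is High or worse (REBA total ≥ 8,
RULA grand 7, OWAS category 4). The band criterion, not the score argmax,
defines the reported fraction — a cycle can hold many frames above the High
threshold whose scores differ — but the argmax frames are reported
separately as the single worst postures. Per-frame totals form a time
series; their sum over the cycle is also emitted (`cumulative_score`) for
transparency. Pooling over several operations divides summed high-risk
frames by summed totals.

## Synthetic data

The generator renders a planar stick figure facing +x from five flexion
angles via forward kinematics built to be the exact inverse of the angle
definitions: the shoulder keypoint is co-located with the neck so the
hip–shoulder line is the trunk line, the thigh tilts forward by half the
knee flexion, and contralateral points are the same pose shifted by a 6 px
constant depth offset (synthetic placeholders). Default segment lengths:
trunk 180 px, neck-to-ear 60, upper arm 110, forearm 100, thigh 150, shank
140. Keyposes are linearly interpolated over the cycle; frame count is
round(duration × fps). Noise is isotropic Gaussian on coordinates plus
per-keypoint dropout (confidence set to 0), seeded and reproducible.

The squat preset (five keyposes, 10 s default, closing the cycle; deepest
pose knee 95°/trunk 65°) sweeps all trunk and knee bins. Five scenario
presets are engineered to hit each decision branch: `assembly_wholebody`
(Y,Y,Y → REBA), `office_upper` (Y,Y,N → RULA), `handling_lift` (Y,N,N →
OWAS; a stoop lift with hanging arms), `static_nonrepetitive` (N,Y,N →
RULA) and `idle` (N,N,N → not applicable).

What the generator does *not* emulate: perspective and lens distortion,
genuinely three-dimensional limb excursions, occlusion-correlated (rather
than independent) dropout, detector-specific bias, and a contralateral side
that moves differently from the observed one. Passing tests therefore
demonstrate correctness of the angle math, tables and decision logic under
the stated geometry — not pose-estimator accuracy on real footage.

## Numerical choices and problem sizes

Noise-free forward–inverse recovery is exact to ~1e−13°; tests assert
<1e−6°. The angle formula is checked against an atan2(|cross|, dot) oracle
(<1e−9° on 1000 random triples) and for rigid-transform + scaling
invariance at 1e−6°, relaxed to 2e−5° only at exactly collinear triples
where the acos derivative diverges. Under 2 px coordinate noise the
per-joint recovery MAE over a ~1000-frame squat is 1.0–2.6° (worst: neck,
whose 60 px segment is shortest); the frozen test bound is 3.5°. Table
sweeps are exhaustive (REBA 1 080, RULA 3 456, OWAS 252 combinations).
Default runs use 30 fps cycles of 8–35 s (240–1 050 frames), sizes at which
the full suite and the acceptance script complete in seconds.

## Known limitations

* Flexion vs extension, twist, abduction and left–right asymmetry are
  invisible in one sagittal view; scores are lower bounds in their respect.
* Load, coupling and muscle-use context must be supplied by the operator;
  nothing is estimated from the image.
* OWAS leg codes for kneeling and walking, and back-twist codes, are
  unreachable; the sitting heuristic depends on pixel-space leg geometry.
* The activity-score proxy (repetitive ⇒ +1) is a convention, not a
  measurement of static holding or rapid action.
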