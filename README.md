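# ergopose

Automated ergonomic risk assessment from 2D pose-estimation keypoints.

Work-related musculoskeletal disorders (MSDs) are conventionally assessed by
an ergonomist who watches an operation and scores postures with an
observational instrument — REBA (Rapid Entire Body Assessment), RULA (Rapid
Upper Limb Assessment) or OWAS (Ovako Working Posture Analysing System).
This is slow, subjective, and each instrument only suits certain work:
choosing the wrong one understates risk. `ergopose` automates the whole
chain for a video that has already been run through a 2D pose estimator
(OpenPose, COCO 18-keypoint layout): it computes joint angles from the
keypoints, selects the appropriate instrument with a three-node decision
tree, scores every frame, and flags the high-risk frames so a human expert
can review 3 % of a recording instead of 100 %.

## Method

**Joint angles.** Each joint is defined by an ordered keypoint triple with
the joint at the vertex — neck: (ear, neck, hip); trunk: (neck, hip, knee);
knee: (hip, knee, ankle); shoulder: (hip, shoulder, elbow); elbow:
(shoulder, elbow, wrist). The included angle at vertex *b* is

```
A = acos( (a−b)·(c−b) / (|a−b||c−b|) ) · 180/π
```

which is invariant to translation, rotation and scale of the image, and is
converted to a flexion angle (0° = neutral) per joint. The COCO-18 skeleton
has no hand point, so the wrist angle is fixed at 0°.

**Scale selection.** Three booleans are evaluated on the cycle:
*repetitive* (cycle shorter than 30 s, i.e. fewer than 30 s × fps frames —
900 at 30 fps), *upper-limb activity* (shoulder or elbow angle sweeps every
REBA action-level bin for that joint), and *lower-limb activity* (likewise
for trunk or knee). Upper ∧ lower → REBA; upper only → RULA; otherwise
repetitive → OWAS; else none of the three instruments applies.

**Scoring.** Every frame is scored with the selected instrument using the
published lookup tables (shipped as CSV data, checksummed and verified
against an independent transcription in the tests). Frames whose risk band
is High or worse are reported, together with the frames attaining the
maximum score.

A forward-kinematic stick-figure generator (`ergopose.synthgen`) renders
sagittal-plane keypoint sequences from joint-angle profiles, with Gaussian
keypoint noise and dropout, so the entire pipeline is testable and
benchmarkable without video.

## Worked example

```
$ ergopose synth --preset squat --duration 10 --seed 3 --out squat/
$ ergopose assess --input squat/ --fps 30 --out squat_scores.csv
OWAS: max score 3 (Medium), 0 high-risk frames (0.0%)
```

A 10 s squat cycle is repetitive (300 frames < 900) and sweeps all trunk
and knee action levels but not the shoulder/elbow ones, so the decision
tree routes it to OWAS. The deepest squat postures code as back bent +
both knees bent, action category 3 (Medium risk); no frame reaches the
High band, so the high-risk set is empty. `squat_scores.csv` holds the
per-frame codes and categories and `squat_scores.json` the summary,
including the decision trace (node values and bin occupancy).

The same in Python:

```python
from ergopose import assess, generate_sequence, high_risk_frames, squat_preset

scored = assess(generate_sequence(squat_preset()))
report = high_risk_frames(scored)
print(report.selected_scale, report.max_score, report.max_risk_level)
# ScaleChoice.OWAS 3 Medium
```

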