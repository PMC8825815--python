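"""Reading and writing keypoint sequences and scored outputs.

Two input dialects are supported:

* **OpenPose JSON** — either a directory of per-frame ``*_keypoints.json``
  files or one combined JSON file (a list of frame objects, or
  ``{"frames": [...]}``). Each frame object carries ``people[i]``, each with a
  flat ``pose_keypoints_2d`` list of (x, y, confidence) triplets — 18 points
  (COCO) or 25 points (BODY_25, down-mapped by dropping mid-hip and feet).
* **flat CSV** — header ``frame,<joint>_x,<joint>_y,<joint>_c`` for the 18
  canonical joint names.

Scored output is a per-frame CSV plus a JSON summary (schema below).
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .errors import FormatError
from .pipeline import AssessmentReport, ScoredSequence, high_risk_frames
from .skeleton import (
    BODY25_TO_COCO18,
    COCO18_NAMES,
    DEFAULT_CONFIDENCE_THRESHOLD,
    MotionSequence,
    SkeletonFrame,
)

SUMMARY_SCHEMA_VERSION = 1

PersonPolicy = Callable[[list[np.ndarray]], int]


def largest_person(people: list[np.ndarray]) -> int:
    """Index of the person whose valid keypoints span the largest bounding box.

    Deterministic: ties break toward the lowest person index. The worker is
    normally the dominant figure in occupational footage.
    """
    best, best_area = 0, -1.0
    for i, kp in enumerate(people):
        valid = kp[:, 2] >= DEFAULT_CONFIDENCE_THRESHOLD
        if not valid.any():
            area = 0.0
        else:
            xs, ys = kp[valid, 0], kp[valid, 1]
            area = float((xs.max() - xs.min()) * (ys.max() - ys.min()))
        if area > best_area:
            best, best_area = i, area
    return best


def fixed_person(index: int) -> PersonPolicy:
    """Always select the person at a fixed index (error if absent)."""

    def policy(people: list[np.ndarray]) -> int:
        if index >= len(people):
            raise FormatError(f"person index {index} not present ({len(people)} people)")
        return index

    return policy


def _triplets_to_coco18(flat: list[float], frame_index) -> np.ndarray:
    if len(flat) % 3 != 0:
        raise FormatError(
            f"frame {frame_index}: keypoint list length {len(flat)} is not a multiple of 3"
        )
    pts = np.asarray(flat, dtype=float).reshape(-1, 3)
    if pts.shape[0] == 18:
        return pts
    if pts.shape[0] == 25:
        return pts[list(BODY25_TO_COCO18)]
    raise FormatError(
        f"frame {frame_index}: expected 18 or 25 keypoints, got {pts.shape[0]}"
    )


def _frame_from_obj(obj: dict, frame_index: int, person_policy: PersonPolicy) -> SkeletonFrame:
    people_raw = obj.get("people", [])
    if not people_raw:
        return SkeletonFrame.all_missing(frame_index)
    people = [
        _triplets_to_coco18(p.get("pose_keypoints_2d", []), frame_index) for p in people_raw
    ]
    chosen = people[person_policy(people)]
    chosen = chosen.copy()
    chosen[:, 2] = np.clip(chosen[:, 2], 0.0, 1.0)
    return SkeletonFrame(frame_index=frame_index, keypoints=chosen)


_FRAME_NUM_RE = re.compile(r"(\d+)_keypoints$|(\d+)$")


def _frame_number(stem: str) -> int | None:
    m = _FRAME_NUM_RE.search(stem)
    if m is None:
        return None
    return int(m.group(1) or m.group(2))


def read_openpose_json(
    path: str | Path,
    person_policy: PersonPolicy = largest_person,
    fps: float = 30.0,
    source_label: str | None = None,
) -> MotionSequence:
    """Read an OpenPose-schema JSON directory or combined file into a sequence.

    Per-frame files are ordered by the frame number embedded in their names;
    a gap in the numbering is an error naming the missing frame. A frame with
    zero detected people is retained with all keypoints missing.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("*.json"))
        if not files:
            raise FormatError(f"no frames found in {path}")
        numbered = [(_frame_number(f.stem), f) for f in files]
        if all(n is not None for n, _ in numbered):
            numbered.sort(key=lambda t: t[0])
            nums = [n for n, _ in numbered]
            for a, b in zip(nums, nums[1:]):
                if b != a + 1:
                    raise FormatError(f"missing frame files between {a} and {b} in {path}")
            files = [f for _, f in numbered]
        frame_objs = []
        for f in files:
            with open(f, encoding="utf-8") as fh:
                frame_objs.append(json.load(fh))
    else:
        if not path.exists():
            raise FormatError(f"no frames found at {path}")
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
        frame_objs = data["frames"] if isinstance(data, dict) else data
        if not isinstance(frame_objs, list) or not frame_objs:
            raise FormatError(f"no frames found in {path}")
    frames = [
        _frame_from_obj(obj, i, person_policy) for i, obj in enumerate(frame_objs)
    ]
    return MotionSequence(frames=frames, fps=fps,
                          source_label=source_label or str(path))


def write_openpose_json(path: str | Path, sequence: MotionSequence, combined: bool = False) -> None:
    """Serialize a sequence to the OpenPose JSON schema (directory or one file)."""
    path = Path(path)
    objs = [
        {"version": 1.3,
         "people": [{"pose_keypoints_2d": [round(float(v), 6) for v in f.keypoints.ravel()]}]}
        for f in sequence.frames
    ]
    if combined:
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps({"frames": objs}, indent=None), encoding="utf-8")
    else:
        path.mkdir(parents=True, exist_ok=True)
        for i, obj in enumerate(objs):
            (path / f"frame_{i:012d}_keypoints.json").write_text(json.dumps(obj), encoding="utf-8")


def read_keypoint_csv(path: str | Path, fps: float = 30.0,
                      source_label: str | None = None) -> MotionSequence:
    """Read the flat CSV dialect (``frame,<joint>_x,<joint>_y,<joint>_c`` columns)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no frames found at {path}")
    df = pd.read_csv(path)
    expected = ["frame"] + [f"{n}_{s}" for n in COCO18_NAMES for s in ("x", "y", "c")]
    for col in expected:
        if col not in df.columns:
            raise FormatError(f"CSV {path} is missing column {col!r}")
    for col in expected:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            row = int((bad | df[col].isna()).idxmax())
            raise FormatError(f"CSV {path}: non-numeric value in column {col!r}, row {row}")
    if df.empty:
        raise FormatError(f"no frames found in {path}")
    frames = []
    for _, row in df.iterrows():
        kp = np.empty((18, 3))
        for j, name in enumerate(COCO18_NAMES):
            kp[j] = (row[f"{name}_x"], row[f"{name}_y"], row[f"{name}_c"])
        frames.append(SkeletonFrame(frame_index=int(row["frame"]), keypoints=kp))
    return MotionSequence(frames=frames, fps=fps, source_label=source_label or str(path))


def write_keypoint_csv(path: str | Path, sequence: MotionSequence) -> None:
    """Serialize a sequence to the flat CSV dialect."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = {"frame": [f.frame_index for f in sequence.frames]}
    for j, name in enumerate(COCO18_NAMES):
        cols[f"{name}_x"] = [round(float(f.keypoints[j, 0]), 6) for f in sequence.frames]
        cols[f"{name}_y"] = [round(float(f.keypoints[j, 1]), 6) for f in sequence.frames]
        cols[f"{name}_c"] = [round(float(f.keypoints[j, 2]), 6) for f in sequence.frames]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_motion(path: str | Path, fmt: str = "auto", fps: float = 30.0,
                person_policy: PersonPolicy = largest_person) -> MotionSequence:
    """Dispatch to the right reader; ``auto`` keys on the path's suffix."""
    path = Path(path)
    if fmt == "auto":
        fmt = "csv" if path.suffix.lower() == ".csv" else "openpose-json"
    if fmt == "csv":
        return read_keypoint_csv(path, fps=fps)
    if fmt == "openpose-json":
        return read_openpose_json(path, person_policy=person_policy, fps=fps)
    raise FormatError(f"unknown format {fmt!r}")


def _resolve_out_paths(path: str | Path) -> tuple[Path, Path]:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return path, path.with_suffix(".json")
    # treat as a directory base
    return path / "scores.csv", path / "summary.json"


def report_to_dict(report: AssessmentReport) -> dict:
    return {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "selected_scale": report.selected_scale.value,
        "decision_trace": report.decision_trace,
        "total_frames": report.total_frames,
        "max_score": report.max_score,
        "max_risk_level": str(report.max_risk_level) if report.max_risk_level is not None else None,
        "high_risk_frame_indices": list(report.high_risk_frame_indices),
        "high_risk_fraction": report.high_risk_fraction,
        "highest_score_frame_indices": list(report.highest_score_frame_indices),
        "cumulative_score": report.cumulative_score,
        "source_label": report.source_label,
        "advisory": report.advisory,
    }


def write_scored(path: str | Path, scored: ScoredSequence) -> tuple[Path, Path]:
    """Write the per-frame score CSV and the JSON summary; returns both paths.

    ``path`` may be a ``.csv`` file path (the summary lands next to it with a
    ``.json`` suffix) or a directory (``scores.csv`` + ``summary.json``).
    """
    csv_path, json_path = _resolve_out_paths(path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)

    sub_keys: list[str] = []
    for f in scored.per_frame:
        for k in f.subscores:
            if k not in sub_keys:
                sub_keys.append(k)
    rows = [
        {"frame": f.frame_index, "scale": scored.scale.value,
         **{k: f.subscores.get(k) for k in sub_keys},
         "total": f.total, "risk_level": str(f.risk)}
        for f in scored.per_frame
    ]
    columns = ["frame", "scale", *sub_keys, "total", "risk_level"]
    pd.DataFrame(rows, columns=columns).to_csv(csv_path, index=False)

    report = high_risk_frames(scored)
    json_path.write_text(json.dumps(report_to_dict(report), indent=2, sort_keys=True) + "\n",
                         encoding="utf-8")
    return csv_path, json_path


def read_summary(path: str | Path) -> dict:
    """Load a JSON summary written by :func:`write_scored`."""
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
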