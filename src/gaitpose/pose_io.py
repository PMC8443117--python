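"""Canonical 2D pose-trajectory model and tracker-dialect readers.

A :class:`PoseTrajectory` holds time-ordered per-frame keypoint observations
(image pixel coordinates, origin top-left, y down-positive) with per-joint
confidence scores for one recording. Readers exist for the on-disk output
formats of three pose trackers (OpenPose per-frame JSON, AlphaPose results
JSON, Detectron per-frame records) plus a canonical long-form CSV interchange
format with a JSON sidecar header.

The joint vocabulary is the 17-keypoint COCO skeleton; a derived MID_HIP
(mean of the two hips, confidence = min of the two) is always recomputed and
never read from input, so trackers that expose extra landmarks (e.g. BODY-25
mid-hip and toes) reduce to the common denominator.
"""

from __future__ import annotations

import enum
import json
import logging
import re
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError

logger = logging.getLogger(__name__)

TRACKERS = ("alphapose", "openpose", "detectron")
"""Video tracker labels with a confidence-threshold convention."""

SOURCE_LABELS = TRACKERS + ("reference", "synthetic")
CAMERAS = ("eye_level", "top")
VIEWS = ("front", "back", "mixed")


class Joint(enum.IntEnum):
    """COCO-17 keypoints plus the derived MID_HIP."""

    NOSE = 0
    LEFT_EYE = 1
    RIGHT_EYE = 2
    LEFT_EAR = 3
    RIGHT_EAR = 4
    LEFT_SHOULDER = 5
    RIGHT_SHOULDER = 6
    LEFT_ELBOW = 7
    RIGHT_ELBOW = 8
    LEFT_WRIST = 9
    RIGHT_WRIST = 10
    LEFT_HIP = 11
    RIGHT_HIP = 12
    LEFT_KNEE = 13
    RIGHT_KNEE = 14
    LEFT_ANKLE = 15
    RIGHT_ANKLE = 16
    MID_HIP = 17


N_COCO = 17
N_JOINTS = 18  # COCO-17 + MID_HIP

#: Left/right joint pairs, distal-to-proximal order irrelevant.
LR_PAIRS: tuple[tuple[Joint, Joint], ...] = (
    (Joint.LEFT_EYE, Joint.RIGHT_EYE),
    (Joint.LEFT_EAR, Joint.RIGHT_EAR),
    (Joint.LEFT_SHOULDER, Joint.RIGHT_SHOULDER),
    (Joint.LEFT_ELBOW, Joint.RIGHT_ELBOW),
    (Joint.LEFT_WRIST, Joint.RIGHT_WRIST),
    (Joint.LEFT_HIP, Joint.RIGHT_HIP),
    (Joint.LEFT_KNEE, Joint.RIGHT_KNEE),
    (Joint.LEFT_ANKLE, Joint.RIGHT_ANKLE),
)

#: The pairs the swap corrector must have (lower limb).
LOWER_LR_PAIRS: tuple[tuple[Joint, Joint], ...] = (
    (Joint.LEFT_HIP, Joint.RIGHT_HIP),
    (Joint.LEFT_KNEE, Joint.RIGHT_KNEE),
    (Joint.LEFT_ANKLE, Joint.RIGHT_ANKLE),
)

# BODY-25 index -> COCO-17 index (BODY-25 extras: neck 1, mid-hip 8, feet 19-24
# are dropped; MID_HIP is recomputed from the hips).
_BODY25_TO_COCO = {
    0: Joint.NOSE, 15: Joint.RIGHT_EYE, 16: Joint.LEFT_EYE,
    17: Joint.RIGHT_EAR, 18: Joint.LEFT_EAR,
    2: Joint.RIGHT_SHOULDER, 5: Joint.LEFT_SHOULDER,
    3: Joint.RIGHT_ELBOW, 6: Joint.LEFT_ELBOW,
    4: Joint.RIGHT_WRIST, 7: Joint.LEFT_WRIST,
    9: Joint.RIGHT_HIP, 12: Joint.LEFT_HIP,
    10: Joint.RIGHT_KNEE, 13: Joint.LEFT_KNEE,
    11: Joint.RIGHT_ANKLE, 14: Joint.LEFT_ANKLE,
}


@dataclass
class PoseTrajectory:
    """Time-ordered 2D keypoints with confidences for one recording.

    Attributes
    ----------
    xy : (n_frames, 18, 2) float array
        Pixel coordinates (x right-positive, y down-positive). NaN = missing.
    conf : (n_frames, 18) float array
        Confidence in [0, 1]; NaN where the observation is missing.
    frame_index : (n_frames,) int array
        Strictly increasing source frame numbers; time = frame_index / frame_rate.
    frame_rate : float
        Hz; 30 for video sources, 100 for reference-role streams.
    tracker, camera, view, subject_id : str
        Source labels.
    """

    xy: np.ndarray
    conf: np.ndarray
    frame_index: np.ndarray
    frame_rate: float
    tracker: str = "synthetic"
    camera: str = "eye_level"
    view: str = "front"
    subject_id: str = "S00"

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float)
        self.conf = np.asarray(self.conf, dtype=float)
        self.frame_index = np.asarray(self.frame_index, dtype=int)
        if self.xy.ndim != 3 or self.xy.shape[1:] != (N_JOINTS, 2):
            raise ValueError(f"xy must be (n, {N_JOINTS}, 2), got {self.xy.shape}")
        if self.conf.shape != self.xy.shape[:2]:
            raise ValueError("conf shape must match xy frames/joints")
        if self.frame_index.shape != (self.xy.shape[0],):
            raise ValueError("frame_index length must match xy")
        if len(self.frame_index) > 1 and not np.all(np.diff(self.frame_index) > 0):
            raise ValueError("frame_index must be strictly increasing")
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be positive")
        if self.tracker not in SOURCE_LABELS:
            raise ConfigurationError(f"unknown tracker label {self.tracker!r}")
        if self.camera not in CAMERAS:
            raise ConfigurationError(f"unknown camera label {self.camera!r}")
        if self.view not in VIEWS:
            raise ConfigurationError(f"unknown view label {self.view!r}")

    @property
    def n_frames(self) -> int:
        return self.xy.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Timestamps in seconds, frame_index / frame_rate."""
        return self.frame_index / self.frame_rate

    def joint_xy(self, joint: Joint) -> np.ndarray:
        """(n_frames, 2) view of one joint's coordinates."""
        return self.xy[:, int(joint), :]

    def copy(self) -> "PoseTrajectory":
        return replace(self, xy=self.xy.copy(), conf=self.conf.copy(),
                       frame_index=self.frame_index.copy())

    def slice_frames(self, start: int, stop: int) -> "PoseTrajectory":
        """Positional slice [start, stop) preserving original frame indices."""
        return replace(self, xy=self.xy[start:stop].copy(),
                       conf=self.conf[start:stop].copy(),
                       frame_index=self.frame_index[start:stop].copy())

    def derive_mid_hip(self) -> None:
        """Recompute MID_HIP = mean of the hips; confidence = min of the two."""
        lh, rh = int(Joint.LEFT_HIP), int(Joint.RIGHT_HIP)
        self.xy[:, Joint.MID_HIP, :] = 0.5 * (self.xy[:, lh, :] + self.xy[:, rh, :])
        self.conf[:, Joint.MID_HIP] = np.minimum(self.conf[:, lh], self.conf[:, rh])


def _empty_frames(n: int) -> tuple[np.ndarray, np.ndarray]:
    xy = np.full((n, N_JOINTS, 2), np.nan)
    conf = np.full((n, N_JOINTS), np.nan)
    return xy, conf


def _keypoint_bbox_area(kp: np.ndarray) -> float:
    """Area of the bounding box of the finite keypoints (px^2)."""
    ok = np.isfinite(kp[:, 0]) & np.isfinite(kp[:, 1])
    if ok.sum() < 2:
        return 0.0
    x, y = kp[ok, 0], kp[ok, 1]
    return float((x.max() - x.min()) * (y.max() - y.min()))


def select_person(candidates: list[np.ndarray], prev_mid_hip: np.ndarray | None,
                  area_tie_fraction: float = 0.05) -> int:
    """Choose the tracked participant among per-person (17, 3) keypoint arrays.

    The person with the largest keypoint bounding-box area wins; candidates
    within ``area_tie_fraction`` of the largest area are tie-broken by
    continuity (nearest mid-hip to the previously selected mid-hip).
    Deterministic: ties beyond that fall to the lowest candidate index.
    """
    areas = np.array([_keypoint_bbox_area(c[:, :2]) for c in candidates])
    best = int(np.argmax(areas))
    if prev_mid_hip is not None and np.all(np.isfinite(prev_mid_hip)):
        close = np.flatnonzero(areas >= (1.0 - area_tie_fraction) * areas[best])
        if len(close) > 1:
            dists = []
            for i in close:
                hips = candidates[i][[int(Joint.LEFT_HIP), int(Joint.RIGHT_HIP)], :2]
                mh = hips.mean(axis=0)
                d = np.linalg.norm(mh - prev_mid_hip) if np.all(np.isfinite(mh)) else np.inf
                dists.append(d)
            best = int(close[int(np.argmin(dists))])
    return best


def _person_to_frame(kp17: np.ndarray, xy: np.ndarray, conf: np.ndarray, row: int) -> None:
    xy[row, :N_COCO, :] = kp17[:, :2]
    conf[row, :N_COCO] = kp17[:, 2]


def _flat_to_kp(flat: list[float], n_points: int) -> np.ndarray:
    arr = np.asarray(flat, dtype=float)
    if arr.size != 3 * n_points:
        raise FormatError(f"expected {3 * n_points} values in keypoint array, got {arr.size}")
    return arr.reshape(n_points, 3)


def _map_body25(kp25: np.ndarray) -> np.ndarray:
    kp17 = np.full((N_COCO, 3), np.nan)
    for src, dst in _BODY25_TO_COCO.items():
        kp17[int(dst)] = kp25[src]
    return kp17


def _numeric_key(name: str) -> int:
    m = re.findall(r"\d+", name)
    if not m:
        raise FormatError(f"cannot infer a frame number from {name!r}")
    return int(m[0])


def _read_openpose(path: Path, keypoint_order: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    files = sorted(path.glob("*.json"))
    if not files:
        raise FormatError(f"no per-frame JSON files found in {path}")
    n = len(files)
    xy, conf = _empty_frames(n)
    frame_index = np.arange(n)
    prev_mh = None
    for row, f in enumerate(files):
        try:
            data = json.loads(f.read_text())
            people = data.get("people", [])
            persons = []
            for p in people:
                flat = p.get("pose_keypoints_2d", [])
                if keypoint_order == "body25":
                    kp = _map_body25(_flat_to_kp(flat, 25))
                elif keypoint_order == "coco":
                    kp = _flat_to_kp(flat, N_COCO)
                else:
                    raise ConfigurationError(
                        f"unknown keypoint order {keypoint_order!r} (use 'coco' or 'body25')")
                kp[kp[:, 2] == 0] = np.nan  # zero-confidence = not detected
                persons.append(kp)
        except (json.JSONDecodeError, KeyError, TypeError) as exc:
            raise FormatError(f"unparseable OpenPose frame file {f.name}: {exc}") from exc
        prev_mh = _place_best(persons, xy, conf, row, prev_mh, f.name)
    return xy, conf, frame_index


def _place_best(persons: list[np.ndarray], xy: np.ndarray, conf: np.ndarray,
                row: int, prev_mh: np.ndarray | None, label: str) -> np.ndarray | None:
    """Select and store one person for a frame; returns the new mid-hip anchor."""
    if not persons:
        return prev_mh
    idx = select_person(persons, prev_mh)
    if len(persons) > 1:
        logger.debug("frame %s: %d persons detected, selected #%d", label, len(persons), idx)
    _person_to_frame(persons[idx], xy, conf, row)
    hips = persons[idx][[int(Joint.LEFT_HIP), int(Joint.RIGHT_HIP)], :2]
    mh = hips.mean(axis=0)
    return mh if np.all(np.isfinite(mh)) else prev_mh


def _read_alphapose(path: Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    try:
        detections = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"unparseable AlphaPose results file {path.name}: {exc}") from exc
    if not isinstance(detections, list):
        raise FormatError(f"{path.name}: AlphaPose dialect expects a JSON array of detections")
    by_frame: dict[int, list[np.ndarray]] = {}
    for i, det in enumerate(detections):
        try:
            fi = _numeric_key(str(det["image_id"]))
            kp = _flat_to_kp(det["keypoints"], N_COCO)
        except (KeyError, TypeError) as exc:
            raise FormatError(f"{path.name}: bad detection record #{i}: {exc}") from exc
        by_frame.setdefault(fi, []).append(kp)
    if not by_frame:
        raise FormatError(f"{path.name}: no detections")
    frames = np.arange(max(by_frame) + 1)
    xy, conf = _empty_frames(len(frames))
    prev_mh = None
    for row, fi in enumerate(frames):
        prev_mh = _place_best(by_frame.get(int(fi), []), xy, conf, row, prev_mh, f"frame {fi}")
    return xy, conf, frames


def _read_detectron(path: Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    try:
        records = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"unparseable Detectron records file {path.name}: {exc}") from exc
    if not isinstance(records, list):
        raise FormatError(f"{path.name}: Detectron dialect expects a JSON array of frame records")
    n = len(records)
    xy, conf = _empty_frames(n)
    frame_index = np.empty(n, dtype=int)
    prev_mh = None
    for row, rec in enumerate(records):
        try:
            frame_index[row] = int(rec["frame"])
            persons = [_flat_to_kp(np.asarray(inst["keypoints"], dtype=float).ravel(), N_COCO)
                       for inst in rec.get("instances", [])]
        except (KeyError, TypeError, ValueError) as exc:
            raise FormatError(f"{path.name}: bad frame record #{row}: {exc}") from exc
        prev_mh = _place_best(persons, xy, conf, row, prev_mh, f"frame {frame_index[row]}")
    return xy, conf, frame_index


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.stem + ".meta.json")


def write_canonical(traj: PoseTrajectory, path: str | Path) -> None:
    """Write a trajectory as long-form CSV plus a JSON sidecar header.

    Columns: frame, time_s, joint, x, y, confidence (empty cells = missing).
    Reading the result back with dialect="canonical" reproduces the trajectory
    exactly for finite values and preserves missingness.
    """
    path = Path(path)
    rows = {
        "frame": np.repeat(traj.frame_index, N_JOINTS),
        "time_s": np.repeat(traj.times, N_JOINTS),
        "joint": [j.name.lower() for _ in range(traj.n_frames) for j in Joint],
        "x": traj.xy[:, :, 0].ravel(),
        "y": traj.xy[:, :, 1].ravel(),
        "confidence": traj.conf.ravel(),
    }
    try:
        pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")
        meta = {"frame_rate": traj.frame_rate, "tracker": traj.tracker,
                "camera": traj.camera, "view": traj.view, "subject_id": traj.subject_id}
        _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    except OSError as exc:
        raise OSError(f"cannot write canonical trajectory to {path}: {exc}") from exc


def _read_canonical(path: Path) -> PoseTrajectory:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing sidecar header {sidecar.name} for {path.name}")
    meta = json.loads(sidecar.read_text())
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"frame", "joint", "x", "y", "confidence"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path.name}: canonical CSV must have columns {sorted(required)}")
    frames = np.unique(df["frame"].to_numpy())
    pos = {f: i for i, f in enumerate(frames)}
    jidx = {j.name.lower(): int(j) for j in Joint}
    xy, conf = _empty_frames(len(frames))
    rows = df["frame"].map(pos).to_numpy()
    cols_s = df["joint"].map(jidx)
    if cols_s.isna().any():
        bad = df.loc[cols_s.isna(), "joint"].iloc[0]
        raise FormatError(f"{path.name}: unknown joint name {bad!r}")
    cols = cols_s.to_numpy(dtype=int)
    xy[rows, cols, 0] = df["x"].to_numpy()
    xy[rows, cols, 1] = df["y"].to_numpy()
    conf[rows, cols] = df["confidence"].to_numpy()
    traj = PoseTrajectory(xy=xy, conf=conf, frame_index=frames, **meta)
    return traj


def read_pose_run(path: str | Path, dialect: str, *, frame_rate: float = 30.0,
                  keypoint_order: str = "coco", tracker: str | None = None,
                  camera: str = "eye_level", view: str = "front",
                  subject_id: str = "S00") -> PoseTrajectory:
    """Read a tracker output into the canonical trajectory model.

    Parameters
    ----------
    path:
        Directory of per-frame JSON (openpose), results JSON file (alphapose),
        frame-records JSON file (detectron), or long-form CSV (canonical).
    dialect:
        One of "openpose", "alphapose", "detectron", "canonical".
    keypoint_order:
        OpenPose only: "coco" (17) or "body25" (25, extras dropped).

    Frames with no detected person yield all-missing observations; in
    multi-person frames the participant is selected by largest keypoint
    bounding-box area with a mid-hip continuity tie-break. MID_HIP is always
    recomputed from the two hips.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "canonical":
        traj = _read_canonical(path)
        traj.derive_mid_hip()
        return traj
    if dialect == "openpose":
        xy, conf, fi = _read_openpose(path, keypoint_order)
    elif dialect == "alphapose":
        xy, conf, fi = _read_alphapose(path)
    elif dialect == "detectron":
        xy, conf, fi = _read_detectron(path)
    else:
        raise ConfigurationError(f"unknown dialect {dialect!r}")
    traj = PoseTrajectory(xy=xy, conf=conf, frame_index=fi, frame_rate=frame_rate,
                          tracker=tracker or dialect, camera=camera, view=view,
                          subject_id=subject_id)
    traj.derive_mid_hip()
    return traj
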