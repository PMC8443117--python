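"""Trajectory conditioning before gait-event detection.

The fixed pipeline order is: confidence masking + linear interpolation →
left/right swap correction → zero-phase Butterworth smoothing → cropping to
straight-walking bouts. :func:`preprocess_trajectory` enforces that order.

Confidence thresholds are tracker-specific (0.3 OpenPose, 0.5 AlphaPose,
0.15 Detectron); a joint whose pre-interpolation missing fraction reaches 10%
of frames is flagged (not silently dropped). Left/right label swaps — a known
failure mode of per-frame pose estimators — are corrected by a deterministic
displacement-minimizing rule with a margin proportional to the hip width,
optionally followed by a manual-override list.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .errors import (AnnotationError, ConfigurationError, ParameterError,
                     TooShortError, UnrecoverableJointError)
from .pose_io import LR_PAIRS, N_JOINTS, Joint, PoseTrajectory, TRACKERS

logger = logging.getLogger(__name__)

#: Per-tracker low-confidence thresholds (score scales are not calibrated
#: across trackers).
DEFAULT_THRESHOLDS = {"openpose": 0.3, "alphapose": 0.5, "detectron": 0.15}

#: A joint fails the quality rule when >= this fraction of frames is missing.
MISSING_LIMIT = 0.10


def default_threshold(tracker: str) -> float:
    """Tracker-specific low-confidence threshold (0.3 / 0.5 / 0.15)."""
    if tracker not in TRACKERS:
        raise ConfigurationError(
            f"no confidence threshold applies to tracker {tracker!r}; "
            f"expected one of {TRACKERS}")
    return DEFAULT_THRESHOLDS[tracker]


@dataclass
class QualityReport:
    """Data-quality bookkeeping for one trajectory.

    ``missing_fraction`` is computed per joint *before* interpolation.
    """

    missing_fraction: dict[str, float] = field(default_factory=dict)
    interpolated_frame_count: int = 0
    swap_correction_count: int = 0
    threshold_used: float | None = None


@dataclass
class BoutAnnotation:
    """A manually annotated straight-walking segment (turns excluded).

    Frame bounds are 0-based and inclusive on both ends.
    """

    subject_id: str
    start_frame: int
    end_frame: int
    view: str = "front"
    camera: str = "eye_level"

    def __post_init__(self) -> None:
        if self.view not in ("front", "back"):
            raise AnnotationError(f"bout view must be front or back, got {self.view!r}")
        if not self.start_frame < self.end_frame:
            raise AnnotationError(
                f"bout start_frame {self.start_frame} must precede end_frame {self.end_frame}")


@dataclass
class WalkingBout:
    """A cropped straight-walking segment with optional subject metadata."""

    trajectory: PoseTrajectory
    annotation: BoutAnnotation
    height_m: float | None = None
    leg_length_m: float | None = None
    bout_index: int = 0


def mask_and_interpolate(traj: PoseTrajectory, threshold: float
                         ) -> tuple[PoseTrajectory, QualityReport]:
    """Replace low-confidence observations by linear interpolation in time.

    Observations with confidence < ``threshold`` (or missing entirely) are
    replaced, per joint and coordinate, by linear interpolation between the
    nearest flanking confident observations; leading/trailing gaps hold the
    first/last confident value. Confident observations pass through exactly.

    Returns the interpolated trajectory and a :class:`QualityReport` whose
    ``missing_fraction`` reflects the pre-interpolation state.

    Raises
    ------
    UnrecoverableJointError
        If a joint has no confident observation in the whole trajectory.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ParameterError(f"threshold must lie in [0, 1], got {threshold}")
    out = traj.copy()
    report = QualityReport(threshold_used=threshold)
    t = traj.times
    interpolated = 0
    for j in Joint:
        conf = traj.conf[:, int(j)]
        good = np.isfinite(conf) & (conf >= threshold) \
            & np.all(np.isfinite(traj.xy[:, int(j), :]), axis=1)
        frac = float(np.mean(~good))
        report.missing_fraction[j.name.lower()] = frac
        if np.all(good):
            continue
        if not np.any(good):
            raise UnrecoverableJointError(j.name.lower())
        bad = ~good
        for c in range(2):
            out.xy[bad, int(j), c] = np.interp(t[bad], t[good], traj.xy[good, int(j), c])
        interpolated += int(bad.sum())
    report.interpolated_frame_count = interpolated
    return out, report


def check_missing_rule(report: QualityReport, limit: float = MISSING_LIMIT) -> dict[str, bool]:
    """Per-joint pass/fail of the missing-data rule.

    A joint *fails* (False) when its missing fraction is >= ``limit`` — the
    boundary counts as failing, reading the survival rule literally as
    "less than" the limit.
    """
    return {joint: frac < limit for joint, frac in report.missing_fraction.items()}


def _swap_gain(L: np.ndarray, R: np.ndarray, offsets=(-2, -1, 1, 2)) -> np.ndarray:
    """Per-frame mean displacement saved by exchanging L/R, vs. neighbours.

    For each frame the keep-cost is the summed distance of (L, R) to the
    like-labelled joints of the neighbouring frames at the given offsets, the
    swap-cost the same with the frame's labels exchanged; the gain is
    (keep - swap) averaged over the available neighbours. Positive gain means
    exchanging improves continuity.
    """
    n = len(L)
    keep = np.zeros(n)
    swap = np.zeros(n)
    valid = np.zeros(n)
    for o in offsets:
        sl_here = slice(max(0, -o), n - max(0, o))
        sl_nbr = slice(max(0, o), n + min(0, o))
        dLL = np.linalg.norm(L[sl_here] - L[sl_nbr], axis=1)
        dRR = np.linalg.norm(R[sl_here] - R[sl_nbr], axis=1)
        dLR = np.linalg.norm(L[sl_here] - R[sl_nbr], axis=1)
        dRL = np.linalg.norm(R[sl_here] - L[sl_nbr], axis=1)
        ok = np.isfinite(dLL) & np.isfinite(dRR) & np.isfinite(dLR) & np.isfinite(dRL)
        keep[sl_here] += np.where(ok, dLL + dRR, 0.0)
        swap[sl_here] += np.where(ok, dRL + dLR, 0.0)
        valid[sl_here] += ok
    with np.errstate(invalid="ignore"):
        return np.where(valid > 0, (keep - swap) / np.maximum(valid, 1), 0.0)


def correct_lr_swaps(traj: PoseTrajectory, swap_margin_fraction: float = 0.25,
                     overrides: list[tuple[int, str]] | None = None,
                     max_passes: int = 4) -> tuple[PoseTrajectory, QualityReport]:
    """Undo left/right label exchanges.

    For each left/right joint pair, a frame's labels are exchanged when the
    exchange reduces the mean displacement to the like-labelled joints of the
    neighbouring frames (offsets +/-1, +/-2) by more than
    ``swap_margin_fraction`` times the hip width at that frame. Decisions in
    a pass are computed from the current state and applied simultaneously —
    no frame's decision feeds into another's within a pass — so one ambiguous
    frame (the two joints nearly coincident) cannot start a label-inversion
    cascade. Passes repeat until no frame changes, which also makes the
    operation idempotent on its own output.

    Genuine smooth crossings of the two tracks are left alone: exchanging
    them would not improve neighbour continuity beyond the margin. An
    optional ``overrides`` list of (frame_index, pair_name) entries — e.g.
    ``(120, "ankle")`` — is applied after the automatic passes, preserving a
    manual escape hatch.
    """
    out = traj.copy()
    report = QualityReport()
    count = 0
    pair_names = {p[0].name.split("_", 1)[1].lower(): p for p in LR_PAIRS}
    hips_l = out.xy[:, int(Joint.LEFT_HIP), :]
    hips_r = out.xy[:, int(Joint.RIGHT_HIP), :]
    margin = swap_margin_fraction * np.linalg.norm(hips_l - hips_r, axis=1)
    for left, right in LR_PAIRS:
        li, ri = int(left), int(right)
        for _ in range(max_passes):
            gain = _swap_gain(out.xy[:, li, :], out.xy[:, ri, :])
            flip = np.isfinite(margin) & (gain > margin)
            if not np.any(flip):
                break
            rows = np.flatnonzero(flip)
            out.xy[np.ix_(rows, [li, ri])] = out.xy[np.ix_(rows, [ri, li])]
            out.conf[np.ix_(rows, [li, ri])] = out.conf[np.ix_(rows, [ri, li])]
            count += len(rows)
    for frame, pair in (overrides or []):
        if pair not in pair_names:
            raise ConfigurationError(f"unknown joint pair {pair!r} in swap override")
        left, right = pair_names[pair]
        row = int(np.searchsorted(out.frame_index, frame))
        if row >= out.n_frames or out.frame_index[row] != frame:
            raise ConfigurationError(f"swap override frame {frame} not in trajectory")
        li, ri = int(left), int(right)
        out.xy[row, [li, ri]] = out.xy[row, [ri, li]]
        out.conf[row, [li, ri]] = out.conf[row, [ri, li]]
        count += 1
    out.derive_mid_hip()
    report.swap_correction_count = count
    return out, report


def smooth_trajectory(traj: PoseTrajectory, cutoff_hz: float = 8.0,
                      order: int = 2) -> PoseTrajectory:
    """Zero-phase low-pass Butterworth smoothing of every joint coordinate.

    The filter is applied forward and backward (``filtfilt``), giving zero net
    phase and an effective attenuation of twice the design order. Edges are
    handled by reflective padding of length 3 x (order + 1) samples.
    Confidences pass through unchanged. Gaps must already be interpolated;
    joints that are entirely missing are skipped.
    """
    nyquist = traj.frame_rate / 2.0
    if not 0 < cutoff_hz < nyquist:
        raise ParameterError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={nyquist} Hz)")
    padlen = 3 * (order + 1)
    if traj.n_frames <= padlen:
        raise TooShortError(
            f"trajectory of {traj.n_frames} frames is shorter than the "
            f"minimum padded length {padlen + 1}")
    b, a = butter(order, cutoff_hz, btype="low", fs=traj.frame_rate)
    out = traj.copy()
    for j in range(N_JOINTS):
        for c in range(2):
            series = traj.xy[:, j, c]
            if np.all(np.isnan(series)):
                continue
            if np.any(np.isnan(series)):
                raise ParameterError(
                    f"joint {Joint(j).name.lower()} still has gaps; "
                    "interpolate before smoothing")
            out.xy[:, j, c] = filtfilt(b, a, series, padtype="even", padlen=padlen)
    return out


def extract_bouts(traj: PoseTrajectory, annotations: list[BoutAnnotation],
                  height_m: float | None = None, leg_length_m: float | None = None
                  ) -> list[WalkingBout]:
    """Crop a trajectory into straight-walking bouts (inclusive frame bounds)."""
    anns = sorted(annotations, key=lambda a: a.start_frame)
    for prev, nxt in zip(anns, anns[1:]):
        if nxt.start_frame <= prev.end_frame:
            raise AnnotationError(
                f"overlapping bout annotations: [{prev.start_frame}, {prev.end_frame}] "
                f"and [{nxt.start_frame}, {nxt.end_frame}]")
    bouts = []
    for k, ann in enumerate(anns):
        lo = int(np.searchsorted(traj.frame_index, ann.start_frame))
        hi = int(np.searchsorted(traj.frame_index, ann.end_frame))
        if (lo >= traj.n_frames or hi >= traj.n_frames
                or traj.frame_index[lo] != ann.start_frame
                or traj.frame_index[hi] != ann.end_frame):
            raise AnnotationError(
                f"bout [{ann.start_frame}, {ann.end_frame}] outside trajectory frames "
                f"[{traj.frame_index[0]}, {traj.frame_index[-1]}]")
        piece = traj.slice_frames(lo, hi + 1)
        piece.view = ann.view
        piece.camera = ann.camera
        bouts.append(WalkingBout(trajectory=piece, annotation=ann, height_m=height_m,
                                 leg_length_m=leg_length_m, bout_index=k))
    return bouts


def preprocess_trajectory(traj: PoseTrajectory, annotations: list[BoutAnnotation],
                          threshold: float | None = None, *,
                          cutoff_hz: float = 8.0, filter_order: int = 2,
                          swap_margin_fraction: float = 0.25,
                          missing_limit: float = MISSING_LIMIT,
                          swap_overrides: list[tuple[int, str]] | None = None,
                          height_m: float | None = None,
                          leg_length_m: float | None = None,
                          ) -> tuple[list[WalkingBout], QualityReport, dict[str, bool]]:
    """Run the full conditioning chain in its fixed order.

    mask/interpolate → swap-correct → smooth → crop to bouts. Returns the
    bouts, a merged quality report, and the per-joint missing-rule verdict.
    """
    if threshold is None:
        threshold = default_threshold(traj.tracker)
    interp, q1 = mask_and_interpolate(traj, threshold)
    fixed, q2 = correct_lr_swaps(interp, swap_margin_fraction, swap_overrides)
    smoothed = smooth_trajectory(fixed, cutoff_hz, filter_order)
    bouts = extract_bouts(smoothed, annotations, height_m=height_m,
                          leg_length_m=leg_length_m)
    report = QualityReport(missing_fraction=q1.missing_fraction,
                           interpolated_frame_count=q1.interpolated_frame_count,
                           swap_correction_count=q2.swap_correction_count,
                           threshold_used=threshold)
    verdict = check_missing_rule(report, missing_limit)
    failing = [j for j, ok in verdict.items() if not ok]
    if failing:
        warnings.warn(f"joints over the {missing_limit:.0%} missing limit: {failing}",
                      stacklevel=2)
    return bouts, report, verdict


def read_bout_annotations(path: str | Path) -> list[BoutAnnotation]:
    """Read a bout-annotation CSV (subject_id, camera, view, start_frame, end_frame)."""
    df = pd.read_csv(path, comment="#")
    required = {"subject_id", "camera", "view", "start_frame", "end_frame"}
    if not required.issubset(df.columns):
        raise AnnotationError(f"annotation file must have columns {sorted(required)}")
    return [BoutAnnotation(subject_id=str(r.subject_id), camera=str(r.camera),
                           view=str(r.view), start_frame=int(r.start_frame),
                           end_frame=int(r.end_frame))
            for r in df.itertuples()]


def read_swap_overrides(path: str | Path) -> list[tuple[int, str]]:
    """Read a manual swap-override CSV (frame, joint_pair)."""
    df = pd.read_csv(path, comment="#")
    if not {"frame", "joint_pair"}.issubset(df.columns):
        raise ConfigurationError("swap override file must have columns frame, joint_pair")
    return [(int(r.frame), str(r.joint_pair)) for r in df.itertuples()]
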