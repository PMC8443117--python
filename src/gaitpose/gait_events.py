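"""Foot-strike detection and cross-system step-sequence alignment.

Foot strikes are found on the ankle's vertical trajectory: the image y series
is flipped to up-positive, linearly detrended over the bout (the dominant
trend in frontal-view video is the monotone perspective scaling as the subject
approaches or recedes), and local minima — the foot flat on the ground — are
taken as strikes. Candidate minima closer than a minimum stride interval are
merged keeping the lower one, and minima with prominence below a floor
(a fraction of the detrended series' interquartile range) are discarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import detrend, find_peaks

from .errors import AlignmentError
from .pose_io import Joint
from .preprocess import WalkingBout

#: Same-foot strikes cannot be closer than this (s). Safe for cadence
#: up to 130 steps/min (stride ~0.92 s).
MIN_STRIDE_INTERVAL_S = 0.6

#: Minimum prominence of a strike minimum, as a fraction of the IQR of the
#: detrended vertical series.
PROMINENCE_FRACTION = 0.10

#: Cross-system matching window (s); below half the shortest plausible
#: step time (~0.4 s).
MATCH_WINDOW_S = 0.25


@dataclass(frozen=True)
class FootStrikeEvent:
    """One foot's ground contact.

    ``lateral_position`` and ``vertical_position`` are in the source's native
    units (pixels for video, metres for reference streams); hip-width
    normalization of video lateral quantities is frame-local and happens in
    :mod:`gaitpose.gait_metrics`.
    """

    foot: str  # "left" | "right"
    frame_index: int
    time: float  # s
    lateral_position: float
    vertical_position: float  # up-positive, detrended units


@dataclass
class InterleavedSteps:
    """Time-ordered merged strikes of both feet.

    ``valid_step[i]`` says whether the step ending at ``events[i]`` (i >= 1)
    is usable: it is False when the two bounding strikes are of the same foot
    (a missed contralateral strike).
    """

    events: list[FootStrikeEvent]
    valid_step: np.ndarray  # bool, len(events)

    @property
    def n_usable_steps(self) -> int:
        return int(self.valid_step[1:].sum()) if len(self.events) > 1 else 0


@dataclass
class AlignedStepSequences:
    """1:1 matched video/reference strike pairs with trim bookkeeping."""

    pairs: list[tuple[int, int]]  # (index into video events, index into reference events)
    video_events: list[FootStrikeEvent]
    reference_events: list[FootStrikeEvent]
    trimmed_video: int
    trimmed_reference: int


def _ankle_joint(foot: str) -> Joint:
    if foot == "left":
        return Joint.LEFT_ANKLE
    if foot == "right":
        return Joint.RIGHT_ANKLE
    raise ValueError(f"foot must be 'left' or 'right', got {foot!r}")


def detect_foot_strikes(bout: WalkingBout, foot: str,
                        min_stride_interval_s: float = MIN_STRIDE_INTERVAL_S,
                        prominence_fraction: float = PROMINENCE_FRACTION
                        ) -> list[FootStrikeEvent]:
    """Detect one foot's strikes in a preprocessed bout.

    The bout must already be interpolated, swap-corrected and smoothed.
    A bout shorter than one expected stride yields an empty list with a
    warning rather than an error.
    """
    traj = bout.trajectory
    fs = traj.frame_rate
    joint = _ankle_joint(foot)
    y = traj.joint_xy(joint)[:, 1]
    x = traj.joint_xy(joint)[:, 0]
    duration = (traj.n_frames - 1) / fs
    if duration < min_stride_interval_s:
        warnings.warn(f"bout of {duration:.2f} s is shorter than one stride; "
                      "no strikes detected", stacklevel=2)
        return []
    up = -y  # image y is down-positive
    det = detrend(up, type="linear")
    q75, q25 = np.percentile(det, [75, 25])
    floor = prominence_fraction * (q75 - q25)
    distance = max(1, int(round(min_stride_interval_s * fs)))
    # find_peaks on the negated series: maxima of -det are minima of det;
    # the distance rule keeps the higher peak, i.e. the lower minimum.
    idx, _ = find_peaks(-det, distance=distance,
                        prominence=floor if floor > 0 else None)
    events = []
    for i in idx:
        # sub-frame refinement: parabola through the minimum and its
        # neighbours; reduces the frame-quantization error of strike times
        delta = 0.0
        if 0 < i < len(det) - 1:
            denom = det[i - 1] - 2.0 * det[i] + det[i + 1]
            if denom > 0:
                delta = float(np.clip(0.5 * (det[i - 1] - det[i + 1]) / denom, -0.5, 0.5))
        events.append(FootStrikeEvent(foot=foot, frame_index=int(traj.frame_index[i]),
                                      time=float((traj.frame_index[i] + delta) / fs),
                                      lateral_position=float(x[i]),
                                      vertical_position=float(det[i])))
    return events


def interleave_steps(left: list[FootStrikeEvent], right: list[FootStrikeEvent]
                     ) -> InterleavedSteps:
    """Merge per-foot strikes into one time-ordered sequence with gap flags.

    Two consecutive same-foot strikes indicate a missed contralateral strike;
    the enclosed step is flagged invalid and excluded from step-level
    variables downstream.
    """
    events = sorted(left + right, key=lambda e: (e.time, e.foot))
    valid = np.ones(len(events), dtype=bool)
    valid[0:1] = True
    for i in range(1, len(events)):
        if events[i].foot == events[i - 1].foot:
            valid[i] = False
    if len(events) > 0 and (not left or not right):
        valid[:] = False  # one foot entirely absent: no usable steps
    return InterleavedSteps(events=events, valid_step=valid)


def align_step_sequences(video: list[FootStrikeEvent],
                         reference: list[FootStrikeEvent],
                         clock_offset_s: float = 0.0,
                         window_s: float = MATCH_WINDOW_S) -> AlignedStepSequences:
    """Trim and match two strike sequences to the same physical steps.

    Greedy two-pointer matching: after removing ``clock_offset_s`` from the
    reference times, strikes are matched when they fall within ``window_s``
    of each other and carry the same foot label; otherwise the earlier
    unmatched strike is trimmed. The matched subsequences have equal length
    and identical foot-label order, so both systems start and end on the same
    physical strike.
    """
    pairs: list[tuple[int, int]] = []
    i = j = 0
    while i < len(video) and j < len(reference):
        tv = video[i].time
        tr = reference[j].time + clock_offset_s
        if abs(tv - tr) <= window_s and video[i].foot == reference[j].foot:
            pairs.append((i, j))
            i += 1
            j += 1
        elif tv < tr:
            i += 1
        else:
            j += 1
    if len(pairs) < 2:
        raise AlignmentError(
            f"fewer than 2 matchable strikes (video {len(video)}, "
            f"reference {len(reference)}, matched {len(pairs)})")
    matched_v = {p[0] for p in pairs}
    matched_r = {p[1] for p in pairs}
    return AlignedStepSequences(
        pairs=pairs,
        video_events=[video[p[0]] for p in pairs],
        reference_events=[reference[p[1]] for p in pairs],
        trimmed_video=len(video) - len(matched_v),
        trimmed_reference=len(reference) - len(matched_r),
    )
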