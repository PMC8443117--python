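"""Per-step and per-bout gait variables.

Six variables are computed per bout: cadence (steps/min), mean step time (s),
mean step width, the coefficients of variation of step time and step width,
and the estimated margin of stability (eMOS). Video-derived spatial
quantities are normalized frame-locally by the inter-hip pixel distance to
cancel perspective scale, so they are in hip-width units; reference-role
streams stay in metres.

eMOS adapts the inverted-pendulum margin of stability to frontal-view data::

    eMOS = XCOM - BOS,   XCOM = COM + V_COM / omega,   omega = sqrt(g / l)

where COM is the lateral centre-of-mass position (sacrum for the reference
system, the derived mid-hip for video), V_COM its lateral velocity, l the leg
length (metres) and BOS the stance foot's lateral position at strike. omega
is a purely temporal quantity (1/s), so the same SI omega divides a velocity
expressed in hip-width units per second. The per-step lateral axis is
oriented from the stance foot toward the bout-mean COM line, making eMOS
positive when the extrapolated COM stays medial of the stance foot (the
stable configuration) — consistent with reference-scale means of a few
centimetres at typical step widths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, MetadataError, ParameterError, UndefinedStatisticError
from .gait_events import FootStrikeEvent, InterleavedSteps
from .pose_io import Joint, TRACKERS
from .preprocess import WalkingBout

GRAVITY_M_S2 = 9.81

#: Leg length as a fraction of stature when not measured directly
#: (standard anthropometric ratio, trochanter height ~0.53 x height).
LEG_LENGTH_STATURE_RATIO = 0.53


@dataclass
class StepRecord:
    """One step's temporal and spatial measures.

    ``step_width`` and ``emos`` are in hip-width units for video sources and
    metres for reference streams.
    """

    step_index: int
    leading_foot: str  # foot striking at the end of the step
    step_time: float  # s
    step_width: float
    strike_time: float  # s, of the step-ending strike
    strike_frame: int
    emos: float | None = None

    def __post_init__(self) -> None:
        if not self.step_time > 0:
            raise ParameterError(f"step_time must be positive, got {self.step_time}")
        if self.step_width < 0:
            raise ParameterError(f"step_width must be non-negative, got {self.step_width}")


@dataclass
class GaitSummary:
    """The six per-bout gait variables plus bookkeeping labels."""

    cadence: float  # steps/min
    mean_step_time: float  # s
    mean_step_width: float  # hip-width units (video) or m (reference)
    cv_step_time: float
    cv_step_width: float
    mean_emos: float
    n_steps: int
    tracker: str = "synthetic"
    camera: str = "eye_level"
    view: str = "front"
    subject_id: str = "S00"
    bout_index: int = 0


def coefficient_of_variation(values) -> float:
    """Sample standard deviation (n-1 denominator) divided by the mean."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise InsufficientDataError(f"CV needs at least 2 values, got {arr.size}")
    mean = arr.mean()
    if mean == 0:
        raise UndefinedStatisticError("CV undefined for zero mean")
    return float(arr.std(ddof=1) / mean)


def compute_cadence(events: list[FootStrikeEvent]) -> float:
    """Steps per minute: 60 x (n_strikes - 1) / elapsed time."""
    if len(events) < 2:
        raise InsufficientDataError("cadence needs at least 2 strikes")
    span = events[-1].time - events[0].time
    if span <= 0:
        raise InsufficientDataError("strikes must span positive time")
    return 60.0 * (len(events) - 1) / span


def compute_emos(com: float | np.ndarray, v_com: float | np.ndarray,
                 bos: float | np.ndarray, leg_length_m: float,
                 g: float = GRAVITY_M_S2):
    """Estimated margin of stability: (COM + V_COM / sqrt(g/l)) - BOS.

    All positions must share one lateral axis and one unit system; ``v_com``
    is per second. With ``v_com = 0`` this reduces to COM - BOS for any leg
    length. No axis orientation is applied here; see :func:`emos_per_step`.
    """
    if not leg_length_m > 0:
        raise ParameterError(f"leg length must be positive, got {leg_length_m}")
    omega = np.sqrt(g / leg_length_m)
    return (com + v_com / omega) - bos


def hip_width_series(bout: WalkingBout) -> np.ndarray:
    """Per-frame inter-hip distance (px), the frame-local perspective scale."""
    traj = bout.trajectory
    lh = traj.joint_xy(Joint.LEFT_HIP)
    rh = traj.joint_xy(Joint.RIGHT_HIP)
    hw = np.linalg.norm(lh - rh, axis=1)
    if np.any(~(hw > 0)):
        raise ParameterError("hip width must be positive on all frames used "
                             "for normalization")
    return hw


def _is_video(bout: WalkingBout) -> bool:
    return bout.trajectory.tracker in TRACKERS or bout.trajectory.tracker == "synthetic"


def _event_row(bout: WalkingBout, event: FootStrikeEvent) -> int:
    fi = bout.trajectory.frame_index
    row = int(np.searchsorted(fi, event.frame_index))
    if row >= len(fi) or fi[row] != event.frame_index:
        raise ParameterError(f"strike frame {event.frame_index} not in bout")
    return row


def compute_step_records(bout: WalkingBout, steps: InterleavedSteps
                         ) -> list[StepRecord]:
    """Step time and step width for every usable consecutive strike pair.

    Step width is the lateral distance between the two ankles read at the
    step-ending strike frame; for video bouts it is divided by the hip width
    at that same frame. Flagged same-foot gaps are omitted (logged via a
    warning by the caller if desired).
    """
    video = _is_video(bout)
    hw = hip_width_series(bout) if video else None
    traj = bout.trajectory
    records = []
    events = steps.events
    for i in range(1, len(events)):
        if not steps.valid_step[i]:
            continue
        prev, nxt = events[i - 1], events[i]
        if prev.foot == nxt.foot:
            continue
        row = _event_row(bout, nxt)
        lat_next = traj.joint_xy(Joint.LEFT_ANKLE if nxt.foot == "left"
                                 else Joint.RIGHT_ANKLE)[row, 0]
        lat_prev = traj.joint_xy(Joint.LEFT_ANKLE if prev.foot == "left"
                                 else Joint.RIGHT_ANKLE)[row, 0]
        width = abs(float(lat_next - lat_prev))
        if video:
            width /= float(hw[row])
        records.append(StepRecord(step_index=len(records), leading_foot=nxt.foot,
                                  step_time=float(nxt.time - prev.time),
                                  step_width=width, strike_time=float(nxt.time),
                                  strike_frame=int(nxt.frame_index)))
    return records


def resolve_leg_length(bout: WalkingBout) -> float:
    """Leg length in metres from metadata, or 0.53 x height if unmeasured."""
    if bout.leg_length_m is not None:
        return float(bout.leg_length_m)
    if bout.height_m is not None:
        return LEG_LENGTH_STATURE_RATIO * float(bout.height_m)
    raise MetadataError("leg length (or height) is required for eMOS")


def emos_per_step(bout: WalkingBout, records: list[StepRecord],
                  leg_length_m: float | None = None) -> list[StepRecord]:
    """Fill each step record's eMOS, evaluated at the step-ending strike frame.

    COM is the mid-hip lateral series (video, hip-width units via frame-local
    normalization) or the sacrum proxy in metres (reference); V_COM is its
    central finite-difference derivative (one-sided at bout edges). BOS is the
    new stance foot's lateral position at the same frame. The per-step axis
    sign points from the stance foot toward the bout-mean COM line, so a
    medially contained XCOM gives positive eMOS.
    """
    if leg_length_m is None:
        leg_length_m = resolve_leg_length(bout)
    traj = bout.trajectory
    video = _is_video(bout)
    com_raw = traj.joint_xy(Joint.MID_HIP)[:, 0].astype(float)
    if video:
        # Center on the bout-mean mid-hip x before dividing by the frame-local
        # hip width: the image-center offset would otherwise leak a spurious
        # perspective trend into the normalized series (and hence into V_COM),
        # since x_px = cx + scale(t) * lateral while hip width = scale(t) * w.
        hw = hip_width_series(bout)
        x_ref = float(np.mean(com_raw))
        com = (com_raw - x_ref) / hw
    else:
        x_ref = 0.0
        hw = None
        com = com_raw
    t = traj.times
    v_com = np.gradient(com, t)
    com_mean = float(np.mean(com))
    out = []
    for rec in records:
        row = _event_row(bout, _RecEvent(rec.strike_frame))
        ankle = Joint.LEFT_ANKLE if rec.leading_foot == "left" else Joint.RIGHT_ANKLE
        bos = float(traj.joint_xy(ankle)[row, 0])
        if video:
            bos = (bos - x_ref) / float(hw[row])
        raw = float(compute_emos(com[row], v_com[row], bos, leg_length_m))
        sign = 1.0 if bos <= com_mean else -1.0  # axis points foot -> midline
        rec.emos = sign * raw
        out.append(rec)
    return out


class _RecEvent:
    """Minimal event-like carrier for frame lookup."""

    def __init__(self, frame_index: int):
        self.frame_index = frame_index


def summarize_bout(records: list[StepRecord], events: list[FootStrikeEvent],
                   method: str = "mean", **labels):
    """Per-bout summary (method="mean") or per-step table (method="individual").

    With ``method="mean"`` returns one :class:`GaitSummary` with means and
    CVs over the usable steps (CVs are NaN when fewer than 2 steps). With
    ``method="individual"`` returns a :class:`pandas.DataFrame` with one row
    per usable step (cadence and CVs exist only at bout level).
    """
    if method == "individual":
        return pd.DataFrame(
            [{"step_index": r.step_index, "leading_foot": r.leading_foot,
              "step_time": r.step_time, "step_width": r.step_width,
              "emos": r.emos, "strike_time": r.strike_time, **labels}
             for r in records])
    if method != "mean":
        raise ParameterError(f"method must be 'individual' or 'mean', got {method!r}")
    if not records:
        warnings.warn("no usable steps in bout; summary is empty", stacklevel=2)
        return GaitSummary(cadence=np.nan, mean_step_time=np.nan,
                           mean_step_width=np.nan, cv_step_time=np.nan,
                           cv_step_width=np.nan, mean_emos=np.nan, n_steps=0,
                           **labels)
    st = np.array([r.step_time for r in records])
    sw = np.array([r.step_width for r in records])
    em = np.array([r.emos for r in records if r.emos is not None], dtype=float)

    def _cv(vals: np.ndarray) -> float:
        try:
            return coefficient_of_variation(vals)
        except (InsufficientDataError, UndefinedStatisticError):
            return float("nan")

    return GaitSummary(
        cadence=compute_cadence(events) if len(events) >= 2 else float("nan"),
        mean_step_time=float(st.mean()),
        mean_step_width=float(sw.mean()),
        cv_step_time=_cv(st),
        cv_step_width=_cv(sw),
        mean_emos=float(em.mean()) if em.size else float("nan"),
        n_steps=len(records),
        **labels,
    )


def summaries_to_frame(summaries: list[GaitSummary]) -> pd.DataFrame:
    """Long-form DataFrame of bout summaries (one row per bout)."""
    return pd.DataFrame([vars(s) for s in summaries])
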