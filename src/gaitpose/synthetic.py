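"""Synthetic gait: paired ground truth and corrupted 2D keypoint video.

A kinematic frontal-plane walker stands in for study participants: alternating
foot strikes with configurable cadence and step-time variability, lateral foot
placements around +/- half the step width with per-step jitter, a smooth
lateral centre-of-mass sway between stance feet (cubic spline through
strike/mid-stance knots), and a vertical ankle excursion with its minimum
exactly at each strike. The walker is projected through a pinhole camera
(fronto-parallel skeleton, scale f/Z(t)) for front or back views at two
camera-height presets, producing the perspective trend that makes hip-width
normalization non-trivial; the "top" preset adds a vertical foreshortening
factor. Degradation emulates tracker failure modes: i.i.d. Gaussian pixel
noise, confidence dropouts below the tracker's threshold, and left/right
label swaps — all deterministic under a seed, with a swap log for scoring.

Defaults reflect a cohort of ~11 older adults: cadence 106.44 steps/min
(between-subject SD 8.1), step time ~0.57 s with within-bout CV 0.06, step
width 0.09 m, 12-15 steps per bout, 30 fps video against a 100 Hz reference
stream, cameras at 1.11 m (eye level) and 2.05 m (top).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .errors import ConfigurationError
from .gait_events import FootStrikeEvent
from .gait_metrics import GaitSummary, StepRecord, compute_emos, summarize_bout
from .pose_io import N_JOINTS, Joint, PoseTrajectory

CAMERA_HEIGHTS_M = {"eye_level": 1.11, "top": 2.05}


@dataclass
class GaitSimConfig:
    """Study-condition parameters for the synthetic walker.

    Rates and spatial scales default to the cohort the analysis emulates;
    corruption parameters default to mild, realistic tracker noise.
    """

    n_subjects: int = 11
    cadence_mean: float = 106.44  # steps/min
    cadence_sd: float = 8.1  # between subjects
    step_time_cv: float = 0.06  # within bout
    step_width_mean: float = 0.09  # m
    step_width_sd: float = 0.03  # between subjects
    foot_jitter_sd: float = 0.025  # m, per-placement lateral jitter
    step_length_mean: float = 0.60  # m, anterior advance per step
    hip_width: float = 0.30  # m
    leg_length: float | None = None  # m; defaults to 0.53 x height
    subject_height: float = 1.64  # m
    walk_distance: float = 13.0  # m, cap on anterior travel
    n_steps_per_bout: int = 13
    video_frame_rate: float = 30.0  # Hz
    reference_rate: float = 100.0  # Hz
    camera: str = "eye_level"
    view: str = "front"
    tracker: str = "synthetic"
    # camera model
    focal_px: float = 1200.0
    camera_distance_near: float = 6.0  # m, closest approach (turns excluded)
    image_center: tuple[float, float] = (960.0, 540.0)
    # walker shape
    sway_fraction: float = 0.3  # mid-stance COM excursion toward stance foot
    ankle_lift: float = 0.15  # m, peak ankle rise during swing
    # corruption
    pixel_noise_sd: float = 3.0  # px
    pixel_noise_axes: str = "xy"  # "xy" or "x" (lateral only)
    dropout_prob: float = 0.02  # per frame-joint
    dropout_confidence: tuple[float, float] = (0.0, 0.1)
    swap_prob: float = 0.02  # per frame

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if self.camera not in CAMERA_HEIGHTS_M:
            raise ConfigurationError(f"unknown camera preset {self.camera!r}")
        if self.view not in ("front", "back"):
            raise ConfigurationError(f"view must be front or back, got {self.view!r}")
        for name in ("cadence_mean", "step_width_mean", "hip_width",
                     "subject_height", "video_frame_rate", "reference_rate",
                     "focal_px", "ankle_lift", "step_length_mean"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in ("dropout_prob", "swap_prob", "step_time_cv"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        mean_step_time = 60.0 / self.cadence_mean
        if mean_step_time <= 2.0 / self.video_frame_rate:
            raise ConfigurationError(
                "step time must exceed 2 video frame intervals")
        if self.pixel_noise_axes not in ("xy", "x"):
            raise ConfigurationError("pixel_noise_axes must be 'xy' or 'x'")

    @property
    def leg_length_m(self) -> float:
        return self.leg_length if self.leg_length is not None \
            else 0.53 * self.subject_height


@dataclass
class _Kinematics:
    """Continuous-time frontal-plane walker for one bout."""

    strike_times: np.ndarray  # all strikes, chronological
    strike_feet: list[str]  # "left"/"right" per strike
    placements: np.ndarray  # lateral foot position (m) per strike
    com_spline: CubicSpline  # lateral COM (m) vs time
    foot_lat: dict  # foot -> callable t -> lateral m
    foot_height: dict  # foot -> callable t -> height m (0 at stance)
    t_start: float
    t_end: float
    forward_speed: float  # m/s
    config: GaitSimConfig


@dataclass
class GroundTruthGait:
    """Reference-role ground truth for one simulated bout."""

    strike_times: np.ndarray
    strike_feet: list[str]
    placements: np.ndarray  # m, lateral
    records: list[StepRecord]
    summary: GaitSummary
    com_times: np.ndarray  # 100 Hz grid
    com_lateral: np.ndarray  # m
    com_velocity: np.ndarray  # m/s
    leg_length_m: float
    hip_width_m: float
    subject_id: str = "S00"
    view: str = "front"
    bout_index: int = 0

    def events(self) -> list[FootStrikeEvent]:
        """Ground-truth strikes as reference-role foot-strike events."""
        return [FootStrikeEvent(foot=f, frame_index=int(round(t * 100)),
                                time=float(t), lateral_position=float(p),
                                vertical_position=0.0)
                for t, f, p in zip(self.strike_times, self.strike_feet,
                                   self.placements)]


@dataclass
class DegradationLog:
    """What degrade_trajectory actually did (for scoring recovery)."""

    swapped_frames: list[tuple[int, str]] = field(default_factory=list)
    dropped: list[tuple[int, str]] = field(default_factory=list)


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _foot_profiles(times: np.ndarray, placements: np.ndarray, lift: float):
    """Per-foot lateral and height profiles from that foot's strike grid.

    ``times``/``placements`` include one virtual strike beyond each end so the
    profiles are defined over the whole bout window. Height is
    lift * |sin(pi u)| between consecutive same-foot strikes: zero exactly at
    each strike with a cusp-like minimum that linear trends cannot displace.
    Lateral position holds the placement for the first 60% of the stride then
    transitions smoothly to the next placement.
    """

    def height(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        k = np.clip(np.searchsorted(times, t, side="right") - 1, 0, len(times) - 2)
        u = (t - times[k]) / (times[k + 1] - times[k])
        return lift * np.abs(np.sin(np.pi * u))

    def lateral(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        k = np.clip(np.searchsorted(times, t, side="right") - 1, 0, len(times) - 2)
        u = (t - times[k]) / (times[k + 1] - times[k])
        s = _smoothstep((u - 0.6) / 0.4)
        return placements[k] * (1 - s) + placements[k + 1] * s

    return lateral, height


def _simulate_kinematics(config: GaitSimConfig, rng: np.random.Generator) -> _Kinematics:
    T = 60.0 / config.cadence_mean
    n = config.n_steps_per_bout
    intervals = rng.normal(T, config.step_time_cv * T, size=n - 1)
    intervals = np.clip(intervals, 2.5 / config.video_frame_rate, None)
    t0 = 0.3
    strikes = t0 + np.concatenate([[0.0], np.cumsum(intervals)])
    feet = ["left" if k % 2 == 0 else "right" for k in range(n)]
    half_w = config.step_width_mean / 2.0
    placements = np.array([
        (half_w if f == "left" else -half_w) + rng.normal(0.0, config.foot_jitter_sd)
        for f in feet])

    t_start = 0.0
    t_end = strikes[-1] + 0.25

    # COM sway spline: zero at strikes, sway_fraction of the stance-foot
    # lateral at mid-stance, pinned at the window edges.
    knots_t = [t_start]
    knots_y = [0.0]
    for k in range(n):
        knots_t.append(strikes[k])
        knots_y.append(0.0)
        if k < n - 1:
            knots_t.append(0.5 * (strikes[k] + strikes[k + 1]))
            knots_y.append(config.sway_fraction * placements[k])
    knots_t.append(t_end)
    knots_y.append(0.0)
    com_spline = CubicSpline(np.array(knots_t), np.array(knots_y), bc_type="natural")

    # per-foot strike grids with one virtual stride beyond each end
    foot_lat = {}
    foot_height = {}
    for foot in ("left", "right"):
        idx = [k for k in range(n) if feet[k] == foot]
        ft = strikes[idx]
        fp = placements[idx]
        stride = 2.0 * T
        ft = np.concatenate([[ft[0] - stride], ft, [ft[-1] + stride]])
        fp = np.concatenate([[fp[0]], fp, [fp[-1]]])
        foot_lat[foot], foot_height[foot] = _foot_profiles(ft, fp, config.ankle_lift)

    total_time = t_end - t_start
    travel = min(config.step_length_mean * n, config.walk_distance)
    forward_speed = travel / total_time
    return _Kinematics(strike_times=strikes, strike_feet=feet, placements=placements,
                       com_spline=com_spline, foot_lat=foot_lat,
                       foot_height=foot_height, t_start=t_start, t_end=t_end,
                       forward_speed=forward_speed, config=config)


def _orient_sign(bos: float) -> float:
    """Axis sign pointing from the stance foot toward the midline (COM~0)."""
    return 1.0 if bos <= 0 else -1.0


def _truth_from_kinematics(kin: _Kinematics, subject_id: str, view: str,
                           bout_index: int) -> GroundTruthGait:
    cfg = kin.config
    t100 = np.arange(kin.t_start, kin.t_end, 1.0 / cfg.reference_rate)
    com = kin.com_spline(t100)
    vel = kin.com_spline(t100, 1)
    leg = cfg.leg_length_m
    records = []
    for k in range(1, len(kin.strike_times)):
        t_k = kin.strike_times[k]
        width = abs(kin.placements[k] - kin.placements[k - 1])
        bos = float(kin.placements[k])
        raw = float(compute_emos(float(kin.com_spline(t_k)),
                                 float(kin.com_spline(t_k, 1)), bos, leg))
        records.append(StepRecord(
            step_index=k - 1, leading_foot=kin.strike_feet[k],
            step_time=float(t_k - kin.strike_times[k - 1]), step_width=float(width),
            strike_time=float(t_k),
            strike_frame=int(round(t_k * cfg.reference_rate)),
            emos=_orient_sign(bos) * raw))
    truth = GroundTruthGait(
        strike_times=kin.strike_times.copy(), strike_feet=list(kin.strike_feet),
        placements=kin.placements.copy(), records=records,
        summary=None, com_times=t100, com_lateral=com, com_velocity=vel,
        leg_length_m=leg, hip_width_m=cfg.hip_width, subject_id=subject_id,
        view=view, bout_index=bout_index)
    truth.summary = summarize_bout(records, truth.events(), method="mean",
                                   tracker="reference", camera="eye_level",
                                   view=view, subject_id=subject_id,
                                   bout_index=bout_index)
    return truth


# body-frame vertical landmark heights as fractions of stature
_JOINT_HEIGHT_FRACTION = {
    Joint.NOSE: 0.93, Joint.LEFT_EYE: 0.95, Joint.RIGHT_EYE: 0.95,
    Joint.LEFT_EAR: 0.94, Joint.RIGHT_EAR: 0.94,
    Joint.LEFT_SHOULDER: 0.82, Joint.RIGHT_SHOULDER: 0.82,
    Joint.LEFT_ELBOW: 0.63, Joint.RIGHT_ELBOW: 0.63,
    Joint.LEFT_WRIST: 0.49, Joint.RIGHT_WRIST: 0.49,
}
_LATERAL_OFFSET_FRACTION = {
    Joint.NOSE: 0.0, Joint.LEFT_EYE: 0.06, Joint.RIGHT_EYE: -0.06,
    Joint.LEFT_EAR: 0.12, Joint.RIGHT_EAR: -0.12,
    Joint.LEFT_SHOULDER: 0.62, Joint.RIGHT_SHOULDER: -0.62,
    Joint.LEFT_ELBOW: 0.70, Joint.RIGHT_ELBOW: -0.70,
    Joint.LEFT_WRIST: 0.72, Joint.RIGHT_WRIST: -0.72,
}


def _project(kin: _Kinematics, camera: str, view: str, subject_id: str,
             tracker: str) -> PoseTrajectory:
    """Pinhole projection of the walker onto a 30 fps image sequence."""
    cfg = kin.config
    fs = cfg.video_frame_rate
    n_frames = int(np.floor((kin.t_end - kin.t_start) * fs)) + 1
    t = kin.t_start + np.arange(n_frames) / fs
    travel = kin.forward_speed * (kin.t_end - kin.t_start)
    if view == "front":
        z = cfg.camera_distance_near + travel - kin.forward_speed * (t - kin.t_start)
    else:
        z = cfg.camera_distance_near + kin.forward_speed * (t - kin.t_start)
    scale = cfg.focal_px / z
    cam_h = CAMERA_HEIGHTS_M[camera]
    # top camera looks down: vertical offsets are foreshortened by cos(tilt)
    if camera == "top":
        z_mid = cfg.camera_distance_near + travel / 2.0
        fore = float(np.cos(np.arctan2(cam_h - 1.0, z_mid)))
    else:
        fore = 1.0
    mirror = 1.0 if view == "front" else -1.0
    cx, cy = cfg.image_center

    com = kin.com_spline(t)
    hw2 = cfg.hip_width / 2.0
    leg = cfg.leg_length_m
    height = cfg.subject_height

    lat = np.empty((n_frames, N_JOINTS))
    vert = np.empty((n_frames, N_JOINTS))
    ankle_base = 0.09
    for foot, hip_j, knee_j, ankle_j in (
            ("left", Joint.LEFT_HIP, Joint.LEFT_KNEE, Joint.LEFT_ANKLE),
            ("right", Joint.RIGHT_HIP, Joint.RIGHT_KNEE, Joint.RIGHT_ANKLE)):
        s = 1.0 if foot == "left" else -1.0
        f_lat = kin.foot_lat[foot](t)
        f_h = kin.foot_height[foot](t) + ankle_base
        lat[:, hip_j] = com + s * hw2
        vert[:, hip_j] = leg
        lat[:, ankle_j] = f_lat
        vert[:, ankle_j] = f_h
        lat[:, knee_j] = 0.5 * (lat[:, hip_j] + f_lat)
        vert[:, knee_j] = 0.5 * (leg + f_h)
    for j, frac in _JOINT_HEIGHT_FRACTION.items():
        vert[:, j] = frac * height
        lat[:, j] = com + _LATERAL_OFFSET_FRACTION[j] * hw2
    lat[:, Joint.MID_HIP] = com
    vert[:, Joint.MID_HIP] = leg

    xy = np.empty((n_frames, N_JOINTS, 2))
    xy[:, :, 0] = cx + scale[:, None] * mirror * lat
    xy[:, :, 1] = cy + scale[:, None] * fore * (cam_h - vert)
    conf = np.ones((n_frames, N_JOINTS))
    traj = PoseTrajectory(xy=xy, conf=conf, frame_index=np.arange(n_frames),
                          frame_rate=fs, tracker=tracker, camera=camera,
                          view=view, subject_id=subject_id)
    traj.derive_mid_hip()
    return traj


def simulate_subject_walk(config: GaitSimConfig, seed: int,
                          subject_id: str = "S00", bout_index: int = 0
                          ) -> tuple[GroundTruthGait, PoseTrajectory]:
    """One bout: 100 Hz ground truth plus a clean 30 fps video projection.

    Deterministic under ``seed``; the projection uses ``config.camera`` /
    ``config.view`` / ``config.tracker``.
    """
    rng = np.random.default_rng(seed)
    kin = _simulate_kinematics(config, rng)
    truth = _truth_from_kinematics(kin, subject_id, config.view, bout_index)
    video = _project(kin, config.camera, config.view, subject_id, config.tracker)
    return truth, video


def degrade_trajectory(traj: PoseTrajectory, config: GaitSimConfig, seed: int
                       ) -> tuple[PoseTrajectory, DegradationLog]:
    """Apply tracker failure modes to a clean trajectory.

    Gaussian pixel noise (``pixel_noise_sd``, on the axes named by
    ``pixel_noise_axes``), per-frame-joint confidence dropouts below the
    tracker thresholds, and per-frame left/right swaps of one random lower
    limb pair. Deterministic under ``seed``; returns the corrupted trajectory
    and a log of the injected swaps and dropouts. The derived MID_HIP is
    recomputed from the corrupted hips.
    """
    rng = np.random.default_rng(seed)
    out = traj.copy()
    log = DegradationLog()
    n, nj = out.n_frames, N_JOINTS
    if config.pixel_noise_sd > 0:
        noise = rng.normal(0.0, config.pixel_noise_sd, size=(n, nj, 2))
        if config.pixel_noise_axes == "x":
            noise[:, :, 1] = 0.0
        out.xy += noise
    if config.dropout_prob > 0:
        lo, hi = config.dropout_confidence
        mask = rng.random((n, nj)) < config.dropout_prob
        out.conf[mask] = rng.uniform(lo, hi, size=int(mask.sum()))
        for f, j in zip(*np.nonzero(mask)):
            log.dropped.append((int(out.frame_index[f]), Joint(j).name.lower()))
    if config.swap_prob > 0:
        pairs = (("hip", Joint.LEFT_HIP, Joint.RIGHT_HIP),
                 ("knee", Joint.LEFT_KNEE, Joint.RIGHT_KNEE),
                 ("ankle", Joint.LEFT_ANKLE, Joint.RIGHT_ANKLE))
        do_swap = rng.random(n) < config.swap_prob
        which = rng.integers(0, len(pairs), size=n)
        for f in np.nonzero(do_swap)[0]:
            name, lj, rj = pairs[which[f]]
            li, ri = int(lj), int(rj)
            out.xy[f, [li, ri]] = out.xy[f, [ri, li]]
            out.conf[f, [li, ri]] = out.conf[f, [ri, li]]
            log.swapped_frames.append((int(out.frame_index[f]), name))
    out.derive_mid_hip()
    return out, log


@dataclass
class BoutBundle:
    """One simulated bout: shared truth and per-(camera, tracker) videos."""

    subject_id: str
    view: str
    bout_index: int
    truth: GroundTruthGait
    videos: dict  # (camera, tracker) -> PoseTrajectory
    clean_videos: dict  # camera -> PoseTrajectory
    degradation: dict  # (camera, tracker) -> DegradationLog


@dataclass
class CohortBundle:
    """A full synthetic study: subjects x views x bouts x cameras x trackers."""

    config: GaitSimConfig
    subjects: pd.DataFrame  # subject_id, height_m, leg_length_m, cadence, step_width
    bouts: list[BoutBundle]
    seed: int


#: Per-tracker multipliers on pixel noise; one tracker is noisier so that
#: pairwise agreement is not degenerate across trackers.
TRACKER_NOISE_SCALE = {"alphapose": 1.0, "detectron": 1.1, "openpose": 1.6}


def simulate_cohort(config: GaitSimConfig, n_subjects: int | None = None,
                    seed: int = 0,
                    trackers: tuple[str, ...] = ("alphapose", "openpose", "detectron"),
                    cameras: tuple[str, ...] = ("eye_level", "top"),
                    degrade: bool = True) -> CohortBundle:
    """Simulate a full study bundle.

    Per subject, cadence and step width are drawn from the configured
    between-subject distributions; front views get 2-3 bouts of 13-15 steps,
    back views 1-2 bouts of 11-13 steps. Each physical bout is projected once
    per camera and corrupted once per tracker (sharing the underlying walk,
    as in a real multi-camera recording). ``degrade=False`` keeps the clean
    projections under each tracker label (useful for parameter-recovery
    checks).
    """
    if n_subjects is None:
        n_subjects = config.n_subjects
    if n_subjects < 1:
        raise ConfigurationError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    subjects = []
    bouts: list[BoutBundle] = []
    for s in range(n_subjects):
        sid = f"S{s:02d}"
        cadence = float(np.clip(rng.normal(config.cadence_mean, config.cadence_sd),
                                80.0, 130.0))
        width = float(np.clip(rng.normal(config.step_width_mean, config.step_width_sd),
                              0.03, 0.25))
        height = float(np.clip(rng.normal(config.subject_height, 0.097), 1.40, 1.95))
        sub_cfg = replace(config, cadence_mean=cadence, step_width_mean=width,
                          subject_height=height, leg_length=None)
        subjects.append({"subject_id": sid, "height_m": height,
                         "leg_length_m": sub_cfg.leg_length_m,
                         "cadence": cadence, "step_width_m": width})
        for view, n_bouts_choices, n_steps_choices in (
                ("front", (2, 3), (13, 14, 15)),
                ("back", (1, 2), (11, 12, 13))):
            n_bouts = int(rng.choice(n_bouts_choices))
            for b in range(n_bouts):
                n_steps = int(rng.choice(n_steps_choices))
                bout_cfg = replace(sub_cfg, view=view, n_steps_per_bout=n_steps)
                kin_seed = int(rng.integers(0, 2**31 - 1))
                krng = np.random.default_rng(kin_seed)
                kin = _simulate_kinematics(bout_cfg, krng)
                truth = _truth_from_kinematics(kin, sid, view, b)
                videos = {}
                clean = {}
                degs = {}
                for camera in cameras:
                    clean_traj = _project(kin, camera, view, sid, "synthetic")
                    clean[camera] = clean_traj
                    for tracker in trackers:
                        labeled = replace(clean_traj, xy=clean_traj.xy.copy(),
                                          conf=clean_traj.conf.copy(),
                                          frame_index=clean_traj.frame_index.copy(),
                                          tracker=tracker)
                        if degrade:
                            tr_cfg = replace(
                                bout_cfg, camera=camera, tracker=tracker,
                                pixel_noise_sd=config.pixel_noise_sd
                                * TRACKER_NOISE_SCALE.get(tracker, 1.0))
                            deg_seed = int(rng.integers(0, 2**31 - 1))
                            labeled, dlog = degrade_trajectory(labeled, tr_cfg, deg_seed)
                        else:
                            dlog = DegradationLog()
                        videos[(camera, tracker)] = labeled
                        degs[(camera, tracker)] = dlog
                bouts.append(BoutBundle(subject_id=sid, view=view, bout_index=b,
                                        truth=truth, videos=videos,
                                        clean_videos=clean, degradation=degs))
    return CohortBundle(config=config, subjects=pd.DataFrame(subjects),
                        bouts=bouts, seed=seed)


def write_bundle(bundle: CohortBundle, out_dir: str | Path) -> None:
    """Write a cohort bundle to disk as canonical CSVs plus metadata/truth logs."""
    from .pose_io import write_canonical

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.subjects.to_csv(out / "subjects.csv", index=False)
    ann_rows = []
    truth_rows = []
    strike_rows = []
    for bout in bundle.bouts:
        stem = f"{bout.subject_id}_{bout.view}_b{bout.bout_index}"
        for (camera, tracker), traj in bout.videos.items():
            tdir = out / "video"
            tdir.mkdir(exist_ok=True)
            write_canonical(traj, tdir / f"{stem}_{camera}_{tracker}.csv")
            ann_rows.append({"subject_id": bout.subject_id, "camera": camera,
                             "view": bout.view, "start_frame": 0,
                             "end_frame": traj.n_frames - 1,
                             "file": f"{stem}_{camera}_{tracker}.csv",
                             "tracker": tracker, "bout_index": bout.bout_index})
        for rec in bout.truth.records:
            truth_rows.append({"subject_id": bout.subject_id, "view": bout.view,
                               "bout_index": bout.bout_index,
                               "step_index": rec.step_index,
                               "leading_foot": rec.leading_foot,
                               "step_time_s": rec.step_time,
                               "step_width_m": rec.step_width,
                               "emos_m": rec.emos,
                               "strike_time_s": rec.strike_time})
        for t, f, p in zip(bout.truth.strike_times, bout.truth.strike_feet,
                           bout.truth.placements):
            strike_rows.append({"subject_id": bout.subject_id, "view": bout.view,
                                "bout_index": bout.bout_index,
                                "strike_time_s": float(t), "foot": f,
                                "lateral_m": float(p)})
    pd.DataFrame(ann_rows).to_csv(out / "bout_annotations.csv", index=False)
    pd.DataFrame(truth_rows).to_csv(out / "truth_steps.csv", index=False)
    pd.DataFrame(strike_rows).to_csv(out / "truth_strikes.csv", index=False)
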