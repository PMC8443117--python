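"""Shared fixtures: programmatically built trajectories and small simulations."""

import numpy as np
import pytest

from gaitpose.pose_io import N_JOINTS, Joint, PoseTrajectory
from gaitpose.preprocess import BoutAnnotation, WalkingBout


def make_trajectory(n_frames=60, frame_rate=30.0, tracker="alphapose",
                    base=200.0, conf=1.0, **labels) -> PoseTrajectory:
    """A static, fully confident trajectory with plausible joint layout."""
    xy = np.zeros((n_frames, N_JOINTS, 2))
    # hips 120 px apart around x=base, everything else stacked vertically
    layout = {
        Joint.LEFT_HIP: (base + 60, 500), Joint.RIGHT_HIP: (base - 60, 500),
        Joint.LEFT_KNEE: (base + 55, 650), Joint.RIGHT_KNEE: (base - 55, 650),
        Joint.LEFT_ANKLE: (base + 50, 800), Joint.RIGHT_ANKLE: (base - 50, 800),
        Joint.LEFT_SHOULDER: (base + 70, 300), Joint.RIGHT_SHOULDER: (base - 70, 300),
        Joint.LEFT_ELBOW: (base + 80, 380), Joint.RIGHT_ELBOW: (base - 80, 380),
        Joint.LEFT_WRIST: (base + 85, 450), Joint.RIGHT_WRIST: (base - 85, 450),
        Joint.NOSE: (base, 200), Joint.LEFT_EYE: (base + 10, 190),
        Joint.RIGHT_EYE: (base - 10, 190), Joint.LEFT_EAR: (base + 20, 195),
        Joint.RIGHT_EAR: (base - 20, 195), Joint.MID_HIP: (base, 500),
    }
    for j, (x, y) in layout.items():
        xy[:, int(j), :] = (x, y)
    c = np.full((n_frames, N_JOINTS), conf)
    traj = PoseTrajectory(xy=xy, conf=c, frame_index=np.arange(n_frames),
                          frame_rate=frame_rate, tracker=tracker, **labels)
    traj.derive_mid_hip()
    return traj


def make_bout(traj: PoseTrajectory, **meta) -> WalkingBout:
    ann = BoutAnnotation(subject_id=traj.subject_id,
                         start_frame=int(traj.frame_index[0]),
                         end_frame=int(traj.frame_index[-1]),
                         view=traj.view if traj.view != "mixed" else "front",
                         camera=traj.camera)
    return WalkingBout(trajectory=traj, annotation=ann, **meta)


def sine_ankle_bout(period_s=1.2, duration_s=6.0, frame_rate=30.0,
                    amplitude=20.0, trend_slope=0.0, trend_offset=0.0,
                    foot="left") -> WalkingBout:
    """Bout whose up-positive ankle height is sin(2*pi*t/period) plus a trend."""
    n = int(duration_s * frame_rate) + 1
    traj = make_trajectory(n_frames=n, frame_rate=frame_rate)
    t = np.arange(n) / frame_rate
    up = amplitude * np.sin(2 * np.pi * t / period_s) + trend_slope * t + trend_offset
    joint = Joint.LEFT_ANKLE if foot == "left" else Joint.RIGHT_ANKLE
    traj.xy[:, int(joint), 1] = -up  # image y is down-positive
    return make_bout(traj)


@pytest.fixture
def static_traj() -> PoseTrajectory:
    return make_trajectory()


@pytest.fixture(scope="session")
def clean_walk():
    """One clean simulated walk (truth + video), shared across tests."""
    from gaitpose.synthetic import GaitSimConfig, simulate_subject_walk

    cfg = GaitSimConfig(tracker="alphapose")
    truth, video = simulate_subject_walk(cfg, seed=12345)
    return cfg, truth, video
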