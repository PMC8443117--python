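"""Step records, cadence, CV, and the estimated margin of stability."""

import numpy as np
import pytest

from gaitpose.errors import (InsufficientDataError, ParameterError,
                             UndefinedStatisticError)
from gaitpose.gait_events import FootStrikeEvent, interleave_steps
from gaitpose.gait_metrics import (coefficient_of_variation, compute_cadence,
                                   compute_emos, compute_step_records,
                                   emos_per_step, summarize_bout)
from gaitpose.pose_io import Joint

from conftest import make_bout, make_trajectory


def _ev(foot, time, fs=30):
    return FootStrikeEvent(foot=foot, frame_index=int(round(time * fs)),
                           time=time, lateral_position=0.0, vertical_position=0.0)


class TestStepRecords:
    def test_step_times_from_strikes(self):
        bout = make_bout(make_trajectory(n_frames=80))
        steps = interleave_steps([_ev("left", 0.9), _ev("left", 2.1)],
                                 [_ev("right", 1.5)])
        records = compute_step_records(bout, steps)
        assert [r.step_time for r in records] == pytest.approx([0.6, 0.6])

    def test_step_width_hip_normalized(self):
        """300 px vs 360 px ankles over a 120 px hip width -> 0.5 hip-widths."""
        traj = make_trajectory(n_frames=80)
        traj.xy[:, int(Joint.LEFT_ANKLE), 0] = 300.0
        traj.xy[:, int(Joint.RIGHT_ANKLE), 0] = 360.0
        bout = make_bout(traj)
        steps = interleave_steps([_ev("left", 0.9)], [_ev("right", 1.5)])
        records = compute_step_records(bout, steps)
        assert records[0].step_width == pytest.approx(0.5)

    def test_reference_units_passthrough(self):
        """Metre-scale reference widths pass through without normalization."""
        traj = make_trajectory(n_frames=300, frame_rate=100.0, tracker="reference")
        traj.xy[:, int(Joint.LEFT_ANKLE), 0] = 0.02
        traj.xy[:, int(Joint.RIGHT_ANKLE), 0] = 0.12
        bout = make_bout(traj)
        steps = interleave_steps([_ev("left", 0.9, 100)], [_ev("right", 1.5, 100)])
        records = compute_step_records(bout, steps)
        assert records[0].step_width == pytest.approx(0.10)

    def test_flagged_gap_omitted(self):
        bout = make_bout(make_trajectory(n_frames=120))
        steps = interleave_steps(
            [_ev("left", 0.9), _ev("left", 2.1), _ev("left", 3.3)],
            [_ev("right", 1.5)])
        records = compute_step_records(bout, steps)
        assert len(records) == 2  # L->R and R->L; the L->L gap step is dropped


class TestCadence:
    def test_eleven_strikes_six_seconds(self):
        events = [_ev("left" if k % 2 == 0 else "right", 0.6 * k) for k in range(11)]
        assert compute_cadence(events) == pytest.approx(100.0)

    def test_two_strikes(self):
        events = [_ev("left", 1.0), _ev("right", 1.57)]
        assert compute_cadence(events) == pytest.approx(60 / 0.57)

    def test_single_strike_rejected(self):
        with pytest.raises(InsufficientDataError):
            compute_cadence([_ev("left", 1.0)])


class TestCV:
    def test_zero_variance(self):
        assert coefficient_of_variation([2, 2, 2]) == 0.0

    def test_sample_sd_convention(self):
        assert coefficient_of_variation([1, 2, 3]) == pytest.approx(0.5)

    def test_zero_mean_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            coefficient_of_variation([1, -1])

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            coefficient_of_variation([1.0])


class TestEmos:
    def test_degenerate_zero(self):
        assert compute_emos(com=0.3, v_com=0.0, bos=0.3, leg_length_m=0.9) == 0.0

    def test_worked_value(self):
        """com 0.10 m, v 0.20 m/s, l 1 m: omega = sqrt(9.81), eMOS = 0.16386 m."""
        val = compute_emos(com=0.10, v_com=0.20, bos=0.0, leg_length_m=1.0)
        assert val == pytest.approx(0.10 + 0.20 / np.sqrt(9.81), abs=1e-12)
        assert val == pytest.approx(0.16386, abs=5e-6)

    @pytest.mark.parametrize("leg", [0.5, 0.9, 1.3])
    def test_zero_velocity_leg_independent(self, leg):
        assert compute_emos(0.25, 0.0, 0.1, leg) == pytest.approx(0.15)

    def test_invalid_leg_length(self):
        with pytest.raises(ParameterError):
            compute_emos(0.1, 0.1, 0.0, leg_length_m=0.0)

    def test_randomized_closed_form(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            com, v, bos = rng.normal(0, 1, 3)
            leg = rng.uniform(0.4, 1.4)
            expect = (com + v / np.sqrt(9.81 / leg)) - bos
            assert compute_emos(com, v, bos, leg) == pytest.approx(expect, abs=1e-12)


class TestEmosPerStep:
    def test_com_over_stance_foot_zero(self):
        """Constant COM directly over the stance foot, zero velocity -> eMOS 0."""
        traj = make_trajectory(n_frames=90)
        traj.xy[:, int(Joint.LEFT_HIP), 0] = 260.0
        traj.xy[:, int(Joint.RIGHT_HIP), 0] = 140.0
        traj.xy[:, int(Joint.LEFT_ANKLE), 0] = 200.0
        traj.xy[:, int(Joint.RIGHT_ANKLE), 0] = 200.0
        traj.derive_mid_hip()
        bout = make_bout(traj)
        steps = interleave_steps([_ev("left", 1.0)], [_ev("right", 1.6)])
        records = compute_step_records(bout, steps)
        records = emos_per_step(bout, records, leg_length_m=0.9)
        assert records[0].emos == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_formula_on_simulated_bout(self, clean_walk):
        """Per-step eMOS equals an independent evaluation on the same series."""
        from gaitpose.pipeline import process_single_bout

        cfg, truth, video = clean_walk
        res = process_single_bout(video, truth.events(),
                                  leg_length_m=cfg.leg_length_m)
        # independent evaluation: rebuild the normalized series from scratch
        from gaitpose.preprocess import preprocess_trajectory, BoutAnnotation
        bouts, _, _ = preprocess_trajectory(
            video, [BoutAnnotation("S00", 0, video.n_frames - 1,
                                   video.view, video.camera)],
            leg_length_m=cfg.leg_length_m)
        traj = bouts[0].trajectory
        hw = np.linalg.norm(traj.joint_xy(Joint.LEFT_HIP)
                            - traj.joint_xy(Joint.RIGHT_HIP), axis=1)
        mid = traj.joint_xy(Joint.MID_HIP)[:, 0]
        x_ref = mid.mean()
        com = (mid - x_ref) / hw
        v = np.gradient(com, traj.times)
        omega = np.sqrt(9.81 / cfg.leg_length_m)
        for rec in res.records:
            row = int(np.searchsorted(traj.frame_index, rec.strike_frame))
            ankle = (Joint.LEFT_ANKLE if rec.leading_foot == "left"
                     else Joint.RIGHT_ANKLE)
            bos = (traj.joint_xy(ankle)[row, 0] - x_ref) / hw[row]
            raw = (com[row] + v[row] / omega) - bos
            sign = 1.0 if bos <= com.mean() else -1.0
            assert rec.emos == pytest.approx(sign * raw, abs=1e-10)

    def test_scale_invariance(self, clean_walk):
        """Multiplying all pixel coordinates by k leaves normalized outputs alone."""
        from gaitpose.pipeline import process_single_bout

        cfg, truth, video = clean_walk
        res1 = process_single_bout(video, truth.events(), cfg.leg_length_m)
        scaled = video.copy()
        scaled.xy *= 2.37
        res2 = process_single_bout(scaled, truth.events(), cfg.leg_length_m)
        w1 = [r.step_width for r in res1.records]
        w2 = [r.step_width for r in res2.records]
        e1 = [r.emos for r in res1.records]
        e2 = [r.emos for r in res2.records]
        np.testing.assert_allclose(w1, w2, rtol=1e-9)
        np.testing.assert_allclose(e1, e2, rtol=1e-9)


class TestSummaries:
    def _records(self, step_times):
        bout = make_bout(make_trajectory(n_frames=600))
        events = []
        t = 0.9
        for i, st in enumerate(step_times):
            events.append(_ev("left" if i % 2 == 0 else "right", t))
            t += st
        events.append(_ev("left" if len(step_times) % 2 == 0 else "right", t))
        steps = interleave_steps([e for e in events if e.foot == "left"],
                                 [e for e in events if e.foot == "right"])
        return compute_step_records(bout, steps), events

    def test_identical_steps(self):
        records, events = self._records([0.57] * 10)
        s = summarize_bout(records, events)
        assert s.mean_step_time == pytest.approx(0.57, abs=1e-9)
        assert s.cv_step_time == pytest.approx(0.0, abs=1e-9)
        assert s.n_steps == 10

    def test_cv_of_varied_steps(self):
        records, events = self._records([0.5, 0.6, 0.7])
        s = summarize_bout(records, events)
        assert s.mean_step_time == pytest.approx(0.6)
        assert s.cv_step_time == pytest.approx(0.1 / 0.6, rel=1e-6)

    def test_individual_table_row_count(self):
        records, events = self._records([0.5, 0.6, 0.7, 0.55])
        table = summarize_bout(records, events, method="individual")
        assert len(table) == len(records) == 4

    def test_cadence_step_time_consistency(self, clean_walk):
        """|cadence - 60/mean_step_time| / cadence < 5% on a real bout."""
        from gaitpose.pipeline import process_single_bout

        cfg, truth, video = clean_walk
        s = process_single_bout(video, truth.events(), cfg.leg_length_m).summary
        assert s.n_steps >= 4
        assert abs(s.cadence - 60.0 / s.mean_step_time) / s.cadence < 0.05
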