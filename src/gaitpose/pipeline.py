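"""End-to-end orchestration: preprocess → events → metrics → statistics.

The per-bout unit of work is :func:`process_single_bout`: condition a video
trajectory, detect and interleave foot strikes, align them to the reference
strike sequence so both systems measure the same physical steps, and compute
per-step records (step indices keyed to the reference sequence) plus the
bout summary. Cohort-level drivers assemble the long-form step and bout
tables that feed the validation statistics.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import AlignmentError, GaitPoseError
from .gait_events import (MATCH_WINDOW_S, MIN_STRIDE_INTERVAL_S,
                          PROMINENCE_FRACTION, FootStrikeEvent,
                          InterleavedSteps, align_step_sequences,
                          detect_foot_strikes, interleave_steps)
from .gait_metrics import (GaitSummary, StepRecord, compute_step_records,
                           emos_per_step, summarize_bout)
from .preprocess import (MISSING_LIMIT, BoutAnnotation, QualityReport,
                         WalkingBout, check_missing_rule, default_threshold,
                         preprocess_trajectory)
from .pose_io import PoseTrajectory
from .synthetic import CohortBundle, GroundTruthGait
from .validation_stats import (bland_altman_pairs, build_condition_grid,
                               precision_table)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Serializable run configuration; CLI flags override file values."""

    thresholds: dict = field(default_factory=dict)  # per-tracker overrides
    cutoff_hz: float = 8.0
    filter_order: int = 2
    missing_limit: float = MISSING_LIMIT
    swap_margin_fraction: float = 0.25
    min_stride_interval_s: float = MIN_STRIDE_INTERVAL_S
    prominence_fraction: float = PROMINENCE_FRACTION
    match_window_s: float = MATCH_WINDOW_S
    clock_offset_s: float = 0.0
    seed: int = 0

    def threshold_for(self, tracker: str) -> float:
        if tracker in self.thresholds:
            return float(self.thresholds[tracker])
        return default_threshold(tracker)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


@dataclass
class BoutResult:
    records: list[StepRecord]
    summary: GaitSummary
    quality: QualityReport
    quality_pass: dict[str, bool]
    trimmed_video: int
    trimmed_reference: int


def process_single_bout(traj: PoseTrajectory, reference_events: list[FootStrikeEvent],
                        leg_length_m: float, config: PipelineConfig | None = None,
                        annotation: BoutAnnotation | None = None,
                        bout_index: int = 0) -> BoutResult:
    """Full video chain for one bout, aligned to a reference strike sequence.

    Step indices in the returned records are the *reference* step indices, so
    video and reference per-step tables join 1:1 on
    (subject, view, bout, step).
    """
    cfg = config or PipelineConfig()
    if annotation is None:
        annotation = BoutAnnotation(subject_id=traj.subject_id,
                                    start_frame=int(traj.frame_index[0]),
                                    end_frame=int(traj.frame_index[-1]),
                                    view=traj.view, camera=traj.camera)
    bouts, quality, verdict = preprocess_trajectory(
        traj, [annotation], threshold=cfg.threshold_for(traj.tracker),
        cutoff_hz=cfg.cutoff_hz, filter_order=cfg.filter_order,
        swap_margin_fraction=cfg.swap_margin_fraction,
        missing_limit=cfg.missing_limit, leg_length_m=leg_length_m)
    bout = bouts[0]
    bout.bout_index = bout_index
    left = detect_foot_strikes(bout, "left", cfg.min_stride_interval_s,
                               cfg.prominence_fraction)
    right = detect_foot_strikes(bout, "right", cfg.min_stride_interval_s,
                                cfg.prominence_fraction)
    inter = interleave_steps(left, right)
    aligned = align_step_sequences(inter.events, reference_events,
                                   cfg.clock_offset_s, cfg.match_window_s)
    events_m = aligned.video_events
    # A matched step is usable when feet alternate and both systems advanced
    # by exactly one strike (no interior trim on either side).
    valid = np.zeros(len(events_m), dtype=bool)
    for i in range(1, len(events_m)):
        vi_prev, rj_prev = aligned.pairs[i - 1]
        vi, rj = aligned.pairs[i]
        valid[i] = (events_m[i].foot != events_m[i - 1].foot
                    and vi == vi_prev + 1 and rj == rj_prev + 1)
    sub = InterleavedSteps(events=events_m, valid_step=valid)
    records = compute_step_records(bout, sub)
    valid_positions = [i for i in range(1, len(events_m)) if valid[i]]
    for rec, i in zip(records, valid_positions):
        rec.step_index = aligned.pairs[i][1] - 1
    records = emos_per_step(bout, records, leg_length_m)
    summary = summarize_bout(records, events_m, method="mean",
                             tracker=traj.tracker, camera=traj.camera,
                             view=traj.view, subject_id=traj.subject_id,
                             bout_index=bout_index)
    return BoutResult(records=records, summary=summary, quality=quality,
                      quality_pass=verdict, trimmed_video=aligned.trimmed_video,
                      trimmed_reference=aligned.trimmed_reference)


def _records_frame(records: list[StepRecord], **labels) -> pd.DataFrame:
    return pd.DataFrame([{**{"step_index": r.step_index,
                             "leading_foot": r.leading_foot,
                             "step_time": r.step_time, "step_width": r.step_width,
                             "emos": r.emos, "strike_time": r.strike_time},
                          **labels} for r in records])


def reference_tables(truths: list[GroundTruthGait]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reference per-step and per-bout tables from ground-truth bouts."""
    steps = []
    bouts = []
    for truth in truths:
        labels = {"subject_id": truth.subject_id, "view": truth.view,
                  "bout_index": truth.bout_index}
        steps.append(_records_frame(truth.records, **labels))
        row = vars(truth.summary).copy()
        row.update(labels)
        bouts.append(row)
    return (pd.concat(steps, ignore_index=True) if steps else pd.DataFrame(),
            pd.DataFrame(bouts))


def extract_cohort(bundle: CohortBundle, config: PipelineConfig | None = None
                   ) -> dict:
    """Run the extraction chain over every video stream of a cohort bundle.

    Returns a dict with long-form tables: ``video_steps``, ``video_bouts``,
    ``reference_steps``, ``reference_bouts``, and per-stream ``quality`` rows.
    Bouts whose alignment fails are skipped with a log entry.
    """
    cfg = config or PipelineConfig()
    leg_by_subject = dict(zip(bundle.subjects["subject_id"],
                              bundle.subjects["leg_length_m"]))
    step_frames = []
    bout_rows = []
    quality_rows = []
    for bout in bundle.bouts:
        ref_events = bout.truth.events()
        for (camera, tracker), traj in bout.videos.items():
            try:
                result = process_single_bout(
                    traj, ref_events, leg_by_subject[bout.subject_id], cfg,
                    bout_index=bout.bout_index)
            except (AlignmentError, GaitPoseError) as exc:
                logger.warning("skipping %s %s/%s bout %d: %s", bout.subject_id,
                               camera, tracker, bout.bout_index, exc)
                continue
            labels = {"subject_id": bout.subject_id, "tracker": tracker,
                      "camera": camera, "view": bout.view,
                      "bout_index": bout.bout_index}
            step_frames.append(_records_frame(result.records, **labels))
            bout_rows.append(vars(result.summary).copy())
            quality_rows.append({**labels,
                                 "interpolated": result.quality.interpolated_frame_count,
                                 "swaps_corrected": result.quality.swap_correction_count,
                                 "worst_missing_fraction":
                                     max(result.quality.missing_fraction.values()),
                                 "all_joints_pass": all(result.quality_pass.values())})
    ref_steps, ref_bouts = reference_tables([b.truth for b in bundle.bouts])
    return {
        "video_steps": (pd.concat(step_frames, ignore_index=True)
                        if step_frames else pd.DataFrame()),
        "video_bouts": pd.DataFrame(bout_rows),
        "reference_steps": ref_steps,
        "reference_bouts": ref_bouts,
        "quality": pd.DataFrame(quality_rows),
    }


def run_validation(tables: dict, trackers: tuple[str, ...] = ("alphapose", "openpose", "detectron")
                   ) -> dict:
    """Statistical layer over extracted tables: grid, precision, Bland-Altman."""
    grid = build_condition_grid(tables["video_steps"], tables["video_bouts"],
                                tables["reference_steps"], tables["reference_bouts"],
                                trackers=trackers)
    precision = precision_table(tables["video_bouts"])
    ba = bland_altman_pairs(tables["video_steps"])
    ba_rows = [{"tracker_a": r.label[0], "tracker_b": r.label[1],
                "variable": r.label[2], "camera": r.label[3], "view": r.label[4],
                "mean_diff": r.mean_difference, "sd_diff": r.sd_difference,
                "loa_low": r.loa_low, "loa_high": r.loa_high, "n": r.n}
               for r in ba]
    return {"grid": grid, "precision": precision,
            "bland_altman": pd.DataFrame(ba_rows), "bland_altman_results": ba}


def study_bookkeeping(total_steps: int, n_participants: int, bouts_per_participant: float
                      ) -> dict:
    """Derived step-count rates: per participant and per bout.

    Matches the reporting convention of rounding steps/participant to one
    decimal before dividing by bouts/participant.
    """
    per_participant = round(total_steps / n_participants, 1)
    per_bout = round(per_participant / bouts_per_participant, 1)
    return {"steps_per_participant": per_participant, "steps_per_bout": per_bout}
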