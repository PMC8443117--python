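"""Concurrent-validity statistics.

Three layers mirror the study design of a video-vs-reference gait validation:

* a Pearson correlation grid over 24 conditions — 3 trackers x 2 camera
  heights x 2 walking views x 2 calculation methods ("individual steps"
  pools every step; "mean of all steps" averages per participant first);
* precision, the coefficient of variation of per-bout values within each
  tracker/camera/view group, summarized as mean (SD) across participants;
* Bland-Altman agreement between pairs of trackers, with limits of agreement
  at +/- 1.96 sample standard deviations of the paired differences (the
  interval containing ~95% of Gaussian differences).

Temporal variables (cadence, step time) are identical across trackers
whenever the detected strike sequences agree, so Bland-Altman defaults to
the spatial variables (step width, eMOS) only.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, PairingError, UndefinedStatisticError
from .gait_metrics import coefficient_of_variation
from .pose_io import TRACKERS

ALPHA = 0.05  # reporting-time significance level

#: Bout-level and step-level gait variables as they appear in summary frames.
BOUT_VARIABLES = ("cadence", "mean_step_time", "mean_step_width",
                  "cv_step_time", "cv_step_width", "mean_emos")
STEP_VARIABLES = ("step_time", "step_width", "emos")
SPATIAL_VARIABLES = ("step_width", "emos", "mean_step_width", "mean_emos")
TEMPORAL_VARIABLES = ("cadence", "step_time", "mean_step_time")

METHODS = ("individual", "mean")


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int
    condition: tuple = ()

    def __post_init__(self) -> None:
        if np.isfinite(self.r) and abs(self.r) > 1 + 1e-12:
            raise ValueError(f"|r| must be <= 1, got {self.r}")


@dataclass
class BlandAltmanResult:
    """Agreement between two paired measurement series."""

    mean_difference: float
    sd_difference: float
    loa_low: float
    loa_high: float
    n: int
    differences: np.ndarray = field(repr=False, default=None)
    means: np.ndarray = field(repr=False, default=None)
    label: tuple = ()


def pearson_correlation(x, y, condition: tuple = ()) -> CorrelationResult:
    """Pearson r with a two-sided p from the t transform on n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise PairingError(f"paired inputs must be equal-length 1-D, got {x.shape} vs {y.shape}")
    if x.size < 3:
        raise InsufficientDataError(f"correlation needs n >= 3, got {x.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise PairingError("paired inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("correlation undefined for zero variance")
    res = stats.pearsonr(x, y, alternative="two-sided")
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue),
                             n=int(x.size), condition=condition)


def bland_altman(a, b, label: tuple = ()) -> BlandAltmanResult:
    """Bland-Altman agreement: mean difference and +/-1.96 SD limits."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise PairingError(f"paired inputs must be equal-length 1-D, got {a.shape} vs {b.shape}")
    if a.size < 2:
        raise InsufficientDataError("Bland-Altman needs n >= 2")
    d = a - b
    m = 0.5 * (a + b)
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(mean_difference=mean, sd_difference=sd,
                             loa_low=mean - 1.96 * sd, loa_high=mean + 1.96 * sd,
                             n=int(a.size), differences=d, means=m, label=label)


def precision_table(bout_summaries: pd.DataFrame,
                    variables: tuple[str, ...] = BOUT_VARIABLES) -> pd.DataFrame:
    """Within-participant CV of per-bout values, mean (SD) across participants.

    Expects a long-form per-bout summary frame with columns ``subject_id,
    tracker, camera, view`` plus the gait variables. For each
    (tracker, camera, view) group and variable, the CV over each
    participant's bouts is computed (participants with < 2 bouts, or a
    zero-mean variable, contribute nothing), then averaged across
    participants. Groups with no computable CV are marked unavailable (NaN).
    """
    rows = []
    for (tracker, camera, view), grp in bout_summaries.groupby(
            ["tracker", "camera", "view"], sort=True):
        for var in variables:
            cvs = []
            for _, sub in grp.groupby("subject_id"):
                vals = sub[var].dropna().to_numpy()
                try:
                    cvs.append(coefficient_of_variation(vals))
                except (InsufficientDataError, UndefinedStatisticError):
                    continue
            rows.append({
                "tracker": tracker, "camera": camera, "view": view,
                "variable": var,
                "cv_mean": float(np.mean(cvs)) if cvs else np.nan,
                "cv_sd": float(np.std(cvs, ddof=1)) if len(cvs) > 1 else np.nan,
                "n_participants": len(cvs),
            })
    return pd.DataFrame(rows)


def _cell_correlations(video_steps: pd.DataFrame, reference_steps: pd.DataFrame,
                       video_bouts: pd.DataFrame, reference_bouts: pd.DataFrame,
                       method: str, condition: tuple) -> list[dict]:
    """Correlations for one (tracker, camera, view, method) cell."""
    out = []
    step_keys = ["subject_id", "view", "bout_index", "step_index"]
    bout_keys = ["subject_id", "view", "bout_index"]
    if method == "individual":
        merged_steps = video_steps.merge(reference_steps, on=step_keys,
                                         suffixes=("_v", "_r"))
        merged_bouts = video_bouts.merge(reference_bouts, on=bout_keys,
                                         suffixes=("_v", "_r"))
        for var in STEP_VARIABLES:
            out.append(_safe_corr(merged_steps, var, condition))
        # bout-level variables pair per bout under the individual method
        for var in ("cadence", "cv_step_time", "cv_step_width"):
            out.append(_safe_corr(merged_bouts, var, condition))
    else:  # mean: average per participant over all bouts of the view first
        v = video_bouts.groupby("subject_id")[list(BOUT_VARIABLES)].mean()
        r = reference_bouts.groupby("subject_id")[list(BOUT_VARIABLES)].mean()
        merged = v.join(r, lsuffix="_v", rsuffix="_r", how="inner")
        for var in BOUT_VARIABLES:
            out.append(_safe_corr(merged, var, condition))
    return out


def _safe_corr(merged: pd.DataFrame, var: str, condition: tuple) -> dict:
    base = {"tracker": condition[0], "camera": condition[1], "view": condition[2],
            "method": condition[3], "variable": var}
    cols = merged[[f"{var}_v", f"{var}_r"]].dropna()
    try:
        res = pearson_correlation(cols[f"{var}_v"], cols[f"{var}_r"], condition)
        base.update(r=res.r, p=res.p, n=res.n)
    except (InsufficientDataError, UndefinedStatisticError, PairingError):
        base.update(r=np.nan, p=np.nan, n=len(cols))
    return base


def build_condition_grid(video_steps: pd.DataFrame, video_bouts: pd.DataFrame,
                         reference_steps: pd.DataFrame, reference_bouts: pd.DataFrame,
                         trackers: tuple[str, ...] = TRACKERS,
                         cameras: tuple[str, ...] = ("eye_level", "top"),
                         views: tuple[str, ...] = ("front", "back")) -> pd.DataFrame:
    """Populate the tracker x camera x view x method validation grid.

    ``video_steps``/``video_bouts`` must carry ``tracker, camera, view``
    columns; reference tables carry ``view`` (the reference stream is common
    to both cameras and all trackers). Steps must share an aligned
    ``step_index`` key with the reference per-step table. Cells with missing
    inputs are marked unavailable (NaN r) but the grid is still returned with
    its full 3 x 2 x 2 x 2 = 24-cell structure.
    """
    rows: list[dict] = []
    for tracker, camera, view, method in itertools.product(
            trackers, cameras, views, METHODS):
        cond = (tracker, camera, view, method)
        vs = video_steps[(video_steps["tracker"] == tracker)
                         & (video_steps["camera"] == camera)
                         & (video_steps["view"] == view)]
        vb = video_bouts[(video_bouts["tracker"] == tracker)
                         & (video_bouts["camera"] == camera)
                         & (video_bouts["view"] == view)]
        rs = reference_steps[reference_steps["view"] == view]
        rb = reference_bouts[reference_bouts["view"] == view]
        if vs.empty or vb.empty or rs.empty or rb.empty:
            for var in (STEP_VARIABLES + ("cadence", "cv_step_time", "cv_step_width")
                        if method == "individual" else BOUT_VARIABLES):
                rows.append({"tracker": tracker, "camera": camera, "view": view,
                             "method": method, "variable": var,
                             "r": np.nan, "p": np.nan, "n": 0})
            continue
        rows.extend(_cell_correlations(vs, rs, vb, rb, method, cond))
    return pd.DataFrame(rows)


def grid_cell_count(grid: pd.DataFrame) -> int:
    """Number of distinct (tracker, camera, view, method) cells in a grid."""
    return int(grid[["tracker", "camera", "view", "method"]].drop_duplicates().shape[0])


def bland_altman_pairs(video_steps: pd.DataFrame,
                       variables: tuple[str, ...] = ("step_width", "emos"),
                       include_temporal: bool = False) -> list[BlandAltmanResult]:
    """Pairwise tracker agreement on per-step values.

    Spatial variables only by default; ``include_temporal=True`` adds step
    time. Steps are paired across trackers by (subject, camera, view, bout,
    step) keys, so all trackers must have processed the same aligned steps.
    """
    vars_used = variables + (("step_time",) if include_temporal else ())
    keys = ["subject_id", "camera", "view", "bout_index", "step_index"]
    results = []
    trackers = sorted(video_steps["tracker"].unique())
    for (ta, tb) in itertools.combinations(trackers, 2):
        a = video_steps[video_steps["tracker"] == ta]
        b = video_steps[video_steps["tracker"] == tb]
        for camera in sorted(video_steps["camera"].unique()):
            for view in sorted(video_steps["view"].unique()):
                aa = a[(a["camera"] == camera) & (a["view"] == view)]
                bb = b[(b["camera"] == camera) & (b["view"] == view)]
                merged = aa.merge(bb, on=keys, suffixes=("_a", "_b"))
                for var in vars_used:
                    sub = merged[[f"{var}_a", f"{var}_b"]].dropna()
                    if len(sub) < 2:
                        continue
                    results.append(bland_altman(
                        sub[f"{var}_a"], sub[f"{var}_b"],
                        label=(ta, tb, var, camera, view)))
    return results


def plot_bland_altman(result: BlandAltmanResult, ax=None):
    """Scatter of differences vs means with LoA and zero lines."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(result.means, result.differences, s=12, alpha=0.6)
    for yv, style in ((result.mean_difference, "-"),
                      (result.loa_low, "--"), (result.loa_high, "--"), (0.0, ":")):
        ax.axhline(yv, linestyle=style, color="k", linewidth=1)
    ax.set_xlabel("mean of pair")
    ax.set_ylabel("difference")
    if result.label:
        ax.set_title(" / ".join(map(str, result.label)))
    return ax


def plot_correlation(x, y, result: CorrelationResult | None = None, ax=None):
    """Scatter with least-squares fitted line, as in validity scatter plots."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ax.scatter(x, y, s=12, alpha=0.6)
    slope, intercept = np.polyfit(x, y, 1)
    xs = np.linspace(x.min(), x.max(), 50)
    ax.plot(xs, slope * xs + intercept, "r-", linewidth=2)
    if result is not None:
        ax.set_title(f"R = {result.r:.2f}, p = {result.p:.3g}, n = {result.n}")
    return ax
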