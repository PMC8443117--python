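"""Correlation grid, precision CVs, and Bland-Altman agreement."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gaitpose.errors import (InsufficientDataError, PairingError,
                             UndefinedStatisticError)
from gaitpose.validation_stats import (bland_altman, bland_altman_pairs,
                                       build_condition_grid, grid_cell_count,
                                       pearson_correlation, precision_table)


def _pearson_oracle(x, y):
    """Brute-force textbook formula plus the t transform, independent route."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    r = np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2))
    n = len(x)
    t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * stats.t.sf(abs(t), n - 2)
    return r, p


class TestPearson:
    def test_perfect_linearity(self):
        x = np.array([1.0, 2.0, 3.5, 4.0, 7.0])
        res = pearson_correlation(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.p < 0.001

    def test_perfect_negative(self):
        x = np.array([1.0, 2.0, 3.0])
        assert pearson_correlation(x, -x).r == pytest.approx(-1.0)

    def test_against_oracle_small(self):
        x = [1, 2, 3, 4]
        y = [2, 4, 5, 9]
        res = pearson_correlation(x, y)
        r, p = _pearson_oracle(x, y)
        assert res.r == pytest.approx(r, abs=1e-12)
        assert res.p == pytest.approx(p, abs=1e-12)

    def test_against_oracle_random(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            n = int(rng.integers(3, 400))
            x = rng.normal(size=n)
            y = 0.4 * x + rng.normal(size=n)
            res = pearson_correlation(x, y)
            r, p = _pearson_oracle(x, y)
            assert abs(res.r - r) < 1e-12
            assert abs(res.p - p) < 1e-12

    def test_guards(self):
        with pytest.raises(UndefinedStatisticError):
            pearson_correlation([1, 1, 1], [1, 2, 3])
        with pytest.raises(PairingError):
            pearson_correlation([1, 2, 3], [1, 2])
        with pytest.raises(InsufficientDataError):
            pearson_correlation([1, 2], [3, 4])


class TestBlandAltman:
    def test_identical_systems(self):
        a = np.array([1.0, 2.0, 3.0])
        res = bland_altman(a, a)
        assert res.mean_difference == 0.0
        assert res.loa_low == res.loa_high == 0.0

    def test_hand_computed(self):
        res = bland_altman([1, 2, 3], [2, 2, 2])
        assert res.mean_difference == pytest.approx(0.0)
        assert res.sd_difference == pytest.approx(1.0)
        assert res.loa_low == pytest.approx(-1.96)
        assert res.loa_high == pytest.approx(1.96)
        np.testing.assert_allclose(res.means, [1.5, 2.0, 2.5])

    def test_gaussian_coverage(self):
        """±1.96 SD limits contain ≈95% of Gaussian differences."""
        rng = np.random.default_rng(5)
        b = rng.normal(10, 2, 10_000)
        a = b + rng.normal(0.3, 1.0, 10_000)
        res = bland_altman(a, b)
        inside = np.mean((res.differences >= res.loa_low)
                         & (res.differences <= res.loa_high))
        assert inside == pytest.approx(0.95, abs=0.01)

    def test_length_mismatch(self):
        with pytest.raises(PairingError):
            bland_altman([1, 2, 3], [1, 2])


class TestPrecisionTable:
    @staticmethod
    def _summaries(widths_by_subject):
        rows = []
        for sid, widths in widths_by_subject.items():
            for b, w in enumerate(widths):
                rows.append({"subject_id": sid, "tracker": "alphapose",
                             "camera": "eye_level", "view": "front",
                             "bout_index": b, "cadence": 100.0,
                             "mean_step_time": 0.6, "mean_step_width": w,
                             "cv_step_time": 0.05, "cv_step_width": 0.3,
                             "mean_emos": 0.05})
        return pd.DataFrame(rows)

    def test_identical_bouts_zero_cv(self):
        table = precision_table(self._summaries({"S00": [0.3, 0.3, 0.3]}))
        row = table[table.variable == "mean_step_width"].iloc[0]
        assert row.cv_mean == pytest.approx(0.0)

    def test_hand_computed_cv(self):
        table = precision_table(self._summaries({"S00": [0.25, 0.30, 0.35]}))
        row = table[table.variable == "mean_step_width"].iloc[0]
        assert row.cv_mean == pytest.approx(0.05 / 0.30, rel=1e-9)

    def test_group_too_small_unavailable(self):
        table = precision_table(self._summaries({"S00": [0.3]}))
        row = table[table.variable == "mean_step_width"].iloc[0]
        assert np.isnan(row.cv_mean)
        assert row.n_participants == 0


def _paired_tables(trackers=("alphapose", "openpose", "detectron"),
                   cameras=("eye_level", "top"), views=("front", "back"),
                   n_subjects=6, steps_per_bout=8, seed=0, video_noise=0.0):
    """Reference tables plus video copies (optionally noisy) per condition."""
    rng = np.random.default_rng(seed)
    ref_steps, ref_bouts = [], []
    vid_steps, vid_bouts = [], []
    for s in range(n_subjects):
        sid = f"S{s:02d}"
        for view in views:
            for b in range(2):
                st = rng.normal(0.57, 0.05, steps_per_bout)
                sw = np.abs(rng.normal(0.09, 0.03, steps_per_bout))
                em = rng.normal(0.04, 0.02, steps_per_bout)
                for k in range(steps_per_bout):
                    ref_steps.append({"subject_id": sid, "view": view,
                                      "bout_index": b, "step_index": k,
                                      "step_time": st[k], "step_width": sw[k],
                                      "emos": em[k]})
                ref_bouts.append({"subject_id": sid, "view": view, "bout_index": b,
                                  "cadence": 60 / st.mean(),
                                  "mean_step_time": st.mean(),
                                  "mean_step_width": sw.mean(),
                                  "cv_step_time": st.std(ddof=1) / st.mean(),
                                  "cv_step_width": sw.std(ddof=1) / sw.mean(),
                                  "mean_emos": em.mean()})
                for tracker, camera in itertools.product(trackers, cameras):
                    nst = st + rng.normal(0, video_noise * 0.01, steps_per_bout)
                    nsw = sw + rng.normal(0, video_noise, steps_per_bout)
                    for k in range(steps_per_bout):
                        vid_steps.append({"subject_id": sid, "tracker": tracker,
                                          "camera": camera, "view": view,
                                          "bout_index": b, "step_index": k,
                                          "step_time": nst[k],
                                          "step_width": nsw[k], "emos": em[k]})
                    vid_bouts.append({"subject_id": sid, "tracker": tracker,
                                      "camera": camera, "view": view,
                                      "bout_index": b, "cadence": 60 / nst.mean(),
                                      "mean_step_time": nst.mean(),
                                      "mean_step_width": nsw.mean(),
                                      "cv_step_time": nst.std(ddof=1) / nst.mean(),
                                      "cv_step_width": nsw.std(ddof=1) / nsw.mean(),
                                      "mean_emos": em.mean()})
    return (pd.DataFrame(vid_steps), pd.DataFrame(vid_bouts),
            pd.DataFrame(ref_steps), pd.DataFrame(ref_bouts))


class TestConditionGrid:
    def test_grid_has_24_cells(self):
        vs, vb, rs, rb = _paired_tables()
        grid = build_condition_grid(vs, vb, rs, rb)
        assert grid_cell_count(grid) == 24

    def test_reference_self_agreement(self):
        """A video stream identical to the reference correlates perfectly."""
        vs, vb, rs, rb = _paired_tables(video_noise=0.0)
        grid = build_condition_grid(vs, vb, rs, rb)
        populated = grid.dropna(subset=["r"])
        assert (populated.r > 1 - 1e-9).all()

    def test_missing_condition_marked_unavailable(self):
        vs, vb, rs, rb = _paired_tables(cameras=("eye_level",))
        grid = build_condition_grid(vs, vb, rs, rb)
        assert grid_cell_count(grid) == 24
        top = grid[grid.camera == "top"]
        assert top.r.isna().all()
        eye = grid[grid.camera == "eye_level"]
        assert eye.r.notna().all()

    def test_spatial_noise_spares_temporal(self):
        """Noise injected only into spatial variables leaves step-time r higher."""
        vs, vb, rs, rb = _paired_tables(video_noise=0.04, seed=3)
        grid = build_condition_grid(vs, vb, rs, rb)
        ind = grid[grid.method == "individual"]
        for _, cell in ind.groupby(["tracker", "camera", "view"]):
            cv = cell.set_index("variable")["r"]
            assert cv["step_width"] < cv["step_time"]


def test_bland_altman_defaults_to_spatial_pairs():
    vs, _, _, _ = _paired_tables(video_noise=0.02)
    results = bland_altman_pairs(vs)
    variables = {r.label[2] for r in results}
    assert variables == {"step_width", "emos"}
    pairs = {(r.label[0], r.label[1]) for r in results}
    assert len(pairs) == 3  # three tracker pairings
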