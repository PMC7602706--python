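import numpy as np
import pandas as pd
import pytest

from windfa import (average_subjects, average_trials, estimate_slope,
                    lh_rh_contrast, normalize_segment)
from windfa.response import GroupCurve, NormalizedResponse
from windfa.sliding import AlphaTrajectory

from conftest import ols_slope


def _traj(alphas, dt=0.1):
    alphas = np.asarray(alphas, float)
    return AlphaTrajectory(times=np.arange(alphas.size) * dt, alphas=alphas,
                           window_len=500, step=25)


def _resp(times, values, **kw):
    return NormalizedResponse(times_s=np.asarray(times, float),
                              normalized_alpha=np.asarray(values, float), **kw)


class TestNormalizeSegment:
    def test_hand_computed(self):
        traj = _traj([0.9, 0.99, 1.08])
        resp = normalize_segment(traj, 0.0, 0.2)
        assert np.allclose(resp.normalized_alpha, [1.0, 1.1, 1.2])
        assert resp.normalized_alpha[0] == 1.0

    def test_constant_segment(self):
        resp = normalize_segment(_traj([1.3, 1.3]), 0.0, 0.1)
        assert np.allclose(resp.normalized_alpha, [1.0, 1.0])

    def test_elementwise_oracle(self):
        rng = np.random.default_rng(0)
        alphas = 1.0 + 0.2 * rng.standard_normal(40)
        traj = _traj(alphas)
        resp = normalize_segment(traj, 1.0, 3.0)
        i0 = 10
        expected = alphas[i0:31] / alphas[i0]
        assert np.array_equal(resp.normalized_alpha, expected)

    def test_idempotent(self):
        traj = _traj([0.8, 0.9, 1.1, 1.0])
        resp = normalize_segment(traj, 0.0, 0.3)
        again = normalize_segment(
            AlphaTrajectory(times=resp.times_s, alphas=resp.normalized_alpha,
                            window_len=500, step=25), 0.0, 0.3)
        assert np.allclose(again.normalized_alpha, resp.normalized_alpha)

    def test_nonpositive_start_rejected(self):
        with pytest.raises(ValueError, match="not positive"):
            normalize_segment(_traj([-0.2, 0.5, 0.6]), 0.0, 0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            normalize_segment(_traj([1.0, 1.1]), 0.0, 5.0)


class TestEstimateSlope:
    def test_exact_line(self):
        t = np.arange(0.0, 2.0001, 0.1)
        resp = _resp(t, 1.0 + 0.1 * t)
        est = estimate_slope(resp)
        assert est.r == pytest.approx(0.1, abs=1e-12)
        assert est.stderr == pytest.approx(0.0, abs=1e-9)

    def test_flat_response(self):
        t = np.arange(0.0, 1.01, 0.1)
        assert estimate_slope(_resp(t, np.ones_like(t))).r == pytest.approx(0.0, abs=1e-14)

    def test_matches_closed_form_ols(self):
        rng = np.random.default_rng(5)
        t = np.arange(0.0, 2.0, 0.1)
        y = 1.0 + 0.07 * t + 0.01 * rng.standard_normal(t.size)
        est = estimate_slope(_resp(t, y))
        assert est.r == pytest.approx(ols_slope(t, y), abs=1e-12)

    def test_time_rescale_equivariance(self):
        rng = np.random.default_rng(6)
        t = np.arange(0.0, 2.0, 0.1)
        y = 1.0 + 0.05 * t + 0.01 * rng.standard_normal(t.size)
        r1 = estimate_slope(_resp(t, y)).r
        r2 = estimate_slope(_resp(3.0 * t, y)).r
        assert r2 == pytest.approx(r1 / 3.0, rel=1e-12)

    def test_offset_after_normalization_keeps_slope(self):
        t = np.arange(0.0, 2.0, 0.1)
        y = 1.0 + 0.05 * t
        assert estimate_slope(_resp(t, y + 0.4)).r == pytest.approx(
            estimate_slope(_resp(t, y)).r, abs=1e-12)

    def test_too_few_points(self):
        with pytest.raises(ValueError, match=">= 3"):
            estimate_slope(_resp([0.0, 1.0], [1.0, 1.1]))


class TestAveraging:
    def test_single_trial_is_identity(self):
        r = _resp([0.0, 0.1, 0.2], [1.0, 1.1, 1.2])
        curve = average_trials([r])
        assert np.array_equal(curve.mean, r.normalized_alpha)
        assert curve.n == 1

    def test_mirror_trials_flat(self):
        t = [0.0, 0.1, 0.2]
        d = np.array([0.0, 0.05, -0.03])
        curve = average_trials([_resp(t, 1.0 + d), _resp(t, 1.0 - d)])
        assert np.allclose(curve.mean, 1.0)

    def test_pointwise_mean_oracle(self):
        rng = np.random.default_rng(1)
        t = np.arange(5) * 0.1
        stack = 1.0 + 0.1 * rng.standard_normal((4, 5))
        curve = average_trials([_resp(t, row) for row in stack])
        assert np.allclose(curve.mean, stack.mean(axis=0))

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="common time grid"):
            average_trials([_resp([0.0, 0.1], [1.0, 1.1]),
                            _resp([0.0, 0.2], [1.0, 1.1])])

    def test_subject_se_formula(self):
        t = np.array([0.0])
        curves = [GroupCurve(times_s=t, mean=np.array([v]), se=np.array([0.0]), n=3)
                  for v in (0.08, 0.12)]
        g = average_subjects(curves)
        assert g.mean[0] == pytest.approx(0.10)
        assert g.se[0] == pytest.approx(0.02)     # sd/sqrt(2) of {0.08, 0.12}
        assert g.n == 2

    def test_identical_subjects_zero_se(self):
        t = np.arange(3) * 0.1
        curves = [GroupCurve(times_s=t, mean=np.ones(3), se=np.zeros(3), n=5)] * 3
        assert np.allclose(average_subjects(curves).se, 0.0)

    def test_single_subject_se_undefined(self):
        t = np.arange(3) * 0.1
        g = average_subjects([GroupCurve(times_s=t, mean=np.ones(3),
                                         se=np.zeros(3), n=5)])
        assert np.all(np.isnan(g.se))

    def test_double_averaging_consistency(self):
        # equal trial counts: one-stage pooled mean == two-stage mean
        rng = np.random.default_rng(2)
        t = np.arange(6) * 0.1
        subj_a = 1.0 + 0.1 * rng.standard_normal((3, 6))
        subj_b = 1.0 + 0.1 * rng.standard_normal((3, 6))
        two_stage = average_subjects([
            average_trials([_resp(t, row) for row in subj_a]),
            average_trials([_resp(t, row) for row in subj_b])])
        pooled = average_trials([_resp(t, row)
                                 for row in np.vstack([subj_a, subj_b])])
        assert np.allclose(two_stage.mean, pooled.mean)

    def test_unequal_counts_weight_subjects_equally(self):
        t = np.arange(3) * 0.1
        subj_a = [np.full(3, 2.0)] * 4    # many trials, level 2
        subj_b = [np.full(3, 1.0)]        # single trial, level 1
        two_stage = average_subjects([
            average_trials([_resp(t, v) for v in subj_a]),
            average_trials([_resp(t, v) for v in subj_b])])
        assert np.allclose(two_stage.mean, 1.5)   # not the trial-weighted 1.8


class TestHandContrast:
    @staticmethod
    def _table(rows):
        return pd.DataFrame(rows, columns=["group", "subject", "channel",
                                           "segment", "hand", "r"])

    def test_identical_hands_zero(self):
        rows = [("g", "s1", "C4", "clench", h, 0.1) for h in ("LH", "RH")]
        out = lh_rh_contrast(self._table(rows))
        assert out["mean_abs_diff"].iloc[0] == pytest.approx(0.0)

    def test_channel_averaging(self):
        rows = [("g", "s1", "C3", "clench", "LH", 0.11),
                ("g", "s1", "C3", "clench", "RH", 0.10),
                ("g", "s1", "C4", "clench", "LH", 0.13),
                ("g", "s1", "C4", "clench", "RH", 0.10)]
        out = lh_rh_contrast(self._table(rows))
        assert out["mean_abs_diff"].iloc[0] == pytest.approx(0.02)  # mean(0.01, 0.03)

    def test_missing_hand_excluded(self):
        rows = [("g", "s1", "C4", "clench", "LH", 0.1),
                ("g", "s1", "C4", "clench", "RH", 0.12),
                ("g", "s1", "C3", "clench", "LH", 0.2)]   # no RH for C3
        out = lh_rh_contrast(self._table(rows))
        assert out["mean_abs_diff"].iloc[0] == pytest.approx(0.02)

    def test_group_mean_and_se(self):
        rows = []
        for subj, d in (("s1", 0.01), ("s2", 0.03)):
            rows += [("g", subj, "C4", "clench", "LH", 0.1 + d),
                     ("g", subj, "C4", "clench", "RH", 0.1)]
        out = lh_rh_contrast(self._table(rows))
        assert out["mean_abs_diff"].iloc[0] == pytest.approx(0.02)
        assert out["se_abs_diff"].iloc[0] == pytest.approx(0.01)
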