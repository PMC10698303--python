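"""Epoching, condition contrasts, and cluster permutation statistics."""

import numpy as np
import pandas as pd
import pytest

from localglobal.deviance import (
    EmptyEpochsError,
    MissingConditionError,
    cluster_permutation_test,
    condition_timecourses,
    make_epochs,
    paired_t_d_timecourse,
    peak_latency_difference,
)
from localglobal.roi import RoiTimeSeries


def _events(onsets, patterns=None, roles=None):
    n = len(onsets)
    return pd.DataFrame({
        "onset": onsets,
        "duration": 0.65,
        "pattern": patterns or ["xxxxx"] * n,
        "global_role": roles or ["frequent"] * n,
        "session_index": 0,
        "block_index": 0,
    })


class TestMakeEpochs:
    def test_constant_series_zero_after_baseline(self):
        series = RoiTimeSeries(np.full(100, 3.7), tr=1.25)
        epochs = make_epochs(series, _events([20.0, 40.0]), upsample_factor=8)
        assert np.allclose(epochs.data, 0.0)

    def test_unit_step_at_onset(self):
        tr = 1.0
        values = np.zeros(100)
        values[50:] = 1.0
        series = RoiTimeSeries(values, tr=tr)
        epochs = make_epochs(series, _events([50.0]), window=(-2, 12),
                             baseline=(-2, -1), upsample_factor=1)
        t = epochs.times
        assert np.allclose(epochs.data[0][t <= 49 - 50], 0.0)
        assert np.allclose(epochs.data[0][t >= 0], 1.0)

    def test_grid_spacing_is_tr_over_factor(self):
        series = RoiTimeSeries(np.arange(60, dtype=float), tr=1.25)
        epochs = make_epochs(series, _events([30.0]), upsample_factor=1000)
        assert np.allclose(np.diff(epochs.times), 1.25e-3)

    def test_baseline_mean_zero_invariant(self, rng):
        series = RoiTimeSeries(rng.standard_normal(200), tr=1.25)
        epochs = make_epochs(series, _events([30.0, 60.0, 90.0]), upsample_factor=4)
        sel = (epochs.times >= -2) & (epochs.times <= 0)
        assert np.allclose(epochs.data[:, sel].mean(axis=1), 0.0, atol=1e-10)

    def test_edge_events_dropped_and_empty_raises(self, caplog):
        series = RoiTimeSeries(np.zeros(40), tr=1.25)
        with caplog.at_level("INFO", logger="localglobal.deviance"):
            epochs = make_epochs(series, _events([1.0, 20.0]), upsample_factor=2)
        assert epochs.n_trials == 1
        assert any("dropped 1" in rec.getMessage() for rec in caplog.records)
        with pytest.raises(EmptyEpochsError):
            make_epochs(series, _events([0.5]), upsample_factor=2)


class TestConditionTimecourses:
    def _epochset(self, cell_values, n_time=5):
        """One epoch per cell with a constant value."""
        cells = [("xxxxx", "frequent"), ("xxxxY", "rare"),
                 ("xxxxY", "frequent"), ("xxxxx", "rare")]
        data = np.array([[v] * n_time for v in cell_values], dtype=float)
        labels = pd.DataFrame([{"pattern": p, "global_role": r} for p, r in cells])
        from localglobal.deviance import EpochSet
        return EpochSet(data, np.arange(n_time, dtype=float), labels)

    def test_template_cells(self):
        eps = self._epochset([1.0, 1.0, 1.0, 1.0])
        tc = condition_timecourses(eps)
        for cell in [("xxxxx", "frequent"), ("xxxxY", "rare")]:
            assert np.allclose(tc[cell], 1.0)
        assert np.allclose(tc["global"], 0.0)

    def test_interaction_arithmetic(self):
        # cells: fx=1, ry=4, fy=2, rx=3 -> interaction (ry-fx)-(rx-fy)=3-1=2
        eps = self._epochset([1.0, 4.0, 2.0, 3.0])
        tc = condition_timecourses(eps)
        assert np.allclose(tc["interaction"], 2.0)
        assert np.allclose(tc["global"], (4 + 3) / 2 - (1 + 2) / 2)

    def test_missing_cell_raises(self):
        eps = self._epochset([1.0, 2.0, 3.0, 4.0])
        eps.labels.loc[3, "pattern"] = "xxxxY"  # removes the (xxxxx, rare) cell
        with pytest.raises(MissingConditionError):
            condition_timecourses(eps)

    def test_habituation_counts_as_frequent_by_default(self):
        eps = self._epochset([1.0, 2.0, 3.0, 4.0])
        eps.labels.loc[0, "global_role"] = "habituation"
        tc = condition_timecourses(eps)
        assert np.allclose(tc[("xxxxx", "frequent")], 1.0)
        with pytest.raises(MissingConditionError):
            condition_timecourses(eps, include_habituation=False)


class TestPairedTD:
    def test_all_zero(self):
        res = paired_t_d_timecourse(np.zeros((5, 7)))
        assert np.allclose(res.t, 0) and np.allclose(res.d, 0)

    def test_hand_computed_values(self):
        diffs = np.array([[1.0], [2.0], [3.0]])
        res = paired_t_d_timecourse(diffs)
        assert res.t[0] == pytest.approx(2 / (1 / np.sqrt(3)), abs=1e-3)
        assert res.t[0] == pytest.approx(3.464, abs=1e-3)
        assert res.d[0] == pytest.approx(2.000, abs=1e-6)

    def test_d_equals_t_over_sqrt_n_identity(self, rng):
        diffs = rng.standard_normal((24, 30))
        res = paired_t_d_timecourse(diffs)
        assert np.allclose(res.d, res.t / np.sqrt(24))

    def test_printed_effect_size_convention(self):
        # published t/n pairs imply d = t/sqrt(n)
        assert round(3.04 / np.sqrt(24), 2) == 0.62
        assert round(6.85 / np.sqrt(13), 2) == 1.90


class TestClusterPermutation:
    def test_all_zero_no_clusters(self):
        res = cluster_permutation_test(np.zeros((8, 20)), n_permutations=100, seed=0)
        assert res.clusters == []

    def test_planted_effect_minimal_p(self, rng):
        diffs = rng.standard_normal((12, 40)) * 0.1
        diffs[:, 10:20] += 5.0
        res = cluster_permutation_test(diffs, n_permutations=999, seed=1)
        sig = res.significant_clusters()
        assert len(sig) == 1
        assert sig[0].start_idx <= 10 and sig[0].end_idx >= 19
        assert sig[0].p_fwe == pytest.approx(1 / 1000)

    def test_global_sign_flip_invariance(self, rng):
        diffs = rng.standard_normal((10, 30)) + 0.4
        res_pos = cluster_permutation_test(diffs, n_permutations=500, seed=3)
        res_neg = cluster_permutation_test(-diffs, n_permutations=500, seed=3)
        p_pos = sorted(c.p_fwe for c in res_pos.clusters)
        p_neg = sorted(c.p_fwe for c in res_neg.clusters)
        assert np.allclose(p_pos, p_neg)

    def test_matches_mne_implementation(self, rng):
        """Cross-check t values and cluster extents against MNE's
        one-sample cluster permutation test."""
        from mne.stats import permutation_cluster_1samp_test
        from scipy import stats

        diffs = rng.standard_normal((15, 50)) * 0.8
        diffs[:, 20:32] += 1.0
        thr = stats.t.ppf(1 - 0.025, df=14)
        t_mne, clusters_mne, pv_mne, _ = permutation_cluster_1samp_test(
            diffs, threshold=thr, n_permutations=1000, tail=0, seed=7, verbose=False)
        res = cluster_permutation_test(diffs, n_permutations=1000, seed=7)
        assert np.allclose(res.t, t_mne, atol=1e-8)
        pv_by_span = {(int(c[0].min()), int(c[0].max())): pv
                      for c, pv in zip(clusters_mne, pv_mne)}
        spans = {(c.start_idx, c.end_idx): c.p_fwe for c in res.clusters}
        assert sorted(spans) == sorted(pv_by_span)
        # permutation p values agree within Monte-Carlo tolerance
        for span, p in spans.items():
            assert abs(p - pv_by_span[span]) < 0.05


class TestPeakLatency:
    def test_identical_conditions(self, rng):
        tc = rng.standard_normal((10, 50))
        times = np.linspace(0, 12, 50)
        est, (lo, hi) = peak_latency_difference(tc, tc, times, n_bootstrap=200, seed=0)
        assert est == 0.0
        assert lo <= 0.0 <= hi

    def test_noiseless_shift_recovered(self):
        times = np.linspace(0, 12, 121)
        kernel = np.exp(-0.5 * ((times - 5.0) / 1.5) ** 2)
        tc_a = np.tile(kernel, (8, 1))
        shifted = np.exp(-0.5 * ((times - 6.0) / 1.5) ** 2)
        tc_b = np.tile(shifted, (8, 1))
        est, (lo, hi) = peak_latency_difference(tc_a, tc_b, times,
                                                n_bootstrap=200, seed=0)
        assert est == pytest.approx(1.0, abs=1e-9)
        assert lo == pytest.approx(1.0) and hi == pytest.approx(1.0)

    def test_noisy_shift_ci_covers(self, rng):
        times = np.linspace(0, 12, 61)
        kernel = np.exp(-0.5 * ((times - 5.0) / 1.5) ** 2)
        shifted = np.exp(-0.5 * ((times - 6.0) / 1.5) ** 2)
        covered = 0
        for rep in range(20):
            tc_a = kernel + 0.1 * rng.standard_normal((24, times.size))
            tc_b = shifted + 0.1 * rng.standard_normal((24, times.size))
            est, (lo, hi) = peak_latency_difference(tc_a, tc_b, times,
                                                    n_bootstrap=200, seed=rep)
            covered += lo - 1e-9 <= 1.0 <= hi + 1e-9
        assert covered >= 18
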