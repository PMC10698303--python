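"""Residualisation, correlation inference, clustering, condition contrasts."""

import numpy as np
import pytest

from localglobal.connectivity import (
    AlignmentError,
    block_type_scan_mask,
    cluster_regions,
    compare_conditions,
    correlation_analysis,
    cut_clusters,
    residualize_for_connectivity,
    to_newick,
)
from localglobal.paradigm import generate_experiment
from localglobal.roi import DegenerateSignalError, RoiTimeSeries
from localglobal.synth import GroundTruth, simulate_roi_dataset

REGIONS = ["lc", "snvta", "rn", "bf", "sc", "ic"]


def _subject(rng, n_scans=400, shared_blocks=((0, 1, 2), (3, 4, 5)), r_within=0.6):
    factors = [rng.standard_normal(n_scans) for _ in shared_blocks]
    out = {}
    for i, name in enumerate(REGIONS):
        f = next(factors[j] for j, blk in enumerate(shared_blocks) if i in blk)
        y = np.sqrt(r_within) * f + np.sqrt(1 - r_within) * rng.standard_normal(n_scans)
        out[name] = RoiTimeSeries(y, 1.25, (0,), name=name)
    return out


class TestResidualize:
    def test_stimulus_signal_removed(self):
        events = generate_experiment(1, seed=0)
        truth = GroundTruth(innovation_sd=0.3, drift_amplitude=0, physio_gain=0,
                            motion_gain=0, subject_sd=0)
        series, _, info = simulate_roi_dataset(events, truth, 500, rng=3,
                                               include_physio=False)
        resid = residualize_for_connectivity(series, events)
        stim = info["stimulus_signal"]
        r = np.corrcoef(resid["lc"].values, stim)[0, 1]
        assert abs(r) < 0.05

    def test_pure_stimulus_series_degenerates(self):
        events = generate_experiment(1, seed=0)
        truth = GroundTruth(innovation_sd=0, drift_amplitude=0, physio_gain=0,
                            motion_gain=0, subject_sd=0)
        series, _, _ = simulate_roi_dataset(events, truth, 500,
                                            include_physio=False)
        with pytest.raises(DegenerateSignalError):
            residualize_for_connectivity(series, events, upsample_factor=10)

    def test_orthogonal_series_preserved_up_to_scale(self, rng):
        events = generate_experiment(1, seed=0)
        y = rng.standard_normal(500)
        series = {"a": RoiTimeSeries(y, 1.25, (0,))}
        resid = residualize_for_connectivity(series, events)
        r = np.corrcoef(resid["a"].values, y)[0, 1]
        assert r > 0.95

    def test_latent_correlation_preserved(self, rng):
        events = generate_experiment(1, seed=0)
        latent = rng.standard_normal(500)
        truth = GroundTruth(innovation_sd=0, drift_amplitude=0, physio_gain=0,
                            motion_gain=0, subject_sd=0)
        series, _, info = simulate_roi_dataset(events, truth, 500,
                                               include_physio=False)
        stim = info["stimulus_signal"]
        mix = {}
        for name in ("a", "b"):
            noise = rng.standard_normal(500)
            mix[name] = RoiTimeSeries(stim + 0.7 * latent + 0.7 * noise, 1.25, (0,))
        resid = residualize_for_connectivity(mix, events)
        r = np.corrcoef(resid["a"].values, resid["b"].values)[0, 1]
        assert abs(r - 0.5) < 0.08


class TestCorrelationAnalysis:
    @pytest.fixture(scope="class")
    def result(self):
        rng = np.random.default_rng(5)
        subs = [_subject(np.random.default_rng(rng.integers(2**31)))
                for _ in range(12)]
        return correlation_analysis(subs)

    def test_unit_diagonal_and_symmetry(self, result):
        assert np.allclose(np.diag(result.correlation), 1.0)
        assert np.allclose(result.correlation, result.correlation.T)

    def test_pair_count_and_bonferroni_factor(self, result):
        assert result.n_pairs == 15
        iu = np.triu_indices(6, 1)
        ratio = result.p_bonferroni[iu] / result.p_raw[iu]
        capped = result.p_bonferroni[iu] >= 1.0
        assert np.allclose(ratio[~capped], 15)

    def test_shared_variance_expected_r(self, rng):
        # x = s + e1, y = s + e2 with equal variances -> r = 0.5
        subs = []
        for _ in range(6):
            s = rng.standard_normal(2000)
            subs.append({
                "x": RoiTimeSeries(s + rng.standard_normal(2000), 1.25, (0,)),
                "y": RoiTimeSeries(s + rng.standard_normal(2000), 1.25, (0,)),
            })
        res = correlation_analysis(subs)
        assert res.correlation[0, 1] == pytest.approx(0.5, abs=0.05)


class TestClustering:
    def test_identical_profiles_merge_at_zero(self):
        subs = []
        rng = np.random.default_rng(2)
        for _ in range(4):
            y = rng.standard_normal(300)
            subs.append({n: RoiTimeSeries(y.copy() + 1e-9 * rng.standard_normal(300),
                                          1.25, (0,)) for n in ["a", "b", "c"]})
        res = correlation_analysis(subs)
        res = cluster_regions(res)
        assert np.allclose(res.linkage_matrix[:, 2], 0.0, atol=1e-3)

    def test_planted_two_block_recovery(self):
        rng = np.random.default_rng(7)
        hits = 0
        for rep in range(20):
            subs = [_subject(np.random.default_rng(rng.integers(2**31)))
                    for _ in range(8)]
            res = cluster_regions(correlation_analysis(subs))
            labels = cut_clusters(res, 2)
            groups = {labels[r] for r in REGIONS[:3]}, {labels[r] for r in REGIONS[3:]}
            hits += len(groups[0]) == 1 and len(groups[1]) == 1 and groups[0] != groups[1]
        assert hits == 20

    def test_anticorrelated_region_merges_last(self, rng):
        n = 2000
        base = rng.standard_normal(n)
        subs = [{
            "a": RoiTimeSeries(base + 0.5 * rng.standard_normal(n), 1.25, (0,)),
            "b": RoiTimeSeries(base + 0.5 * rng.standard_normal(n), 1.25, (0,)),
            "c": RoiTimeSeries(base + 0.5 * rng.standard_normal(n), 1.25, (0,)),
            "anti": RoiTimeSeries(-base + 0.5 * rng.standard_normal(n), 1.25, (0,)),
        }]
        res = cluster_regions(correlation_analysis(subs))
        # the last merge joins the anticorrelated singleton
        labels = cut_clusters(res, 2)
        assert labels["anti"] != labels["a"]
        assert labels["a"] == labels["b"] == labels["c"]

    def test_region_order_invariance(self):
        rng = np.random.default_rng(9)
        subs = [_subject(np.random.default_rng(rng.integers(2**31)))
                for _ in range(6)]
        res1 = cluster_regions(correlation_analysis(subs))
        perm = ["ic", "lc", "bf", "snvta", "sc", "rn"]
        subs_perm = [{k: s[k] for k in perm} for s in subs]
        res2 = cluster_regions(correlation_analysis(subs_perm))
        assert cut_clusters(res1, 2) == cut_clusters(res2, 2)

    def test_cosine_profile_mode_and_newick(self):
        rng = np.random.default_rng(3)
        subs = [_subject(np.random.default_rng(rng.integers(2**31)))
                for _ in range(6)]
        res = correlation_analysis(subs)
        profiles = np.vstack([rng.standard_normal(10) + (i < 3) * 2
                              for i in range(6)])
        res = cluster_regions(res, mode="cortical-profile-cosine",
                              profile_matrix=profiles)
        nwk = to_newick(res)
        assert nwk.endswith(";") and all(r in nwk for r in REGIONS)


class TestCompareConditions:
    def _results(self, delta=0.0, n_sub=10, seed=0):
        rng = np.random.default_rng(seed)
        subsA, subsB = [], []
        for _ in range(n_sub):
            subsA.append(_subject(np.random.default_rng(rng.integers(2**31))))
            subsB.append(_subject(np.random.default_rng(rng.integers(2**31)),
                                  r_within=0.6 + delta))
        return correlation_analysis(subsA, "A"), correlation_analysis(subsB, "B")

    def test_identical_data_t_zero_p_one(self):
        a, _ = self._results()
        tab = compare_conditions(a, a)
        assert (tab["t"] == 0).all() and (tab["p"] == 1).all()

    def test_planted_difference_detected(self):
        a, b = self._results(delta=0.3, n_sub=16, seed=4)
        tab = compare_conditions(a, b)
        within = tab[(tab["region_a"].isin(REGIONS[:3]))
                     & (tab["region_b"].isin(REGIONS[:3]))]
        assert (within["p"] < 0.05).mean() > 0.5

    def test_subject_mismatch(self):
        a, _ = self._results(n_sub=6)
        b, _ = self._results(n_sub=8)
        with pytest.raises(AlignmentError):
            compare_conditions(a, b)


def test_block_type_scan_mask_partitions():
    events = generate_experiment(1, seed=0)
    mask_x = block_type_scan_mask(events, 500, 1.25, (0,), "xxxxx")
    mask_y = block_type_scan_mask(events, 500, 1.25, (0,), "xxxxY")
    assert not (mask_x & mask_y).any()
    assert mask_x.sum() > 100 and mask_y.sum() > 100
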