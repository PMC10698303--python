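"""Epoch-based deviance statistics over peristimulus time.

The epoch pipeline mirrors the assumption-free analysis of phasic
responses: the preprocessed ROI (or pupil) signal is linearly upsampled,
epoched from -2 s to 12 s around each pattern onset, baseline-corrected
with the -2..0 s mean, and averaged per condition cell of the
local x global factorial design.  Group inference over peristimulus time
uses paired t / Cohen's d time courses with family-wise error control by
a sign-flip cluster-mass permutation test (cluster-forming and
cluster-level alphas 0.05, two-tailed, 10,000 permutations by default).

Cohen's d follows the paired convention d = t / sqrt(n).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .roi import RoiTimeSeries

logger = logging.getLogger(__name__)

#: The four pattern-type cells of the design: (pattern, global_role).
CELLS = [
    ("xxxxx", "frequent"),
    ("xxxxY", "rare"),
    ("xxxxY", "frequent"),
    ("xxxxx", "rare"),
]


class EmptyEpochsError(ValueError):
    """No events survive epoching."""


class MissingConditionError(ValueError):
    """A subject lacks epochs in a required condition cell."""


@dataclass
class EpochSet:
    """Trials x peristimulus-time matrix on an upsampled grid.

    ``labels`` carries one row per trial (pattern, global_role, ...);
    after correction the baseline-window mean of every epoch is zero.
    """

    data: np.ndarray
    times: np.ndarray
    labels: pd.DataFrame
    baseline: tuple[float, float] = (-2.0, 0.0)
    subject: int | str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.shape != (len(self.labels), len(self.times)):
            raise ValueError("epoch matrix shape must be (n_trials, n_times)")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


@dataclass
class Cluster:
    """A maximal suprathreshold run over peristimulus time."""

    start_idx: int
    end_idx: int          # inclusive
    start_time: float
    end_time: float
    mass: float
    p_fwe: float


@dataclass
class ClusterTestResult:
    """Per-timepoint paired t and d plus FWE-corrected clusters."""

    times: np.ndarray
    t: np.ndarray
    d: np.ndarray
    clusters: list[Cluster] = field(default_factory=list)
    alpha_forming: float = 0.05
    alpha_cluster: float = 0.05
    n_permutations: int = 0
    tail: str = "two"
    n_subjects: int = 0

    @property
    def t_max(self) -> float:
        return float(self.t[np.nanargmax(np.abs(self.t))])

    @property
    def d_max(self) -> float:
        return float(self.d[np.nanargmax(np.abs(self.d))])

    def significant_clusters(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p_fwe <= self.alpha_cluster]


def make_epochs(
    series: RoiTimeSeries,
    events: pd.DataFrame,
    window: tuple[float, float] = (-2.0, 12.0),
    baseline: tuple[float, float] | None = (-2.0, 0.0),
    upsample_factor: int = 1000,
) -> EpochSet:
    """Epoch an ROI series around event onsets on an upsampled grid.

    The series is linearly upsampled by ``upsample_factor`` (grid spacing
    tr / factor) before epoching; the baseline-window mean is then
    subtracted from each epoch.  Events whose window would cross a
    session edge are dropped.
    """
    dt = series.tr / upsample_factor
    offsets = np.arange(int(round(window[0] / dt)), int(round(window[1] / dt)) + 1) * dt
    epochs, rows = [], []
    n_dropped = 0
    for s, sl in enumerate(series.session_slices()):
        values = series.values[sl]
        scan_times = np.arange(sl.stop - sl.start) * series.tr
        sess_events = events[events["session_index"] == s] if "session_index" in events \
            else events
        for _, ev in sess_events.iterrows():
            t0 = float(ev["onset"])
            if t0 + offsets[0] < scan_times[0] or t0 + offsets[-1] > scan_times[-1]:
                n_dropped += 1
                continue
            epochs.append(np.interp(t0 + offsets, scan_times, values))
            rows.append(ev)
    if not epochs:
        raise EmptyEpochsError("no events fall inside the usable scan span")
    if n_dropped:
        logger.info("dropped %d events too close to session edges", n_dropped)
    data = np.asarray(epochs)
    if baseline is not None:
        in_base = (offsets >= baseline[0]) & (offsets <= baseline[1])
        data = data - data[:, in_base].mean(axis=1, keepdims=True)
    return EpochSet(data, offsets, pd.DataFrame(rows).reset_index(drop=True),
                    baseline=baseline or (np.nan, np.nan))


def condition_timecourses(
    epochs: EpochSet,
    include_habituation: bool = True,
) -> dict:
    """Per-condition mean time courses and factorial contrast series.

    Returns the 4 cell means keyed by (pattern, global_role) plus the
    marginal contrasts: ``global`` (rare - frequent), ``local`` (local
    deviant - local standard) and ``interaction`` (difference of the
    global effect between block types).  Habituation trials count as
    frequent by default.
    """
    lab = epochs.labels.copy()
    if include_habituation:
        lab.loc[lab["global_role"] == "habituation", "global_role"] = "frequent"
    else:
        keep = lab["global_role"] != "habituation"
        lab = lab[keep]
    out: dict = {}
    for cell in CELLS:
        sel = (lab["pattern"] == cell[0]) & (lab["global_role"] == cell[1])
        if not sel.any():
            raise MissingConditionError(
                f"subject {epochs.subject!r} has no epochs in cell {cell}")
        out[cell] = epochs.data[lab.index[sel].to_numpy()].mean(axis=0)
    fx, ry = out[("xxxxx", "frequent")], out[("xxxxY", "rare")]
    fy, rx = out[("xxxxY", "frequent")], out[("xxxxx", "rare")]
    out["global"] = (ry + rx) / 2 - (fx + fy) / 2
    out["local"] = (ry + fy) / 2 - (rx + fx) / 2
    out["interaction"] = (ry - fx) - (rx - fy)
    out["times"] = epochs.times
    return out


def _paired_t(diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise paired t and Cohen's d = t/sqrt(n) for (n_subj, n_time) diffs."""
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    if np.any(~np.isfinite(t)):
        warnings.warn("zero variance at some timepoints; t reported as +/-inf")
        t = np.where(np.isnan(t), 0.0, t)
    d = t / np.sqrt(n)
    return t, d


def paired_t_d_timecourse(diffs: np.ndarray, times: np.ndarray | None = None) -> ClusterTestResult:
    """Paired t and Cohen's d time courses for per-subject difference curves."""
    diffs = np.asarray(diffs, dtype=float)
    if diffs.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    if times is None:
        times = np.arange(diffs.shape[1], dtype=float)
    t, d = _paired_t(diffs)
    return ClusterTestResult(np.asarray(times, float), t, d, n_subjects=diffs.shape[0])


def _find_clusters(t: np.ndarray, threshold: float) -> list[tuple[int, int, float]]:
    """Maximal runs with |t| > threshold; returns (start, end inclusive, mass)."""
    supra = np.abs(t) > threshold
    if not supra.any():
        return []
    edges = np.flatnonzero(np.diff(np.concatenate([[0], supra.view(np.int8), [0]])))
    starts, stops = edges[::2], edges[1::2]
    return [(int(a), int(b - 1), float(t[a:b].sum())) for a, b in zip(starts, stops)]


def cluster_permutation_test(
    diffs: np.ndarray,
    times: np.ndarray | None = None,
    alpha_forming: float = 0.05,
    alpha_cluster: float = 0.05,
    n_permutations: int = 10000,
    tail: str = "two",
    seed: int | np.random.Generator | None = 0,
) -> ClusterTestResult:
    """Sign-flip cluster-mass permutation test over peristimulus time.

    Clusters are maximal runs where |t| exceeds the two-sided t threshold
    at ``alpha_forming`` (df = n - 1); the cluster statistic is the mass
    (sum of t within the run).  The null distribution is the maximum
    absolute cluster mass over random per-subject sign flips, and
    p_FWE = (1 + #{null >= observed}) / (1 + n_permutations).
    """
    diffs = np.asarray(diffs, dtype=float)
    n, n_time = diffs.shape
    if times is None:
        times = np.arange(n_time, dtype=float)
    times = np.asarray(times, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if tail != "two":
        raise ValueError("only two-tailed tests are implemented")
    t_obs, d_obs = _paired_t(diffs)
    threshold = stats.t.ppf(1 - alpha_forming / 2, df=n - 1)
    observed = _find_clusters(t_obs, threshold)
    result = ClusterTestResult(times, t_obs, d_obs, [], alpha_forming, alpha_cluster,
                               n_permutations, tail, n)
    if not observed:
        return result

    # Sign flips leave sum(x^2) invariant, so the permuted t statistics
    # need only the permuted means.
    ss = np.einsum("st,st->t", diffs, diffs)
    signs = rng.choice([-1.0, 1.0], size=(n_permutations, n))
    null_max = np.empty(n_permutations)
    sqrt_n = np.sqrt(n)
    for p in range(n_permutations):
        mean_p = signs[p] @ diffs / n
        var_p = (ss - n * mean_p**2) / (n - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_p = mean_p / np.sqrt(var_p) * sqrt_n
        t_p = np.nan_to_num(t_p, nan=0.0, posinf=0.0, neginf=0.0)
        clusters_p = _find_clusters(t_p, threshold)
        null_max[p] = max((abs(m) for *_, m in clusters_p), default=0.0)
    for a, b, mass in observed:
        p_fwe = (1 + np.count_nonzero(null_max >= abs(mass))) / (1 + n_permutations)
        result.clusters.append(
            Cluster(a, b, float(times[a]), float(times[b]), mass, float(p_fwe)))
    return result


def peak_latency_difference(
    tc_a: np.ndarray,
    tc_b: np.ndarray,
    times: np.ndarray,
    search_window: tuple[float, float] | None = None,
    n_bootstrap: int = 10000,
    seed: int | np.random.Generator | None = 0,
) -> tuple[float, tuple[float, float]]:
    """Peak-latency difference (B - A) of group-mean time courses with a
    subject-level percentile-bootstrap 95% CI.

    The peak is the argmax of the group-mean curve within the search
    window; a tied maximum resolves to the earliest timepoint.
    """
    tc_a, tc_b = np.asarray(tc_a, float), np.asarray(tc_b, float)
    times = np.asarray(times, float)
    if search_window is None:
        search_window = (times[0], times[-1])
    sel = (times >= search_window[0]) & (times <= search_window[1])
    t_sel = times[sel]

    def peak_diff(idx: np.ndarray) -> float:
        pa = t_sel[np.argmax(tc_a[idx].mean(axis=0)[sel])]
        pb = t_sel[np.argmax(tc_b[idx].mean(axis=0)[sel])]
        return float(pb - pa)

    n = tc_a.shape[0]
    estimate = peak_diff(np.arange(n))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    boots = np.empty(n_bootstrap)
    for i in range(n_bootstrap):
        boots[i] = peak_diff(rng.integers(0, n, size=n))
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return estimate, (float(lo), float(hi))
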