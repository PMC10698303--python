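"""Intrinsic-signal connectivity among ROIs and hierarchical clustering.

Stimulus-evoked variance (canonical-HRF regressors for the four pattern
types) and confounds are regressed out per session before correlating
residual signals between regions.  Group-level significance per pair
uses a one-sample t test on Fisher-z correlations across subjects, with
Bonferroni correction over the distinct pairs.  Regions are clustered
agglomeratively with average linkage, either on the correlation distance
(1 - r) between subcortical residuals or on the cosine distance between
rows of the subcortico-cortical correlation matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .firglm import build_design
from .roi import DegenerateSignalError, RoiTimeSeries, _residualize


class AlignmentError(ValueError):
    """Condition results do not share subjects/regions."""


def residualize_for_connectivity(
    series_set: dict[str, RoiTimeSeries],
    events: pd.DataFrame,
    confounds: np.ndarray | pd.DataFrame | None = None,
    upsample_factor: int = 5,
) -> dict[str, RoiTimeSeries]:
    """Remove stimulus-evoked and confound variance from each ROI series.

    The stimulus model is one canonical-HRF regressor per pattern-type
    cell; residuals are z-scored per session.  All series must share the
    scan grid.
    """
    first = next(iter(series_set.values()))
    design = build_design(
        events, "HRF", first.n_scans, first.tr,
        upsample_factor=upsample_factor, confounds=confounds,
        session_boundaries=first.session_boundaries,
    )
    stim_conf = design.matrix[:, :-len(first.session_boundaries)]  # drop intercepts
    out: dict[str, RoiTimeSeries] = {}
    for name, series in series_set.items():
        if series.n_scans != first.n_scans or series.session_boundaries != first.session_boundaries:
            raise ValueError("all series must share the scan grid")
        values = np.empty(series.n_scans)
        for sl in series.session_slices():
            r = _residualize(series.values[sl].astype(float), stim_conf[sl])
            sd = r.std()
            if sd < 1e-10:
                raise DegenerateSignalError(f"residual of {name!r} is degenerate")
            values[sl] = r / sd
        out[name] = RoiTimeSeries(values, series.tr, series.session_boundaries,
                                  name=name, flags=series.flags + ("residualized",))
    return out


@dataclass
class ConnectivityResult:
    """Region x region intrinsic-correlation summary for one condition."""

    regions: list[str]
    correlation: np.ndarray            # group-mean r (tanh of mean Fisher z)
    subject_z: np.ndarray              # subjects x regions x regions Fisher z
    p_raw: np.ndarray
    p_bonferroni: np.ndarray
    condition: str = "all"
    linkage_matrix: np.ndarray | None = None
    distance: np.ndarray | None = None
    distance_mode: str | None = None

    @property
    def n_pairs(self) -> int:
        n = len(self.regions)
        return n * (n - 1) // 2

    def significant(self, alpha: float = 0.05, corrected: bool = True) -> np.ndarray:
        p = self.p_bonferroni if corrected else self.p_raw
        return p <= alpha


def _fisher_z(r: np.ndarray, cap: float = 7.0) -> np.ndarray:
    return np.clip(np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12)), -cap, cap)


def correlation_analysis(
    subject_series: list[dict[str, RoiTimeSeries]],
    condition: str = "all",
    scan_mask: np.ndarray | None = None,
) -> ConnectivityResult:
    """Subject-level Pearson matrices and group tests per region pair.

    ``scan_mask`` optionally restricts the correlation to a subset of
    scans (e.g. scans belonging to one block type).  A pair is marked
    undefined (NaN) when a residual is constant.
    """
    regions = list(subject_series[0].keys())
    n = len(regions)
    if n < 2:
        raise ValueError("need at least 2 regions")
    zs = np.empty((len(subject_series), n, n))
    for s, series_set in enumerate(subject_series):
        mat = np.vstack([series_set[r].values for r in regions])
        if scan_mask is not None:
            mat = mat[:, scan_mask]
        if mat.shape[1] < 30:
            raise ValueError("need at least 30 scans per subject")
        sds = mat.std(axis=1)
        corr = np.full((n, n), np.nan)
        ok = sds > 0
        if ok.any():
            sub = np.corrcoef(mat[ok])
            corr[np.ix_(ok, ok)] = sub
        zs[s] = _fisher_z(corr)
        np.fill_diagonal(zs[s], 0.0)
    iu = np.triu_indices(n, k=1)
    p_raw = np.full((n, n), np.nan)
    for i, j in zip(*iu):
        vals = zs[:, i, j]
        if np.isnan(vals).any():
            continue
        res = stats.ttest_1samp(vals, 0.0)
        p_raw[i, j] = p_raw[j, i] = res.pvalue
    m = n * (n - 1) // 2
    p_bonf = np.minimum(p_raw * m, 1.0)
    corr_group = np.tanh(zs.mean(axis=0))
    np.fill_diagonal(corr_group, 1.0)
    np.fill_diagonal(p_raw, np.nan)
    np.fill_diagonal(p_bonf, np.nan)
    return ConnectivityResult(regions, corr_group, zs, p_raw, p_bonf, condition)


def cluster_regions(
    result: ConnectivityResult,
    mode: str = "subcortical-correlation-distance",
    profile_matrix: np.ndarray | None = None,
) -> ConnectivityResult:
    """Agglomerative clustering of regions with average linkage.

    ``subcortical-correlation-distance``: distance = 1 - group-mean r on
    the region x region matrix.  ``cortical-profile-cosine``: rows of
    ``profile_matrix`` (region x cortical-correlation profile) compared
    with cosine distance.  Fills ``linkage_matrix``/``distance`` in place
    and returns the result.
    """
    if mode == "subcortical-correlation-distance":
        dist = 1.0 - result.correlation
        np.fill_diagonal(dist, 0.0)
        if np.isnan(dist).any():
            bad = [(result.regions[i], result.regions[j])
                   for i, j in zip(*np.where(np.isnan(dist)))]
            raise ValueError(f"undefined distances for pairs: {bad}")
        condensed = squareform(np.maximum(dist, 0.0), checks=False)
    elif mode == "cortical-profile-cosine":
        if profile_matrix is None:
            raise ValueError("cortical-profile-cosine mode needs a profile matrix")
        if np.isnan(profile_matrix).any():
            raise ValueError("profile matrix contains undefined entries")
        condensed = pdist(np.asarray(profile_matrix, float), metric="cosine")
    else:
        raise ValueError(f"unknown clustering mode {mode!r}")
    result.linkage_matrix = linkage(condensed, method="average")
    result.distance = squareform(condensed)
    result.distance_mode = mode
    return result


def cut_clusters(result: ConnectivityResult, n_clusters: int) -> dict[str, int]:
    """Flat cluster assignment at a given number of clusters."""
    if result.linkage_matrix is None:
        raise ValueError("run cluster_regions first")
    labels = fcluster(result.linkage_matrix, t=n_clusters, criterion="maxclust")
    return dict(zip(result.regions, labels.tolist()))


def to_newick(result: ConnectivityResult) -> str:
    """The cluster tree as a newick string with branch lengths."""
    from skbio.tree import TreeNode

    tree = TreeNode.from_linkage_matrix(result.linkage_matrix, result.regions)
    return str(tree).strip()


def compare_conditions(
    result_a: ConnectivityResult,
    result_b: ConnectivityResult,
) -> pd.DataFrame:
    """Per-pair paired t tests between two conditions' Fisher-z correlations."""
    if result_a.regions != result_b.regions or \
            result_a.subject_z.shape[0] != result_b.subject_z.shape[0]:
        raise AlignmentError("conditions must share regions and subjects")
    n = len(result_a.regions)
    m = n * (n - 1) // 2
    rows = []
    for i, j in zip(*np.triu_indices(n, k=1)):
        za = result_a.subject_z[:, i, j]
        zb = result_b.subject_z[:, i, j]
        diff = za - zb
        if np.allclose(diff, 0.0):
            tval, pval = 0.0, 1.0
        else:
            res = stats.ttest_rel(za, zb)
            tval, pval = float(res.statistic), float(res.pvalue)
        rows.append({
            "region_a": result_a.regions[i],
            "region_b": result_a.regions[j],
            "t": tval,
            "p": pval,
            "p_bonferroni": min(pval * m, 1.0),
        })
    return pd.DataFrame(rows)


def block_type_scan_mask(
    events: pd.DataFrame,
    n_scans: int,
    tr: float,
    session_boundaries: tuple[int, ...],
    rare_pattern: str,
) -> np.ndarray:
    """Boolean scan mask for blocks whose rare pattern is ``rare_pattern``.

    Scans are assigned to the block whose span (first onset to last
    offset) contains them; boundary scans split at block edges.
    """
    mask = np.zeros(n_scans, dtype=bool)
    edges = list(session_boundaries) + [n_scans]
    for s, (start, stop) in enumerate(zip(edges[:-1], edges[1:])):
        sess = events[events["session_index"] == s] if "session_index" in events else events
        for b, block in sess.groupby("block_index"):
            rare_rows = block[block["global_role"] == "rare"]
            if rare_rows.empty or rare_rows["pattern"].iloc[0] != rare_pattern:
                continue
            t0 = block["onset"].min()
            t1 = (block["onset"] + block["duration"]).max()
            scans = np.arange(stop - start) * tr
            mask[start:stop] |= (scans >= t0) & (scans <= t1)
    return mask
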