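"""Design matrices (FIR and canonical HRF) and AR(1)-prewhitened GLMs.

These are the complementary analyses to the epoch approach: both model
the superposition of responses to successive patterns explicitly.  The
FIR model estimates one amplitude per post-stimulus time bin over
0..12 s on a grid upsampled 5x relative to the TR (48 bins at
TR = 1.25 s), by default for rare patterns only.  The GLM convolves
stick functions for the four pattern-type cells with the canonical
double-gamma HRF and estimates subject-level betas under an AR(1) noise
model (two-pass: OLS, lag-1 residual autocorrelation, prewhitened GLS).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .deviance import CELLS, cluster_permutation_test
from .roi import RoiTimeSeries


class IdentifiabilityError(ValueError):
    """More design columns than scans."""


def canonical_hrf(
    time_grid: np.ndarray,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    peak_dispersion: float = 1.0,
    undershoot_dispersion: float = 1.0,
    undershoot_ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, scaled to unit peak.

    Difference of two gamma densities (response peaking near 5 s,
    undershoot near 15 s, amplitude ratio 1/6); zero for t <= 0 and
    beyond the 32 s support.
    """
    t = np.asarray(time_grid, dtype=float)

    def gpdf(x, delay, disp):
        a, b = delay / disp, 1.0 / disp
        with np.errstate(divide="ignore"):
            logpdf = a * np.log(b) + (a - 1) * np.log(np.where(x > 0, x, 1.0)) \
                - b * x - gammaln(a)
        return np.where(x > 0, np.exp(logpdf), 0.0)

    h = gpdf(t, peak_delay, peak_dispersion) \
        - undershoot_ratio * gpdf(t, undershoot_delay, undershoot_dispersion)
    h = np.where((t > 0) & (t <= 32.0), h, 0.0)
    peak = np.abs(h).max()
    return h / peak if peak > 0 else h


@dataclass
class DesignMatrix:
    """Scans x regressors design with named columns."""

    matrix: np.ndarray
    names: list[str]
    mode: str                      # "FIR" | "HRF"
    tr: float
    upsample_factor: int
    n_stimulus_columns: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[1] != len(self.names):
            raise ValueError("column names must match matrix width")

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]


def _session_lengths(n_scans: int, session_boundaries: tuple[int, ...]) -> list[int]:
    edges = list(session_boundaries) + [n_scans]
    return [b - a for a, b in zip(edges[:-1], edges[1:])]


def build_design(
    events: pd.DataFrame,
    mode: str,
    n_scans: int,
    tr: float = 1.25,
    window: tuple[float, float] = (0.0, 12.0),
    upsample_factor: int = 5,
    confounds: np.ndarray | pd.DataFrame | None = None,
    session_boundaries: tuple[int, ...] = (0,),
    rare_only: bool = True,
    include_habituation: bool = True,
    highpass_cutoff: float | None = 1.0 / 128,
) -> DesignMatrix:
    """Build a scans x columns design matrix in FIR or HRF mode.

    FIR mode places stick functions on a tr/upsample_factor grid and
    forms one indicator column per post-stimulus bin over ``window``
    (rare patterns only by default; ``rare_only=False`` models the four
    cells separately).  HRF mode convolves per-cell sticks with the
    canonical HRF.  Confound columns and one intercept per session are
    appended.  Event onsets are relative to their session start.
    """
    if mode not in ("FIR", "HRF"):
        raise ValueError(f"unknown design mode {mode!r}")
    dt = tr / upsample_factor
    lengths = _session_lengths(n_scans, tuple(session_boundaries))
    ev = events.copy()
    if include_habituation:
        ev.loc[ev["global_role"] == "habituation", "global_role"] = "frequent"
    else:
        ev = ev[ev["global_role"] != "habituation"]

    if mode == "FIR":
        n_bins = int(round((window[1] - window[0]) / dt))
        groups = [("rare", ev["global_role"] == "rare")] if rare_only else [
            (f"{p}_{r}", (ev["pattern"] == p) & (ev["global_role"] == r)) for p, r in CELLS]
        names = [f"fir_{g}_bin{j:03d}" for g, _ in groups for j in range(n_bins)]
        stim = np.zeros((n_scans, len(names)))
        for s, (start, n_sess) in enumerate(zip(session_boundaries, lengths)):
            n_fine = n_sess * upsample_factor
            sess = ev[ev["session_index"] == s] if "session_index" in ev else ev
            scan_rows = np.arange(n_sess) * upsample_factor
            for gi, (_, sel) in enumerate(groups):
                fine = np.zeros((n_fine, n_bins))
                onset_bins = np.round(
                    (sess.loc[sel[sess.index], "onset"].to_numpy() + window[0]) / dt
                ).astype(int)
                for b0 in onset_bins:
                    if b0 + n_bins > n_fine or b0 < 0:
                        hi = min(n_fine, b0 + n_bins)
                        js = np.arange(max(0, -b0), hi - b0)
                        fine[b0 + js, js] += 1.0
                    else:
                        fine[b0 + np.arange(n_bins), np.arange(n_bins)] += 1.0
                stim[start:start + n_sess, gi * n_bins:(gi + 1) * n_bins] = fine[scan_rows]
    else:  # HRF
        names = [f"hrf_{p}_{r}" for p, r in CELLS]
        stim = np.zeros((n_scans, len(CELLS)))
        for s, (start, n_sess) in enumerate(zip(session_boundaries, lengths)):
            n_fine = n_sess * upsample_factor
            sess = ev[ev["session_index"] == s] if "session_index" in ev else ev
            kernel = canonical_hrf(np.arange(1, int(round(32.0 / dt)) + 1) * dt)
            scan_rows = np.arange(n_sess) * upsample_factor
            for ci, (p, r) in enumerate(CELLS):
                sel = (sess["pattern"] == p) & (sess["global_role"] == r)
                sticks = np.zeros(n_fine)
                idx = np.round(sess.loc[sel, "onset"].to_numpy() / dt).astype(int)
                idx = idx[(idx >= 0) & (idx < n_fine)]
                np.add.at(sticks, idx, 1.0)
                conv = np.convolve(sticks, kernel)[:n_fine]
                stim[start:start + n_sess, ci] = conv[scan_rows]

    blocks = [stim]
    if confounds is not None:
        conf = np.asarray(confounds, dtype=float)
        if conf.ndim == 1:
            conf = conf[:, None]
        if conf.shape[0] != n_scans:
            raise ValueError("confound rows must equal the scan count")
        if isinstance(confounds, pd.DataFrame):
            names += [str(c) for c in confounds.columns]
        else:
            names += [f"confound{j}" for j in range(conf.shape[1])]
        blocks.append(conf)
    if highpass_cutoff:
        from .roi import dct_highpass_basis
        for s, (start, n_sess) in enumerate(zip(session_boundaries, lengths)):
            basis = dct_highpass_basis(n_sess, tr, highpass_cutoff)
            block = np.zeros((n_scans, basis.shape[1]))
            block[start:start + n_sess] = basis
            blocks.append(block)
            names += [f"dct_sess{s}_{k}" for k in range(basis.shape[1])]
    intercepts = np.zeros((n_scans, len(lengths)))
    for s, (start, n_sess) in enumerate(zip(session_boundaries, lengths)):
        intercepts[start:start + n_sess, s] = 1.0
    names += [f"intercept_sess{s}" for s in range(len(lengths))]
    blocks.append(intercepts)
    X = np.column_stack(blocks)
    return DesignMatrix(X, names, mode, tr, upsample_factor, stim.shape[1])


@dataclass
class GlmFit:
    """Subject-level GLM estimates under an AR(1) noise model."""

    betas: pd.Series
    ar_coefficient: float
    residual_variance: float
    contrasts: pd.DataFrame = field(default_factory=pd.DataFrame)
    dof: int = 0


def _prewhiten(arr: np.ndarray, rho: float, slices: list[slice]) -> np.ndarray:
    out = np.empty_like(arr, dtype=float)
    for sl in slices:
        a = arr[sl]
        out[sl] = np.concatenate([np.sqrt(1 - rho**2) * a[:1], a[1:] - rho * a[:-1]])
    return out


def fit_glm_ar1(
    series: RoiTimeSeries,
    design: DesignMatrix,
    contrasts: dict[str, dict[str, float]] | None = None,
) -> GlmFit:
    """Two-pass AR(1) GLM: OLS, lag-1 residual autocorrelation pooled over
    sessions, prewhitening, then GLS betas and contrast standard errors."""
    X, y = design.matrix, series.values
    n, p = X.shape
    if n <= p:
        raise IdentifiabilityError(f"{n} scans cannot identify {p} columns")
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta_ols
    num = den = 0.0
    for sl in series.session_slices():
        r = resid[sl]
        num += float(r[1:] @ r[:-1])
        den += float(r @ r)
    rho = 0.0 if den < 1e-30 else float(np.clip(num / den, -0.99, 0.99))
    slices = series.session_slices()
    Xw = np.column_stack([_prewhiten(X[:, j], rho, slices) for j in range(p)])
    yw = _prewhiten(y, rho, slices)
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid_w = yw - Xw @ beta
    dof = n - np.linalg.matrix_rank(Xw)
    sigma2 = float(resid_w @ resid_w) / max(dof, 1)
    cov = sigma2 * np.linalg.pinv(Xw.T @ Xw)

    rows = []
    if contrasts:
        for cname, weights in contrasts.items():
            c = np.zeros(p)
            for col, w in weights.items():
                c[design.names.index(col)] = w
            est = float(c @ beta)
            se = float(np.sqrt(c @ cov @ c))
            tval = est / se if se > 0 else np.inf * np.sign(est)
            pval = 2 * stats.t.sf(abs(tval), dof)
            rows.append({"contrast": cname, "estimate": est, "se": se,
                         "t": tval, "p": pval})
    return GlmFit(
        betas=pd.Series(beta, index=design.names),
        ar_coefficient=rho,
        residual_variance=sigma2,
        contrasts=pd.DataFrame(rows),
        dof=dof,
    )


RARE_MINUS_FREQUENT = {
    "hrf_xxxxY_rare": 0.5, "hrf_xxxxx_rare": 0.5,
    "hrf_xxxxx_frequent": -0.5, "hrf_xxxxY_frequent": -0.5,
}


def group_test(values, times: np.ndarray | None = None, **cluster_kwargs):
    """Group-level inference on subject-level effects.

    Scalar contrasts (1D array, one value per subject) are tested against
    zero with a one-sample t test, returning ``(t, p)``.  FIR beta time
    courses (subjects x bins) are passed to the cluster-mass permutation
    test and return a :class:`~localglobal.deviance.ClusterTestResult`.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 1:
        if arr.shape[0] < 2:
            raise ValueError("need at least 2 subjects")
        if arr.std(ddof=1) == 0 and arr.mean() == 0:
            return 0.0, 1.0
        res = stats.ttest_1samp(arr, 0.0)
        return float(res.statistic), float(res.pvalue)
    return cluster_permutation_test(arr, times=times, **cluster_kwargs)
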