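"""End-to-end conveniences chaining the analysis stages.

These helpers run the standard subject-level pipelines (preprocess ->
epoch -> condition contrasts; FIR fit; GLM fit) over a simulated or
loaded multi-subject study, producing the per-subject inputs that the
group statistics consume.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .deviance import condition_timecourses, make_epochs
from .firglm import RARE_MINUS_FREQUENT, build_design, fit_glm_ar1
from .roi import RoiTimeSeries, preprocess_timeseries


def preprocess_subject(subject: dict, roi: str,
                       use_confounds: bool = True) -> RoiTimeSeries:
    """High-pass + confound-regress + z-score one subject's ROI series."""
    series = subject["series"][roi]
    conf = subject["confounds"].to_numpy() if use_confounds else None
    return preprocess_timeseries(series, conf)


def epoch_global_effect(
    study: list[dict],
    roi: str = "lc",
    window: tuple[float, float] = (-2.0, 12.0),
    baseline: tuple[float, float] = (-2.0, 0.0),
    upsample_factor: int = 8,
    use_confounds: bool = True,
    contrast: str = "global",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject contrast time courses from the epoch pipeline.

    Returns (subjects x timepoints difference curves, time grid).
    ``contrast`` may be ``global``, ``local`` or ``interaction``.
    """
    diffs, times = [], None
    for subject in study:
        series = preprocess_subject(subject, roi, use_confounds)
        epochs = make_epochs(series, subject["events"], window, baseline,
                             upsample_factor)
        tc = condition_timecourses(epochs)
        diffs.append(tc[contrast])
        times = tc["times"]
    return np.asarray(diffs), times


def epoch_condition_means(
    study: list[dict],
    roi: str = "lc",
    **kwargs,
) -> tuple[dict, np.ndarray]:
    """Per-subject cell-mean time courses, stacked as subjects x time."""
    per_cell: dict = {}
    times = None
    for subject in study:
        series = preprocess_subject(subject, roi, kwargs.pop("use_confounds", True))
        epochs = make_epochs(series, subject["events"], **kwargs)
        tc = condition_timecourses(epochs)
        times = tc.pop("times")
        for key, val in tc.items():
            per_cell.setdefault(key, []).append(val)
    return {k: np.asarray(v) for k, v in per_cell.items()}, times


def glm_contrasts(study: list[dict], roi: str = "lc",
                  use_confounds: bool = True) -> pd.DataFrame:
    """Subject-level rare-frequent GLM contrasts under AR(1) noise."""
    rows = []
    for i, subject in enumerate(study):
        series = subject["series"][roi]
        conf = subject["confounds"] if use_confounds else None
        design = build_design(subject["events"], "HRF", series.n_scans, series.tr,
                              confounds=conf,
                              session_boundaries=series.session_boundaries)
        fit = fit_glm_ar1(series, design,
                          contrasts={"rare_minus_frequent": RARE_MINUS_FREQUENT})
        row = fit.contrasts.iloc[0].to_dict()
        row.update(subject=i, ar_coefficient=fit.ar_coefficient)
        rows.append(row)
    return pd.DataFrame(rows)


def fir_betas(
    study: list[dict],
    roi: str = "lc",
    window: tuple[float, float] = (0.0, 12.0),
    upsample_factor: int = 5,
    use_confounds: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Subject-level FIR beta time courses for rare patterns.

    Returns (subjects x bins betas, bin-centre times).
    """
    betas = []
    for subject in study:
        series = subject["series"][roi]
        conf = subject["confounds"] if use_confounds else None
        design = build_design(subject["events"], "FIR", series.n_scans, series.tr,
                              window=window, upsample_factor=upsample_factor,
                              confounds=conf,
                              session_boundaries=series.session_boundaries)
        fit = fit_glm_ar1(series, design)
        betas.append(fit.betas.iloc[:design.n_stimulus_columns].to_numpy())
    dt = study[0]["series"][roi].tr / upsample_factor
    n_bins = len(betas[0])
    times = window[0] + (np.arange(n_bins) + 0.5) * dt
    return np.asarray(betas), times


def epoch_effect_scalar(diffs: np.ndarray, times: np.ndarray,
                        window: tuple[float, float] = (2.0, 8.0)) -> np.ndarray:
    """Collapse per-subject difference curves to a mean over a response window."""
    sel = (times >= window[0]) & (times <= window[1])
    return diffs[:, sel].mean(axis=1)
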