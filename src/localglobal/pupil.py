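"""Pupillometry preprocessing, epoch selection, and pupil-ROI coupling.

The preprocessing chain: (1) expand each annotated blink by a 50 ms
margin and merge overlaps, (2) interpolate linearly across each blink,
(3) zero-phase low-pass filter at 5 Hz, then z-score per session.
Epochs span -0.5..3 s around pattern onsets; an epoch is dropped when
blinks cover more than 20% of it, and a subject is excluded from pupil
analyses when fewer than 20% of their epochs survive.

Trial-wise pupil-ROI coupling correlates single-trial response
amplitudes (window means) across modalities within subject and tests
the Fisher-z transformed correlations against zero at the group level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal, stats

from .deviance import EpochSet


class UnusableTraceError(ValueError):
    """Blink coverage (or another defect) leaves no usable pupil signal."""


@dataclass
class PupilTrace:
    """Continuous pupil-size samples for one session with blink annotations."""

    values: np.ndarray
    sampling_rate: float
    blinks: list[tuple[float, float]] = field(default_factory=list)
    session: int = 0
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling rate must be positive")
        dur = self.duration
        for s, e in self.blinks:
            if e < s or s < 0 or e > dur:
                raise ValueError(f"blink ({s}, {e}) outside the trace span")

    @property
    def duration(self) -> float:
        return (len(self.values) - 1) / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.sampling_rate


def merge_intervals(intervals, margin: float = 0.0, clip: tuple[float, float] | None = None):
    """Expand intervals by ``margin`` on both sides and merge overlaps."""
    if not intervals:
        return []
    grown = [(s - margin, e + margin) for s, e in intervals]
    if clip is not None:
        grown = [(max(clip[0], s), min(clip[1], e)) for s, e in grown]
    grown.sort()
    merged = [list(grown[0])]
    for s, e in grown[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(iv) for iv in merged]


def preprocess_pupil(
    trace: PupilTrace,
    margin: float = 0.050,
    lowpass: float = 5.0,
    zscore: bool = True,
) -> PupilTrace:
    """Blink-interpolate, low-pass, and z-score a pupil trace.

    Blinks are widened by ``margin`` seconds and merged, the signal is
    linearly interpolated across each interval, filtered with a
    zero-phase (forward-backward) Butterworth low-pass at ``lowpass`` Hz,
    and finally z-scored over the session.
    """
    if trace.sampling_rate <= 2 * lowpass:
        raise ValueError("sampling rate must exceed twice the low-pass cutoff")
    fs, dur = trace.sampling_rate, trace.duration
    blinks = merge_intervals(trace.blinks, margin=margin, clip=(0.0, dur))
    covered = sum(e - s for s, e in blinks)
    if covered >= dur:
        raise UnusableTraceError("blinks cover the entire trace")
    y = trace.values.copy()
    t = trace.times
    for s, e in blinks:
        inside = (t >= s) & (t <= e)
        if not inside.any():
            continue
        lo = np.flatnonzero(inside)[0]
        hi = np.flatnonzero(inside)[-1]
        x0 = lo - 1 if lo > 0 else hi + 1
        x1 = hi + 1 if hi + 1 < len(y) else lo - 1
        y[inside] = np.interp(t[inside], [t[x0], t[x1]], [y[x0], y[x1]]) \
            if x0 >= 0 and x1 < len(y) and x0 != x1 else y[min(max(x0, 0), len(y) - 1)]
    flags = ("blink-interpolated", "low-passed")
    sos = signal.butter(3, lowpass, btype="low", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos, y)
    if zscore:
        sd = y.std()
        if sd < 1e-12:
            warnings.warn("degenerate pupil trace: zero variance after filtering")
            flags += ("degenerate",)
        else:
            y = (y - y.mean()) / sd
            flags += ("z-scored",)
    return replace(trace, values=y, blinks=blinks, flags=trace.flags + flags)


@dataclass
class InclusionReport:
    """Outcome of epoch-level and subject-level pupil exclusion rules."""

    n_events: int
    n_kept: int
    valid_fraction: float
    subject_included: bool
    blink_fractions: np.ndarray = field(default_factory=lambda: np.empty(0))


def _blink_fraction(blinks, start: float, end: float) -> float:
    covered = sum(max(0.0, min(e, end) - max(s, start)) for s, e in blinks)
    return covered / (end - start)


def epoch_and_select(
    trace: PupilTrace,
    events: pd.DataFrame,
    window: tuple[float, float] = (-0.5, 3.0),
    baseline: tuple[float, float] = (-0.5, 0.0),
    blink_fraction_max: float = 0.20,
    subject_valid_fraction_min: float = 0.20,
) -> tuple[EpochSet | None, InclusionReport]:
    """Epoch a preprocessed pupil trace and apply the exclusion rules.

    An epoch is dropped iff its blink fraction strictly exceeds
    ``blink_fraction_max``; the subject is excluded iff the surviving
    fraction is strictly below ``subject_valid_fraction_min``.  Epochs
    are baseline-corrected with the mean over ``baseline``.
    """
    dt = 1.0 / trace.sampling_rate
    offsets = np.arange(int(round(window[0] / dt)), int(round(window[1] / dt)) + 1) * dt
    sess_events = events[events["session_index"] == trace.session] \
        if "session_index" in events else events
    epochs, rows, fracs = [], [], []
    t = trace.times
    for _, ev in sess_events.iterrows():
        t0 = float(ev["onset"])
        if t0 + offsets[0] < 0 or t0 + offsets[-1] > trace.duration:
            continue
        frac = _blink_fraction(trace.blinks, t0 + window[0], t0 + window[1])
        fracs.append(frac)
        if frac > blink_fraction_max:
            continue
        epochs.append(np.interp(t0 + offsets, t, trace.values))
        rows.append(ev)
    n_events = len(fracs)
    n_kept = len(epochs)
    valid = n_kept / n_events if n_events else 0.0
    included = valid >= subject_valid_fraction_min and n_kept > 0
    report = InclusionReport(n_events, n_kept, valid, included, np.asarray(fracs))
    if n_kept == 0:
        return None, report
    data = np.asarray(epochs)
    in_base = (offsets >= baseline[0]) & (offsets <= baseline[1])
    data = data - data[:, in_base].mean(axis=1, keepdims=True)
    eps = EpochSet(data, offsets, pd.DataFrame(rows).reset_index(drop=True),
                   baseline=baseline)
    return eps, report


def trialwise_coupling(
    pupil_epochs: list[EpochSet],
    roi_epochs: list[EpochSet],
    pupil_window: tuple[float, float] = (0.5, 2.5),
    roi_window: tuple[float, float] = (2.0, 8.0),
    min_trials: int = 5,
    fisher_z_cap: float = 5.0,
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Trial-wise coupling between pupil and ROI response amplitudes.

    Per subject: single-trial amplitudes are window means, trials are
    matched on the ``trial`` label column (or row order), and amplitudes
    are correlated (Pearson).  The group test is a one-sample t on the
    Fisher-z correlations (|z| capped to guard r = +/-1).
    Returns (per-subject table, (t, p)).
    """
    rows = []
    for subj, (pe, re_) in enumerate(zip(pupil_epochs, roi_epochs)):
        if pe is None or re_ is None:
            continue
        pa = pe.data[:, (pe.times >= pupil_window[0]) & (pe.times <= pupil_window[1])].mean(axis=1)
        ra = re_.data[:, (re_.times >= roi_window[0]) & (re_.times <= roi_window[1])].mean(axis=1)
        if "trial" in pe.labels.columns and "trial" in re_.labels.columns:
            ps = pd.Series(pa, index=pe.labels["trial"])
            rs = pd.Series(ra, index=re_.labels["trial"])
            common = ps.index.intersection(rs.index)
            pa, ra = ps.loc[common].to_numpy(), rs.loc[common].to_numpy()
        else:
            k = min(len(pa), len(ra))
            pa, ra = pa[:k], ra[:k]
        if len(pa) < min_trials:
            warnings.warn(f"subject {subj}: fewer than {min_trials} matched trials; dropped")
            continue
        r = float(np.corrcoef(pa, ra)[0, 1]) if pa.std() > 0 and ra.std() > 0 else np.nan
        if np.isnan(r):
            continue
        z = float(np.clip(np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12)),
                          -fisher_z_cap, fisher_z_cap))
        rows.append({"subject": subj, "n_trials": len(pa), "r": r, "fisher_z": z})
    table = pd.DataFrame(rows)
    if len(table) < 2:
        return table, (np.nan, np.nan)
    res = stats.ttest_1samp(table["fisher_z"].to_numpy(), 0.0)
    return table, (float(res.statistic), float(res.pvalue))


def read_pupil_samples(path) -> PupilTrace:
    """Read tab-separated pupil samples (time, value, blink flag)."""
    df = pd.read_csv(path, sep="\t")
    fs = 1.0 / float(np.median(np.diff(df["time"])))
    blink = df["blink"].to_numpy().astype(bool) if "blink" in df else \
        np.zeros(len(df), dtype=bool)
    intervals = []
    t = df["time"].to_numpy()
    in_blink = False
    for i, b in enumerate(blink):
        if b and not in_blink:
            start, in_blink = t[i], True
        elif not b and in_blink:
            intervals.append((start, t[i - 1]))
            in_blink = False
    if in_blink:
        intervals.append((start, t[-1]))
    return PupilTrace(df["value"].to_numpy(), fs, intervals)


def write_pupil_samples(trace: PupilTrace, path) -> None:
    t = trace.times
    blink = np.zeros(len(t), dtype=int)
    for s, e in trace.blinks:
        blink[(t >= s) & (t <= e)] = 1
    pd.DataFrame({"time": t, "value": trace.values, "blink": blink}).to_csv(
        path, sep="\t", index=False)
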