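"""Physiological nuisance regressors (RETROICOR-style Fourier expansion).

Cardiac and respiratory recordings are converted to instantaneous phases
and expanded into sine/cosine harmonics evaluated at one reference
instant per volume, following the RETROICOR convention.  With cardiac
order 4, respiratory order 3 and interaction order 1 the basis has
2*4 + 2*3 + 4*1 = 18 columns.

Cardiac phase is 0 at each detected pulse peak and grows linearly to 2*pi
at the next peak.  Respiratory phase uses amplitude-histogram
equalisation signed by the trace slope, so inhalation maps to (0, pi)
and exhalation to (pi, 2*pi), with phase 0 at end-expiration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks


class UnusableTraceError(ValueError):
    """A physiological trace has no usable periodic structure."""


class CoverageError(ValueError):
    """A physiological trace does not cover the scanning period."""


@dataclass(frozen=True)
class PhysioBasisSpec:
    """Harmonic orders of the nuisance basis (defaults: 4 cardiac, 3
    respiratory, 1 cardio-respiratory interaction -> 18 columns)."""

    cardiac_order: int = 4
    respiratory_order: int = 3
    interaction_order: int = 1

    def __post_init__(self) -> None:
        if min(self.cardiac_order, self.respiratory_order, self.interaction_order) < 0:
            raise ValueError("orders must be >= 0")

    @property
    def n_columns(self) -> int:
        return 2 * self.cardiac_order + 2 * self.respiratory_order + 4 * self.interaction_order


def detect_peaks(trace: np.ndarray, sampling_rate: float, expected_rate: float) -> np.ndarray:
    """Peak times (s) via local maxima with a 0.5/expected_rate refractory distance."""
    trace = np.asarray(trace, dtype=float)
    if trace.size < 2 or np.ptp(trace) == 0:
        raise UnusableTraceError("trace is constant or too short for peak detection")
    distance = max(1, int(round(0.5 / expected_rate * sampling_rate)))
    idx, _ = find_peaks(trace, distance=distance)
    if idx.size < 2:
        raise UnusableTraceError("fewer than 2 peaks detected")
    return idx / sampling_rate


def cardiac_phase(
    trace: np.ndarray,
    sampling_rate: float,
    query_times: np.ndarray,
    expected_rate: float = 1.0,
) -> np.ndarray:
    """Cardiac phase in [0, 2*pi): 0 at each peak, linear in time between peaks.

    Queries outside the detected peak range are extrapolated with the
    nearest inter-peak interval.
    """
    peaks = detect_peaks(trace, sampling_rate, expected_rate)
    query_times = np.atleast_1d(np.asarray(query_times, dtype=float))
    # cumulative phase 2*pi*k at peak k, linear between; linear extrapolation at edges
    cum = 2 * np.pi * np.arange(peaks.size)
    phase = np.interp(query_times, peaks, cum)
    first_slope = 2 * np.pi / (peaks[1] - peaks[0])
    last_slope = 2 * np.pi / (peaks[-1] - peaks[-2])
    before = query_times < peaks[0]
    after = query_times > peaks[-1]
    phase[before] = cum[0] + (query_times[before] - peaks[0]) * first_slope
    phase[after] = cum[-1] + (query_times[after] - peaks[-1]) * last_slope
    return np.mod(phase, 2 * np.pi)


def respiratory_phase(
    trace: np.ndarray,
    sampling_rate: float,
    query_times: np.ndarray,
) -> np.ndarray:
    """Respiratory phase in [0, 2*pi) via histogram-equalised amplitude.

    phi = pi * H(b) * sign(db/dt) mapped into [0, 2*pi), with H the
    empirical amplitude CDF.  For a sinusoidal trace this is linear in
    time with phase 0 at the trough.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size < 2 or np.ptp(trace) == 0:
        raise UnusableTraceError("respiratory trace is constant")
    query_times = np.atleast_1d(np.asarray(query_times, dtype=float))
    t = np.arange(trace.size) / sampling_rate
    values = np.interp(query_times, t, trace)
    slope_full = np.gradient(trace, 1.0 / sampling_rate)
    slopes = np.interp(query_times, t, slope_full)
    order = np.sort(trace)
    # empirical CDF in (0, 1]
    h = np.searchsorted(order, values, side="right") / trace.size
    signs = np.where(slopes >= 0, 1.0, -1.0)
    phase = np.pi * h * signs
    return np.mod(phase, 2 * np.pi)


def physio_regressors(
    cardiac_trace: np.ndarray,
    resp_trace: np.ndarray,
    spec: PhysioBasisSpec | None = None,
    n_scans: int = 0,
    tr: float = 1.25,
    *,
    cardiac_sampling_rate: float = 50.0,
    resp_sampling_rate: float = 50.0,
    cardiac_expected_rate: float = 1.0,
    reference_offset: float | None = None,
) -> pd.DataFrame:
    """Slice-reference-timed physiological regressor matrix (n_scans x columns).

    Columns: sin/cos of k*phase for k = 1..order per modality, then for
    each interaction order sin/cos of the sum and difference of cardiac
    and respiratory phase (4 columns per order).  ``reference_offset``
    is the slice-timing reference instant within each TR (default TR/2,
    the middle slice).
    """
    if spec is None:
        spec = PhysioBasisSpec()
    if n_scans <= 0:
        raise ValueError("n_scans must be positive")
    if reference_offset is None:
        reference_offset = tr / 2.0
    query = np.arange(n_scans) * tr + reference_offset
    span_needed = query[-1]
    if spec.cardiac_order or spec.interaction_order:
        if (len(cardiac_trace) - 1) / cardiac_sampling_rate < span_needed:
            raise CoverageError("cardiac trace shorter than the scan span")
    if spec.respiratory_order or spec.interaction_order:
        if (len(resp_trace) - 1) / resp_sampling_rate < span_needed:
            raise CoverageError("respiratory trace shorter than the scan span")

    cols: dict[str, np.ndarray] = {}
    phi_c = phi_r = None
    if spec.cardiac_order or spec.interaction_order:
        phi_c = cardiac_phase(cardiac_trace, cardiac_sampling_rate, query,
                              expected_rate=cardiac_expected_rate)
    if spec.respiratory_order or spec.interaction_order:
        phi_r = respiratory_phase(resp_trace, resp_sampling_rate, query)
    for k in range(1, spec.cardiac_order + 1):
        cols[f"cardiac_sin{k}"] = np.sin(k * phi_c)
        cols[f"cardiac_cos{k}"] = np.cos(k * phi_c)
    for k in range(1, spec.respiratory_order + 1):
        cols[f"resp_sin{k}"] = np.sin(k * phi_r)
        cols[f"resp_cos{k}"] = np.cos(k * phi_r)
    for k in range(1, spec.interaction_order + 1):
        cols[f"interaction_sum_sin{k}"] = np.sin(k * (phi_c + phi_r))
        cols[f"interaction_sum_cos{k}"] = np.cos(k * (phi_c + phi_r))
        cols[f"interaction_diff_sin{k}"] = np.sin(k * (phi_c - phi_r))
        cols[f"interaction_diff_cos{k}"] = np.cos(k * (phi_c - phi_r))
    out = pd.DataFrame(cols, index=pd.RangeIndex(n_scans, name="scan"))
    if out.shape[1] != spec.n_columns:  # pragma: no cover - internal consistency
        warnings.warn("unexpected physiological column count")
    return out


def read_physio_log(path) -> tuple[np.ndarray, float]:
    """Read a two-column (time, value) text log; returns (values, sampling_rate)."""
    arr = np.loadtxt(path)
    times, values = arr[:, 0], arr[:, 1]
    dt = np.median(np.diff(times))
    return values, 1.0 / dt


def write_physio_log(values: np.ndarray, sampling_rate: float, path) -> None:
    t = np.arange(len(values)) / sampling_rate
    np.savetxt(path, np.column_stack([t, values]), fmt="%.6f")
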