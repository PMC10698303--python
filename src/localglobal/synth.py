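"""Ground-truth-known synthetic datasets for the local-global analyses.

The generator emits everything the pipeline consumes — ROI BOLD series,
small 4D volumes with masks, cardiac/respiratory traces, motion-like
confounds, and pupil traces — with known condition amplitudes so that
every estimator can be validated against the injected truth.

Forward model for an ROI signal: condition amplitudes x canonical-HRF
(or plateau) regressors for the four pattern-type cells, plus AR(1)
noise, slow cosine drift, a linear mix of the physiological Fourier
basis, and motion-coupled variance.  With all noise scales at zero the
series equals its design-by-amplitude prediction exactly.

Pupil traces superpose a condition-scaled dilation kernel on slow drift
and white noise, with blinks as a Poisson process with lognormal
durations recorded as annotations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt

from . import physio as physio_mod
from .firglm import build_design, canonical_hrf
from .paradigm import PATTERN_DEVIANT, PATTERN_STANDARD
from .pupil import PupilTrace, merge_intervals
from .roi import RoiMask, RoiTimeSeries


class EventsOutOfRangeError(ValueError):
    """Events extend past the scanned duration."""


@dataclass(frozen=True)
class GroundTruth:
    """Injected effect sizes and noise structure of a synthetic dataset.

    BOLD amplitudes are in raw signal units per condition cell of the
    local x global design; ``subject_sd`` is the between-subject SD of
    the rare-frequent (global) amplitude difference.  Defaults target a
    subject-level standardized global effect near d = 0.6 in an LC-like
    ROI under the default noise.
    """

    base_amplitude: float = 0.5
    global_effect: float = 0.60
    local_effect: float = 0.0
    interaction_effect: float = 0.0
    subject_sd: float = 0.30
    response_shape: str = "canonical"     # "canonical" | "plateau"
    plateau_duration: float = 4.0
    ar_coef: float = 0.4
    innovation_sd: float = 1.0
    drift_amplitude: float = 0.5
    n_drift_components: int = 3
    physio_gain: float = 0.15
    motion_gain: float = 0.1
    cardiac_rate: float = 1.0
    respiratory_rate: float = 0.25
    physio_jitter: float = 0.05
    pupil_frequent_amplitude: float = 0.2
    pupil_rare_amplitude: float = 0.7
    pupil_noise_sd: float = 0.3
    pupil_drift_amplitude: float = 0.5
    blink_rate: float = 0.2
    blink_duration_mean: float = 0.2
    blink_duration_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1 < self.ar_coef < 1:
            raise ValueError("AR(1) coefficient must lie in (-1, 1)")
        for name in ("innovation_sd", "drift_amplitude", "physio_gain", "motion_gain",
                     "pupil_noise_sd", "blink_rate", "subject_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.response_shape not in ("canonical", "plateau"):
            raise ValueError("response_shape must be 'canonical' or 'plateau'")

    def amplitudes(self) -> dict[tuple[str, str], float]:
        """The four cell amplitudes implied by the factorial effects."""
        g, l, x = self.global_effect / 2, self.local_effect / 2, self.interaction_effect / 4
        a = self.base_amplitude
        return {
            (PATTERN_STANDARD, "frequent"): a - g - l + x,
            (PATTERN_DEVIANT, "rare"): a + g + l + x,
            (PATTERN_DEVIANT, "frequent"): a - g + l - x,
            (PATTERN_STANDARD, "rare"): a + g - l - x,
        }


@dataclass
class VolumeSeries:
    """A 4D intensity array with affine, TR, and session boundaries."""

    data: np.ndarray
    affine: np.ndarray
    tr: float = 1.25
    session_boundaries: tuple[int, ...] = (0,)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("volume series must be 4D")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be invertible")
        b = tuple(self.session_boundaries)
        if not b or b[0] != 0 or list(b) != sorted(b) or b[-1] >= self.data.shape[3]:
            raise ValueError("session boundaries must be sorted scan indices starting at 0")
        self.session_boundaries = b

    def to_nifti(self):
        import nibabel as nib
        return nib.Nifti1Image(self.data.astype(np.float32), self.affine)


def simulate_physio_traces(
    duration: float,
    cardiac_rate: float = 1.0,
    resp_rate: float = 0.25,
    jitter: float = 0.05,
    sampling_rate: float = 50.0,
    rng: np.random.Generator | int | None = 0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Quasi-periodic cardiac and respiratory traces with cycle jitter.

    Cycle lengths are drawn as (1/rate) * (1 + jitter * N(0, 1)); each
    trace is a cosine of the piecewise-linear phase, so peak times are
    recoverable by local-maximum detection.  Returns (cardiac, resp,
    sampling_rate).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if cardiac_rate <= 0 or resp_rate <= 0:
        raise ValueError("rates must be positive")
    if sampling_rate <= 4 * cardiac_rate:
        raise ValueError("sampling_rate must exceed 4x the cardiac rate")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    t = np.arange(int(np.ceil(duration * sampling_rate)) + 1) / sampling_rate

    def one(rate: float) -> np.ndarray:
        mean_cycle = 1.0 / rate
        n_cycles = int(np.ceil(duration * rate * 1.5)) + 4
        cycles = mean_cycle * (1.0 + jitter * rng.standard_normal(n_cycles))
        cycles = np.clip(cycles, 0.2 * mean_cycle, None)
        peaks = np.concatenate([[0.0], np.cumsum(cycles)])
        phase = np.interp(t, peaks, 2 * np.pi * np.arange(peaks.size))
        return np.cos(phase)

    return one(cardiac_rate), one(resp_rate), sampling_rate


def _response_kernel(truth: GroundTruth, dt: float) -> np.ndarray | None:
    if truth.response_shape == "canonical":
        return None  # build_design's own canonical kernel
    grid = np.arange(1, int(round(32.0 / dt)) + 1) * dt
    box = np.ones(max(1, int(round(truth.plateau_duration / dt))))
    k = np.convolve(canonical_hrf(grid), box)[: grid.size]
    return k / np.abs(k).max()


def _stimulus_signal(
    events: pd.DataFrame,
    truth: GroundTruth,
    n_scans: int,
    tr: float,
    session_boundaries: tuple[int, ...],
    upsample_factor: int = 10,
) -> np.ndarray:
    design = build_design(events, "HRF", n_scans, tr,
                          upsample_factor=upsample_factor,
                          session_boundaries=session_boundaries)
    amps = truth.amplitudes()
    from .deviance import CELLS
    amp_vec = np.array([amps[c] for c in CELLS])
    stim = design.matrix[:, : len(CELLS)] @ amp_vec
    if truth.response_shape == "plateau":
        # rebuild with plateau kernel: replace the per-cell convolution
        dt = tr / upsample_factor
        kernel = _response_kernel(truth, dt)
        stim = _convolved_cells(events, kernel, n_scans, tr, session_boundaries,
                                upsample_factor) @ amp_vec
    return stim


def _convolved_cells(events, kernel, n_scans, tr, session_boundaries, upsample_factor):
    from .deviance import CELLS
    dt = tr / upsample_factor
    edges = list(session_boundaries) + [n_scans]
    out = np.zeros((n_scans, len(CELLS)))
    ev = events.copy()
    ev.loc[ev["global_role"] == "habituation", "global_role"] = "frequent"
    for s, (start, stop) in enumerate(zip(edges[:-1], edges[1:])):
        n_sess = stop - start
        n_fine = n_sess * upsample_factor
        sess = ev[ev["session_index"] == s] if "session_index" in ev else ev
        rows = np.arange(n_sess) * upsample_factor
        for ci, (p, r) in enumerate(CELLS):
            sel = (sess["pattern"] == p) & (sess["global_role"] == r)
            sticks = np.zeros(n_fine)
            idx = np.round(sess.loc[sel, "onset"].to_numpy() / dt).astype(int)
            idx = idx[(idx >= 0) & (idx < n_fine)]
            np.add.at(sticks, idx, 1.0)
            out[start:stop, ci] = np.convolve(sticks, kernel)[:n_fine][rows]
    return out


def _ar1(n: int, coef: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    innov = rng.standard_normal(n) * sd
    out = np.empty(n)
    prev = innov[0] / np.sqrt(1 - coef**2) if abs(coef) < 1 else innov[0]
    for i in range(n):
        prev = coef * prev + innov[i]
        out[i] = prev
    return out


def simulate_roi_dataset(
    events: pd.DataFrame,
    truth: GroundTruth,
    n_scans: int,
    tr: float = 1.25,
    session_boundaries: tuple[int, ...] = (0,),
    roi_scales: dict[str, float] | None = None,
    rng: np.random.Generator | int | None = None,
    include_physio: bool = True,
) -> tuple[dict[str, RoiTimeSeries], pd.DataFrame, dict]:
    """Simulate raw ROI series plus a confound table for one subject.

    Each ROI carries the stimulus signal scaled by its entry in
    ``roi_scales`` plus AR(1) noise, drift, physiological contamination
    (a random linear mix of the RETROICOR basis) and motion-coupled
    variance.  Returns (series per ROI, confound table, info with the
    injected amplitudes and noiseless prediction).
    """
    rng = rng if isinstance(rng, np.random.Generator) else \
        np.random.default_rng(truth.seed if rng is None else rng)
    if roi_scales is None:
        roi_scales = {"lc": 1.0}
    edges = list(session_boundaries) + [n_scans]
    for s, (start, stop) in enumerate(zip(edges[:-1], edges[1:])):
        sess = events[events["session_index"] == s] if "session_index" in events else events
        if len(sess) and (sess["onset"] + sess["duration"]).max() > (stop - start) * tr:
            raise EventsOutOfRangeError(f"events exceed the scan span of session {s}")

    stim = _stimulus_signal(events, truth, n_scans, tr, session_boundaries)
    duration = n_scans * tr
    scan_t = np.arange(n_scans) * tr

    conf_cols: dict[str, np.ndarray] = {}
    # motion-like confounds: scaled random walks
    motion = np.cumsum(rng.standard_normal((n_scans, 6)) * 0.02, axis=0)
    for j, name in enumerate(["trans_x", "trans_y", "trans_z",
                              "rot_x", "rot_y", "rot_z"]):
        conf_cols[name] = motion[:, j]
    conf_cols["ventricle"] = _ar1(n_scans, 0.3, 1.0, rng)

    physio_basis = None
    if include_physio:
        cardiac, resp, fs = simulate_physio_traces(
            duration + 2 * tr, truth.cardiac_rate, truth.respiratory_rate,
            truth.physio_jitter, rng=rng)
        physio_basis = physio_mod.physio_regressors(
            cardiac, resp, physio_mod.PhysioBasisSpec(), n_scans, tr,
            cardiac_sampling_rate=fs, resp_sampling_rate=fs,
            cardiac_expected_rate=truth.cardiac_rate)
        for c in physio_basis.columns:
            conf_cols[c] = physio_basis[c].to_numpy()
    confounds = pd.DataFrame(conf_cols)

    series: dict[str, RoiTimeSeries] = {}
    for name, scale in roi_scales.items():
        noise = np.zeros(n_scans)
        for start, stop in zip(edges[:-1], edges[1:]):
            n_sess = stop - start
            if truth.innovation_sd > 0:
                noise[start:stop] += _ar1(n_sess, truth.ar_coef, truth.innovation_sd, rng)
            if truth.drift_amplitude > 0:
                t_sess = scan_t[:n_sess]
                for k in range(1, truth.n_drift_components + 1):
                    ph = rng.uniform(0, 2 * np.pi)
                    noise[start:stop] += (truth.drift_amplitude / k) * np.cos(
                        np.pi * k * t_sess / (n_sess * tr) + ph)
        if include_physio and truth.physio_gain > 0:
            gains = rng.standard_normal(physio_basis.shape[1]) * truth.physio_gain
            noise += physio_basis.to_numpy() @ gains
        if truth.motion_gain > 0:
            noise += motion @ (rng.standard_normal(6) * truth.motion_gain)
        series[name] = RoiTimeSeries(scale * stim + noise, tr,
                                     session_boundaries, name=name, flags=("simulated",))
    info = {"amplitudes": truth.amplitudes(), "stimulus_signal": stim,
            "truth": truth}
    return series, confounds, info


def simulate_volume_dataset(
    roi_signals: dict[str, np.ndarray],
    grid_shape: tuple[int, int, int],
    masks: dict[str, RoiMask],
    noise_scale: float = 1.0,
    kernel_width_mm: float = 2.0,
    tr: float = 1.25,
    session_boundaries: tuple[int, ...] = (0,),
    rng: np.random.Generator | int | None = 0,
) -> VolumeSeries:
    """Embed ROI signals in a 4D volume with spatially decaying leakage.

    Voxels inside mask m carry signal m at full amplitude; outside, the
    amplitude decays as a Gaussian of the millimetre distance to the
    mask (width ``kernel_width_mm``), so that mask-shift analyses see an
    attenuating effect.  Gaussian voxel noise of ``noise_scale`` SD is
    added everywhere.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    union = np.zeros(grid_shape, dtype=int)
    affine = None
    for name, mask in masks.items():
        if mask.data.shape != tuple(grid_shape):
            raise ValueError(f"mask {name!r} does not match the grid")
        union += mask.data.astype(int)
        affine = mask.affine
    if union.max() > 1:
        raise ValueError("masks overlap")
    n_scans = len(next(iter(roi_signals.values())))
    data = rng.standard_normal((*grid_shape, n_scans)) * noise_scale
    voxdims = np.abs(np.diag(affine)[:3])
    for name, mask in masks.items():
        sig = np.asarray(roi_signals[name], dtype=float)
        dist_mm = distance_transform_edt(~mask.data, sampling=voxdims)
        weight = np.exp(-dist_mm**2 / (2 * kernel_width_mm**2))
        weight[mask.data] = 1.0
        data += weight[..., None] * sig[None, None, None, :]
    return VolumeSeries(data, affine, tr=tr, session_boundaries=session_boundaries)


def pupil_response_kernel(dt: float, support: float = 3.0,
                          shape: float = 3.0, scale: float = 0.45) -> np.ndarray:
    """Unit-peak gamma-shaped pupil dilation kernel (mode near 0.9 s)."""
    t = np.arange(1, int(round(support / dt)) + 1) * dt
    k = t ** (shape - 1) * np.exp(-t / scale)
    return k / k.max()


def simulate_pupil_dataset(
    events: pd.DataFrame,
    truth: GroundTruth,
    sampling_rate: float = 60.0,
    session: int = 0,
    duration: float | None = None,
    rng: np.random.Generator | int | None = None,
    kernel_support: float = 3.0,
) -> tuple[PupilTrace, dict]:
    """Simulate a raw pupil trace with deviance-scaled dilations and blinks.

    Rare patterns dilate with ``pupil_rare_amplitude`` and frequent (and
    habituation) patterns with ``pupil_frequent_amplitude``; blinks
    follow a Poisson process with lognormal durations and are recorded
    as annotations (the sample value drops to 0 within a blink, as in a
    raw eye-tracker record).
    """
    if sampling_rate < 50:
        raise ValueError("sampling_rate must be >= 50 Hz")
    rng = rng if isinstance(rng, np.random.Generator) else \
        np.random.default_rng(truth.seed if rng is None else rng)
    ev = events[events["session_index"] == session] if "session_index" in events else events
    if duration is None:
        duration = float((ev["onset"] + ev["duration"]).max()) + kernel_support + 2.0
    dt = 1.0 / sampling_rate
    n = int(round(duration * sampling_rate)) + 1
    y = np.zeros(n)
    kernel = pupil_response_kernel(dt, support=kernel_support)
    sticks = np.zeros(n)
    amp_map = {"rare": truth.pupil_rare_amplitude,
               "frequent": truth.pupil_frequent_amplitude,
               "habituation": truth.pupil_frequent_amplitude}
    for _, row in ev.iterrows():
        i = int(round(row["onset"] / dt))
        if 0 <= i < n:
            sticks[i] += amp_map[row["global_role"]]
    y += np.convolve(sticks, kernel)[:n]
    if truth.pupil_drift_amplitude > 0:
        t = np.arange(n) * dt
        for k in range(1, 3):
            y += (truth.pupil_drift_amplitude / k) * np.cos(
                2 * np.pi * k * t / (4 * duration) + rng.uniform(0, 2 * np.pi))
    if truth.pupil_noise_sd > 0:
        y += rng.standard_normal(n) * truth.pupil_noise_sd

    blinks: list[tuple[float, float]] = []
    if truth.blink_rate > 0:
        t_blink = 0.0
        while True:
            t_blink += rng.exponential(1.0 / truth.blink_rate)
            if t_blink >= duration:
                break
            d = rng.lognormal(np.log(truth.blink_duration_mean),
                              truth.blink_duration_sigma)
            blinks.append((t_blink, min(t_blink + d, duration)))
        blinks = merge_intervals(blinks, clip=(0.0, duration))
        tgrid = np.arange(n) * dt
        for s, e in blinks:
            y[(tgrid >= s) & (tgrid <= e)] = 0.0
    info = {"rare_amplitude": truth.pupil_rare_amplitude,
            "frequent_amplitude": truth.pupil_frequent_amplitude,
            "kernel": kernel}
    return PupilTrace(y, sampling_rate, blinks, session=session), info


def subject_truths(truth: GroundTruth, n_subjects: int,
                   rng: np.random.Generator) -> list[GroundTruth]:
    """Per-subject ground truths with the global effect drawn
    N(global_effect, subject_sd^2)."""
    out = []
    for _ in range(n_subjects):
        g = truth.global_effect + truth.subject_sd * rng.standard_normal()
        out.append(replace(truth, global_effect=float(g)))
    return out


def simulate_study(
    n_subjects: int = 24,
    truth: GroundTruth | None = None,
    n_sessions: int = 1,
    seed: int = 0,
    tr: float = 1.25,
    roi_scales: dict[str, float] | None = None,
    include_physio: bool = True,
    events: pd.DataFrame | None = None,
    extra_scans: int = 12,
) -> list[dict]:
    """Simulate a multi-subject study sharing one event schedule.

    Returns one dict per subject with keys ``events``, ``series`` (per
    ROI raw :class:`RoiTimeSeries`), ``confounds``, and ``truth`` (the
    subject's drawn amplitudes).  Scan count is derived from the event
    schedule plus ``extra_scans`` volumes of padding per session.
    """
    from .paradigm import BlockSpec, generate_experiment

    if truth is None:
        truth = GroundTruth(seed=seed)
    rng = np.random.default_rng(seed)
    if events is None:
        events = generate_experiment(n_sessions=n_sessions, base_spec=BlockSpec(),
                                     seed=seed)
    per_session = []
    for s in range(events["session_index"].max() + 1):
        sess = events[events["session_index"] == s]
        dur = float((sess["onset"] + sess["duration"]).max())
        per_session.append(int(np.ceil(dur / tr)) + extra_scans)
    boundaries = tuple(np.concatenate([[0], np.cumsum(per_session)[:-1]]).astype(int))
    n_scans = int(np.sum(per_session))

    subjects = []
    for st in subject_truths(truth, n_subjects, rng):
        series, confounds, info = simulate_roi_dataset(
            events, st, n_scans, tr, boundaries, roi_scales=roi_scales,
            rng=np.random.default_rng(rng.integers(2**31)),
            include_physio=include_physio)
        subjects.append({"events": events, "series": series,
                         "confounds": confounds, "truth": st, "info": info})
    return subjects


def write_ground_truth(truth: GroundTruth, path) -> None:
    """JSON sidecar with the injected parameters."""
    payload = {k: v for k, v in truth.__dict__.items()}
    payload["cell_amplitudes"] = {f"{p}_{r}": a for (p, r), a in truth.amplitudes().items()}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
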