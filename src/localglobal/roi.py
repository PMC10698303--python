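"""ROI masks, time-series extraction, and the shared fMRI preprocessing.

Masks are binary 3D arrays on the EPI grid (probabilistic atlas maps are
binarised at a probability threshold, 0.05 by default).  The anatomical
specificity analysis translates a mask by whole voxels along one grid
axis (the anteroposterior axis for an elongated brainstem nucleus such
as the locus coeruleus).

Preprocessing before every ROI analysis, applied per session:
discrete-cosine high-pass (cutoff period 128 s), least-squares removal
of confounds (motion, 4th-ventricle signal, physiological regressors),
then z-scoring of the residual.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import nibabel as nib
import numpy as np


class EmptyMaskError(ValueError):
    """Binarisation produced a mask with no voxels."""


class GeometryError(ValueError):
    """Mask and volume grids do not match."""


class OutOfBoundsError(ValueError):
    """A shifted mask would leave the volume grid."""


class DegenerateSignalError(ValueError):
    """A residual signal has (near-)zero variance."""


@dataclass
class RoiMask:
    """Binary region-of-interest mask on a voxel grid."""

    data: np.ndarray
    affine: np.ndarray
    name: str = "roi"
    provenance: str = "native-delineation"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3D")
        if not self.data.any():
            raise EmptyMaskError(f"mask {self.name!r} has no voxels")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def voxel_size(self, axis: int) -> float:
        return float(np.linalg.norm(self.affine[:3, axis]))

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.data.astype(np.uint8), self.affine)

    @classmethod
    def from_nifti(cls, img, name: str = "roi", threshold: float = 0.5) -> "RoiMask":
        if isinstance(img, (str, bytes)) or hasattr(img, "__fspath__"):
            img = nib.load(img)
        return cls(np.asanyarray(img.dataobj) >= threshold, img.affine, name=name)


@dataclass
class RoiTimeSeries:
    """One ROI's scan-by-scan signal.

    ``session_boundaries`` holds the starting scan index of each session
    (first element 0).  ``flags`` records the preprocessing provenance.
    """

    values: np.ndarray
    tr: float = 1.25
    session_boundaries: tuple[int, ...] = (0,)
    name: str = "roi"
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        b = tuple(self.session_boundaries)
        if not b or b[0] != 0 or list(b) != sorted(b) or b[-1] >= len(self.values):
            raise ValueError("session boundaries must be sorted scan indices starting at 0")
        self.session_boundaries = b

    @property
    def n_scans(self) -> int:
        return len(self.values)

    def session_slices(self) -> list[slice]:
        edges = list(self.session_boundaries) + [self.n_scans]
        return [slice(a, b) for a, b in zip(edges[:-1], edges[1:])]


def binarize_mask(
    probabilistic_map: np.ndarray,
    threshold: float = 0.05,
    affine: np.ndarray | None = None,
    name: str = "roi",
) -> RoiMask:
    """Binarise a probabilistic mask: voxel included iff p >= threshold (and p > 0)."""
    p = np.asarray(probabilistic_map, dtype=float)
    if p.min() < 0 or p.max() > 1:
        raise ValueError("probabilistic map values must lie in [0, 1]")
    data = (p >= threshold) & (p > 0)
    if affine is None:
        affine = np.eye(4)
    if not data.any():
        raise EmptyMaskError(f"threshold {threshold} leaves no voxels in {name!r}")
    return RoiMask(data, affine, name=name, provenance=f"binarized(threshold={threshold})")


def shift_mask(mask: RoiMask, axis: int, voxels: int) -> RoiMask:
    """Translate a mask by an integer number of voxels along a grid axis.

    Voxel count is preserved; any voxel that would leave the grid raises
    :class:`OutOfBoundsError`.  Provenance records the offset in voxels
    and millimetres (voxels x voxel size along the axis).
    """
    if voxels == 0:
        return replace(mask, provenance=f"shifted(+0 vox, +0.0 mm, axis={axis})")
    idx = np.argwhere(mask.data)
    idx[:, axis] += voxels
    if idx[:, axis].min() < 0 or idx[:, axis].max() >= mask.data.shape[axis]:
        raise OutOfBoundsError(
            f"shifting {mask.name!r} by {voxels} voxels along axis {axis} leaves the grid")
    data = np.zeros_like(mask.data)
    data[tuple(idx.T)] = True
    mm = voxels * mask.voxel_size(axis)
    return RoiMask(
        data,
        mask.affine,
        name=mask.name,
        provenance=f"shifted({voxels:+d} vox, {mm:+.1f} mm, axis={axis})",
    )


def extract_mean_timeseries(volumes, mask: RoiMask, name: str | None = None) -> RoiTimeSeries:
    """Unweighted mean over mask voxels at each scan of a 4D volume series."""
    data = volumes.data
    if data.shape[:3] != mask.data.shape or not np.allclose(volumes.affine, mask.affine):
        raise GeometryError("volume and mask grids do not match")
    values = data[mask.data].mean(axis=0)
    return RoiTimeSeries(
        values,
        tr=volumes.tr,
        session_boundaries=tuple(volumes.session_boundaries),
        name=name or mask.name,
        flags=("extracted",),
    )


def dct_highpass_basis(n: int, tr: float, cutoff_hz: float = 1.0 / 128) -> np.ndarray:
    """Discrete-cosine drift basis with K = floor(2*n*tr*cutoff) regressors
    (SPM convention, constant term excluded)."""
    k_max = int(np.floor(2 * n * tr * cutoff_hz))
    t = np.arange(n)
    basis = np.empty((n, k_max))
    for k in range(1, k_max + 1):
        basis[:, k - 1] = np.sqrt(2.0 / n) * np.cos(np.pi * k * (2 * t + 1) / (2 * n))
    return basis


def _residualize(y: np.ndarray, regressors: np.ndarray) -> np.ndarray:
    """Residual of y after least-squares fit of [regressors, intercept]."""
    X = np.column_stack([regressors, np.ones(len(y))]) if regressors.size else \
        np.ones((len(y), 1))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn("rank-deficient nuisance matrix; using pseudo-inverse", stacklevel=3)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def preprocess_timeseries(
    series: RoiTimeSeries,
    confounds: np.ndarray | None = None,
    highpass_cutoff: float = 1.0 / 128,
) -> RoiTimeSeries:
    """High-pass, confound-regress, and z-score an ROI series per session.

    Order within each session: DCT high-pass (cutoff period 128 s by
    default) -> least-squares removal of confound columns (with
    intercept) -> z-score.  Confound rows must match the scan count.
    """
    if confounds is not None:
        confounds = np.asarray(confounds, dtype=float)
        if confounds.ndim == 1:
            confounds = confounds[:, None]
        if confounds.shape[0] != series.n_scans:
            raise ValueError("confound rows must equal the scan count")
    out = np.empty_like(series.values)
    for sl in series.session_slices():
        y = series.values[sl].astype(float)
        n = len(y)
        if highpass_cutoff is not None and highpass_cutoff > 0:
            y = _residualize(y, dct_highpass_basis(n, series.tr, highpass_cutoff))
        if confounds is not None:
            y = _residualize(y, confounds[sl])
        else:
            y = y - y.mean()
        sd = y.std()
        if sd < 1e-10:
            raise DegenerateSignalError(
                f"residual variance of {series.name!r} is (near) zero in a session")
        out[sl] = y / sd
    return replace(
        series,
        values=out,
        flags=tuple(series.flags) + ("high-passed", "confound-regressed", "z-scored"),
    )


def compute_tsnr(raw_series: np.ndarray, detrend_order: int = 3) -> float:
    """Temporal SNR: mean of the raw series over the SD of its
    polynomial-detrended residual (order 3 by default)."""
    y = np.asarray(raw_series, dtype=float)
    if y.size <= detrend_order + 2:
        raise ValueError("series too short for the requested detrend order")
    x = np.linspace(-1, 1, y.size)
    coefs = np.polynomial.polynomial.polyfit(x, y, detrend_order)
    resid = y - np.polynomial.polynomial.polyval(x, coefs)
    sd = resid.std()
    if sd < 1e-12:
        warnings.warn("zero residual variance; TSNR is infinite")
        return float("inf")
    return float(y.mean() / sd)
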