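"""Temporal and spatial preprocessing of BOLD volumes.

Implements the steps applied between scanner-space alignment (assumed done)
and feature extraction: per-voxel linear detrending, ideal (DFT-masking)
bandpass filtering, Gaussian spatial smoothing, and nuisance regression
against confound time series.  All operations preserve the array shape and,
when a mask is given, leave out-of-mask voxels untouched.

The bandpass is an ideal filter implemented by zeroing DFT bins outside the
band.  This matches the spectral bookkeeping of the ALFF computation bin
for bin and makes passband/stopband gains exactly 1 and 0 on-bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .core import BrainMask, FeatureMap3D, Fmri4DVolume

logger = logging.getLogger(__name__)

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

DEFAULT_ORDER = ("detrend", "nuisance", "smooth", "bandpass")


@dataclass
class PreprocessConfig:
    band_hz: tuple[float, float] = (0.01, 0.12)
    fwhm_mm: float = 6.0
    confound_regressors: np.ndarray | None = None  # (timepoints, k) or None
    order: tuple[str, ...] = DEFAULT_ORDER

    def __post_init__(self) -> None:
        lo, hi = self.band_hz
        if not 0 <= lo < hi:
            raise ValueError(f"invalid band {self.band_hz}")
        if self.fwhm_mm < 0:
            raise ValueError("fwhm_mm must be nonnegative")
        unknown = set(self.order) - {"detrend", "nuisance", "smooth", "bandpass"}
        if unknown:
            raise ValueError(f"unknown preprocessing steps: {sorted(unknown)}")

    def validate_band(self, tr_seconds: float) -> None:
        nyq = 0.5 / tr_seconds
        if self.band_hz[1] > nyq + 1e-12:
            raise ValueError(f"band high edge {self.band_hz[1]} Hz exceeds "
                             f"Nyquist {nyq} Hz for TR {tr_seconds} s")


def _masked_apply(vol: Fmri4DVolume, mask: BrainMask | None, fn) -> Fmri4DVolume:
    """Apply fn to the (n_voxels, t) matrix of in-mask series; rest untouched."""
    if mask is None:
        flat = vol.data.reshape(-1, vol.n_timepoints)
        return vol.copy_with(fn(flat).reshape(vol.data.shape))
    mask.check_grid(vol.grid_shape)
    out = vol.data.copy()
    out[mask.data] = fn(vol.data[mask.data])
    return vol.copy_with(out)


def linear_detrend(vol: Fmri4DVolume, mask: BrainMask | None = None) -> Fmri4DVolume:
    """Remove each voxel's least-squares line (intercept + slope) over time."""
    if vol.n_timepoints < 3:
        raise ValueError("linear detrending needs at least 3 timepoints")
    return _masked_apply(vol, mask, lambda m: signal.detrend(m, axis=-1, type="linear"))


def bandpass(vol: Fmri4DVolume, band_hz: tuple[float, float],
             tr_seconds: float | None = None,
             mask: BrainMask | None = None) -> Fmri4DVolume:
    """Ideal bandpass: keep DFT bins with low <= f <= high (closed interval)."""
    tr = vol.tr_seconds if tr_seconds is None else tr_seconds
    lo, hi = band_hz
    nyq = 0.5 / tr
    if not 0 < lo < hi <= nyq + 1e-12:
        raise ValueError(f"band {band_hz} outside (0, Nyquist={nyq}] for TR {tr} s")
    n = vol.n_timepoints
    freqs = np.fft.rfftfreq(n, d=tr)
    keep = (freqs >= lo - 1e-12) & (freqs <= hi + 1e-12)
    if not keep.any():
        raise ValueError(f"band {band_hz} contains no DFT bins at n={n}, TR={tr}")

    def _filt(m: np.ndarray) -> np.ndarray:
        spec = np.fft.rfft(m, axis=-1)
        spec[..., ~keep] = 0.0
        return np.fft.irfft(spec, n=n, axis=-1)

    return _masked_apply(vol, mask, _filt)


def smooth_gaussian(obj: Fmri4DVolume | FeatureMap3D, fwhm_mm: float,
                    voxel_size_mm: float | None = None,
                    mask: BrainMask | None = None):
    """Spatial Gaussian smoothing with sigma = FWHM / (2*sqrt(2 ln 2) * voxel).

    Applied per timepoint (4D input) or once (3D feature map); boundary
    handling reflects at array edges, and the mask (if any) is re-applied
    afterwards so out-of-mask voxels stay untouched.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be nonnegative")
    vsize = voxel_size_mm if voxel_size_mm is not None else obj.voxel_size_mm
    if fwhm_mm == 0:
        return obj
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / vsize
    is_vol = isinstance(obj, Fmri4DVolume)
    data = obj.data
    sigmas = (sigma_vox, sigma_vox, sigma_vox, 0.0) if is_vol else (sigma_vox,) * 3
    smoothed = ndimage.gaussian_filter(data, sigma=sigmas, mode="reflect")
    if mask is not None:
        mask.check_grid(data.shape[:3])
        keep = mask.data if not is_vol else mask.data[..., None]
        smoothed = np.where(keep, smoothed, data)
    if is_vol:
        return obj.copy_with(smoothed)
    return FeatureMap3D(data=smoothed, kind=obj.kind, band_hz=obj.band_hz,
                        voxel_size_mm=obj.voxel_size_mm, meta=dict(obj.meta))


def _clean_design(confounds: np.ndarray | None, n: int) -> np.ndarray:
    """Intercept column plus confounds, dropping linearly dependent columns."""
    cols = [np.ones(n)]
    if confounds is not None and np.size(confounds) > 0:
        conf = np.atleast_2d(np.asarray(confounds, dtype=np.float64))
        if conf.shape[0] != n:
            conf = conf.T
        if conf.shape[0] != n:
            raise ValueError(f"confound rows {conf.shape} do not match {n} timepoints")
        cols.extend(conf.T)
    design = np.column_stack(cols)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        # drop dependent columns, judged by the magnitude of QR diagonal entries
        _, r = np.linalg.qr(design)
        diag = np.abs(np.diag(r))
        keep = diag > diag.max() * 1e-10
        logger.warning("nuisance design rank-deficient: dropping %d dependent column(s)",
                       int((~keep).sum()))
        design = design[:, keep]
    return design


def nuisance_regress(vol: Fmri4DVolume, confound_regressors: np.ndarray | None,
                     mask: BrainMask | None = None) -> Fmri4DVolume:
    """Per-voxel residual of OLS regression on confounds (+ intercept).

    With an empty confound set this reduces to mean-centering.  Residuals
    are orthogonal to every retained confound column.
    """
    design = _clean_design(confound_regressors, vol.n_timepoints)

    def _resid(m: np.ndarray) -> np.ndarray:
        beta, *_ = np.linalg.lstsq(design, m.T, rcond=None)
        return m - (design @ beta).T

    return _masked_apply(vol, mask, _resid)


def preprocess_volume(vol: Fmri4DVolume, config: PreprocessConfig,
                      mask: BrainMask | None = None,
                      steps: tuple[str, ...] | None = None) -> Fmri4DVolume:
    """Run the configured steps in order (default detrend→nuisance→smooth→bandpass)."""
    config.validate_band(vol.tr_seconds)
    for step in (steps if steps is not None else config.order):
        if step == "detrend":
            vol = linear_detrend(vol, mask=mask)
        elif step == "nuisance":
            vol = nuisance_regress(vol, config.confound_regressors, mask=mask)
        elif step == "smooth":
            vol = smooth_gaussian(vol, config.fwhm_mm, mask=mask)
        elif step == "bandpass":
            vol = bandpass(vol, config.band_hz, mask=mask)
        else:
            raise ValueError(f"unknown preprocessing step {step!r}")
    return vol


def load_confounds(path) -> np.ndarray:
    """Read a whitespace- or comma-delimited confound table (rows = timepoints)."""
    try:
        return np.loadtxt(path, delimiter=",", ndmin=2)
    except ValueError:
        return np.loadtxt(path, ndmin=2)
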