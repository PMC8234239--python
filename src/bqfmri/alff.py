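"""Amplitude of low-frequency fluctuations (ALFF) and fractional ALFF.

ALFF is the mean of the per-bin amplitude spectrum (square root of the
power spectrum) of a voxel's time series over a low-frequency band,
conventionally 0.01-0.12 Hz at TR = 2 s.  Fractional ALFF (fALFF) divides
the summed in-band amplitude by the summed amplitude over the whole
detectable range excluding DC, giving a scale-invariant quantity in [0, 1].
The "m"-prefixed maps (mALFF, mfALFF) standardize the raw map by its
in-mask mean, so the standardized map has in-mask mean exactly 1.

Spectrum normalization: one-sided, scaled so a pure on-bin sinusoid of
amplitude A has amplitude A at its bin.  Under this convention Parseval's
identity reads  mean(ts^2) = a_0^2 + sum_interior a_k^2 / 2 (+ a_Nyq^2 for
even n).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import BrainMask, FeatureMap3D, Fmri4DVolume

logger = logging.getLogger(__name__)


@dataclass
class SpectrumResult:
    """One-sided amplitude spectrum on the DFT bin grid."""

    freqs_hz: np.ndarray  # floor(t/2)+1 increasing values, freqs[0] = 0
    amplitude: np.ndarray  # same length, nonnegative


def _amplitudes(ts: np.ndarray, tr_seconds: float) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized one-sided amplitude spectrum over the last axis."""
    ts = np.asarray(ts, dtype=np.float64)
    n = ts.shape[-1]
    if n < 8:
        raise ValueError("need at least 8 timepoints")
    if not np.all(np.isfinite(ts)):
        raise ValueError("time series contains non-finite values")
    freqs = np.fft.rfftfreq(n, d=tr_seconds)
    amp = np.abs(np.fft.rfft(ts, axis=-1)) / n
    amp[..., 1:] *= 2.0
    if n % 2 == 0:
        amp[..., -1] /= 2.0  # Nyquist bin is not doubled
    return freqs, amp


def amplitude_spectrum(ts: np.ndarray, tr_seconds: float) -> SpectrumResult:
    freqs, amp = _amplitudes(np.atleast_1d(ts), tr_seconds)
    return SpectrumResult(freqs_hz=freqs, amplitude=amp)


def _band_bins(freqs: np.ndarray, band_hz: tuple[float, float]) -> np.ndarray:
    lo, hi = band_hz
    if not 0 <= lo < hi:
        raise ValueError(f"invalid band {band_hz}")
    # closed interval on bin frequencies; tolerance guards float bin edges
    return (freqs >= lo - 1e-12) & (freqs <= hi + 1e-12)


def alff(ts: np.ndarray, tr_seconds: float, band_hz: tuple[float, float] = (0.01, 0.12),
         sqrt_after_mean: bool = False) -> float | np.ndarray:
    """Mean in-band amplitude (default), or sqrt of mean in-band power.

    ``sqrt_after_mean=True`` selects the literal "square root after
    averaging the power" reading; the default follows the convention of the
    ALFF literature (mean of per-bin square-rooted power).
    """
    freqs, amp = _amplitudes(ts, tr_seconds)
    in_band = _band_bins(freqs, band_hz)
    if not in_band.any():
        raise ValueError(f"band {band_hz} contains no DFT bins "
                         f"(n={np.shape(ts)[-1]}, TR={tr_seconds})")
    if sqrt_after_mean:
        out = np.sqrt((amp[..., in_band] ** 2).mean(axis=-1))
    else:
        out = amp[..., in_band].mean(axis=-1)
    return float(out) if out.ndim == 0 else out


def falff(ts: np.ndarray, tr_seconds: float, band_hz: tuple[float, float] = (0.01, 0.12)
          ) -> float | np.ndarray:
    """In-band amplitude sum over total non-DC amplitude sum; in [0, 1].

    DC is excluded from the denominator: detrending removes it, and it
    would otherwise dominate.  All-zero series yield 0 with a warning.
    """
    freqs, amp = _amplitudes(ts, tr_seconds)
    in_band = _band_bins(freqs, band_hz) & (freqs > 0)
    num = amp[..., in_band].sum(axis=-1)
    den = amp[..., 1:].sum(axis=-1)
    zero = den == 0
    if np.any(zero):
        logger.warning("fALFF of an all-zero (non-DC) series defined as 0")
    out = np.divide(num, den, out=np.zeros_like(num), where=~zero)
    return float(out) if out.ndim == 0 else out


def feature_map(vol: Fmri4DVolume, mask: BrainMask,
                kind: str = "mfalff", band_hz: tuple[float, float] = (0.01, 0.12),
                sqrt_after_mean: bool = False) -> FeatureMap3D:
    """Voxel-wise ALFF-family map; kinds malff/mfalff divide by the in-mask mean."""
    if kind not in ("alff", "falff", "malff", "mfalff"):
        raise ValueError(f"unsupported ALFF-family kind {kind!r}")
    mask.check_grid(vol.grid_shape)
    series = vol.data[mask.data]  # (n_in_mask, t)
    if kind in ("alff", "malff"):
        vals = alff(series, vol.tr_seconds, band_hz, sqrt_after_mean=sqrt_after_mean)
    else:
        vals = falff(series, vol.tr_seconds, band_hz)
    vals = np.asarray(vals, dtype=np.float64)
    if kind in ("malff", "mfalff"):
        mean = vals.mean()
        if mean <= 0:
            raise ValueError(f"cannot standardize {kind}: in-mask mean is {mean}")
        vals = vals / mean
    data = np.zeros(vol.grid_shape)
    data[mask.data] = vals
    return FeatureMap3D(data=data, kind=kind, band_hz=tuple(band_hz),
                        voxel_size_mm=vol.voxel_size_mm)
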