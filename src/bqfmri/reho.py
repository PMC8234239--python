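"""Regional homogeneity (ReHo) via Kendall's coefficient of concordance.

Each voxel's ReHo is Kendall's W computed over that voxel together with its
in-mask 26-connected neighbors (up to K = 27 concordant time series),
measuring how similarly the local neighborhood ranks the timepoints:

    W = 12 * S / (K^2 * (n^3 - n)),   S = sum_t (R_t - K(n+1)/2)^2

where R_t is the rank sum across the K series at timepoint t and ranks are
mid-ranks under ties.  By default no tie-correction term enters the
denominator, matching the original ReHo formulation; a corrected
denominator K^2(n^3 - n) - K * sum_j T_j is available as an option.

The mReHo map divides a ReHo map by its in-mask mean (result mean 1).
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage
from scipy.stats import rankdata

from .core import BrainMask, FeatureMap3D, Fmri4DVolume

logger = logging.getLogger(__name__)


def _tie_term(values: np.ndarray) -> float:
    """Kendall tie statistic T = sum over tie groups of (t^3 - t) for one series."""
    _, counts = np.unique(values, return_counts=True)
    counts = counts[counts > 1]
    return float((counts**3 - counts).sum())


def kendalls_w(series: np.ndarray, tie_correction: bool = False) -> float:
    """Kendall's W of K time series over n timepoints, in [0, 1].

    ``series`` is a (K, n) array of raw values or of precomputed rankings;
    mid-ranks are (re)assigned internally, which is idempotent on rankings.
    If every series is constant (all ranks tied) W is defined as 0.
    """
    series = np.asarray(series, dtype=np.float64)
    if series.ndim != 2:
        raise ValueError("expected a (K, n) matrix of series")
    k, n = series.shape
    if k < 2 or n < 2:
        raise ValueError(f"need K >= 2 raters and n >= 2 timepoints, got {series.shape}")
    ranks = rankdata(series, axis=1)
    rank_sums = ranks.sum(axis=0)
    s = float(((rank_sums - k * (n + 1) / 2.0) ** 2).sum())
    denom = k * k * (n**3 - n)
    if tie_correction:
        denom -= k * sum(_tie_term(row) for row in series)
    if denom <= 0 or np.all(ranks == (n + 1) / 2.0):
        logger.warning("all series constant (every rank tied): W defined as 0")
        return 0.0
    return 12.0 * s / denom


def _neighborhood_kernel(size: int) -> np.ndarray:
    """3x3x3 structuring element: 27 (full box), 19 (faces+edges), or 7 (faces)."""
    off = np.abs(np.indices((3, 3, 3)) - 1).sum(axis=0)
    if size == 27:
        return np.ones((3, 3, 3))
    if size == 19:
        return (off <= 2).astype(float)
    if size == 7:
        return (off <= 1).astype(float)
    raise ValueError(f"neighborhood must be 7, 19 or 27, got {size}")


def reho_map(vol: Fmri4DVolume, mask: BrainMask, k_min: int = 14,
             neighborhood: int = 27, tie_correction: bool = False,
             require_full: bool = False) -> FeatureMap3D:
    """Voxel-wise Kendall's W over each voxel's in-mask neighborhood.

    At mask edges W is computed over the available in-mask neighbors
    (K <= neighborhood); voxels with fewer than ``k_min`` contributing
    series are set to 0.  ``require_full=True`` keeps only voxels with the
    complete neighborhood in-mask.
    """
    mask.check_grid(vol.grid_shape)
    if any(s < 3 for s in vol.grid_shape):
        raise ValueError(f"grid {vol.grid_shape} too small: need >= 3 voxels per axis")
    n = vol.n_timepoints
    kernel = _neighborhood_kernel(neighborhood)
    k_req = neighborhood if require_full else k_min

    maskf = mask.data.astype(np.float64)
    ranks = rankdata(vol.data, axis=-1) * maskf[..., None]
    # rank sum over the neighborhood, per timepoint, in one 4D correlation
    rank_sums = ndimage.correlate(ranks, kernel[..., None], mode="constant", cval=0.0)
    k_count = ndimage.correlate(maskf, kernel, mode="constant", cval=0.0)
    k_count = np.rint(k_count)

    s = ((rank_sums - k_count[..., None] * (n + 1) / 2.0) ** 2).sum(axis=-1)
    denom = k_count**2 * (n**3 - n)
    if tie_correction:
        ties = np.zeros(vol.grid_shape)
        ties[mask.data] = [_tie_term(row) for row in vol.data[mask.data]]
        denom = denom - k_count * ndimage.correlate(ties, kernel, mode="constant", cval=0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(denom > 0, 12.0 * s / denom, 0.0)
    w[(k_count < max(k_req, 2)) | ~mask.data] = 0.0
    w = np.clip(w, 0.0, 1.0)
    return FeatureMap3D(data=w, kind="reho", voxel_size_mm=vol.voxel_size_mm,
                        meta={"k_min": k_req, "neighborhood": neighborhood,
                              "tie_correction": tie_correction})


def mreho(fmap: FeatureMap3D, mask: BrainMask) -> FeatureMap3D:
    """Standardize a ReHo map by its in-mask mean (result in-mask mean = 1)."""
    mask.check_grid(fmap.data.shape)
    mean = fmap.data[mask.data].mean()
    if mean <= 0:
        raise ValueError(f"cannot standardize: in-mask mean ReHo is {mean}")
    data = np.where(mask.data, fmap.data / mean, 0.0)
    return FeatureMap3D(data=data, kind="mreho", band_hz=fmap.band_hz,
                        voxel_size_mm=fmap.voxel_size_mm, meta=dict(fmap.meta))
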