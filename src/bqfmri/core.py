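"""Core in-memory containers shared by every pipeline stage.

A scan is a 4D BOLD array (x, y, z, t) with its repetition time and voxel
size; a mask is a binary 3D array on the same grid; a feature map is one
scalar per voxel (zero outside the mask).  NIfTI round-trips go through
nibabel with a diagonal affine scaled by the voxel size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

FEATURE_KINDS = ("alff", "falff", "malff", "mfalff", "reho", "mreho")


@dataclass
class Fmri4DVolume:
    """One resting-state scan: BOLD time series on a 3D voxel grid."""

    data: np.ndarray  # (x, y, z, t), float
    tr_seconds: float
    voxel_size_mm: float = 3.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D (x, y, z, t) array, got ndim={self.data.ndim}")
        if self.data.shape[3] < 8:
            raise ValueError(f"need at least 8 timepoints, got {self.data.shape[3]}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def nyquist_hz(self) -> float:
        return 0.5 / self.tr_seconds

    def copy_with(self, data: np.ndarray) -> "Fmri4DVolume":
        return Fmri4DVolume(data=data, tr_seconds=self.tr_seconds,
                            voxel_size_mm=self.voxel_size_mm)


@dataclass
class BrainMask:
    """Binary inclusion mask aligned to a scan's spatial grid."""

    data: np.ndarray  # (x, y, z), bool

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3D")
        if not self.data.any():
            raise ValueError("mask is empty: no in-mask voxels")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def check_grid(self, grid_shape: tuple[int, int, int]) -> None:
        if tuple(self.data.shape) != tuple(grid_shape):
            raise ValueError(
                f"mask shape {self.data.shape} does not match grid {grid_shape}")


@dataclass
class FeatureMap3D:
    """One scalar feature per voxel (ALFF/fALFF/mALFF/mfALFF/ReHo/mReHo).

    Values are zero outside the mask; standardized kinds (``malff``,
    ``mfalff``, ``mreho``) have in-mask mean 1 by construction.
    """

    data: np.ndarray  # (x, y, z)
    kind: str
    band_hz: tuple[float, float] | None = None
    voxel_size_mm: float = 3.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("feature map must be 3D")
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}; expected one of {FEATURE_KINDS}")


def _affine(voxel_size_mm: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = float(voxel_size_mm)
    return aff


def save_volume(vol: Fmri4DVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(vol.data.astype(np.float32), _affine(vol.voxel_size_mm))
    img.header.set_zooms((vol.voxel_size_mm,) * 3 + (vol.tr_seconds,))
    nib.save(img, str(path))


def load_volume(path: str | Path) -> Fmri4DVolume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    return Fmri4DVolume(data=data, tr_seconds=tr, voxel_size_mm=float(zooms[0]))


def save_mask(mask: BrainMask, path: str | Path, voxel_size_mm: float = 3.0) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), _affine(voxel_size_mm))
    nib.save(img, str(path))


def load_mask(path: str | Path) -> BrainMask:
    img = nib.load(str(path))
    return BrainMask(data=np.asanyarray(img.dataobj) > 0)


def save_feature_map(fmap: FeatureMap3D, path: str | Path) -> None:
    """Write a 3D NIfTI plus a sidecar JSON recording kind/band/meta."""
    img = nib.Nifti1Image(fmap.data.astype(np.float32), _affine(fmap.voxel_size_mm))
    nib.save(img, str(path))
    sidecar = Path(str(path)).with_suffix("").with_suffix("")  # strip .nii.gz / .nii
    sidecar = Path(str(sidecar) + ".json")
    payload = {"kind": fmap.kind, "band_hz": list(fmap.band_hz) if fmap.band_hz else None,
               **fmap.meta}
    sidecar.write_text(json.dumps(payload, indent=2))


def load_feature_map(path: str | Path) -> FeatureMap3D:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    sidecar = Path(str(path).removesuffix(".gz").removesuffix(".nii") + ".json")
    kind, band = "alff", None
    meta: dict = {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        kind = meta.pop("kind", kind)
        band = meta.pop("band_hz", None)
    zooms = img.header.get_zooms()
    return FeatureMap3D(data=data, kind=kind,
                        band_hz=tuple(band) if band else None,
                        voxel_size_mm=float(zooms[0]), meta=meta)
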