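"""Synthetic resting-state cohorts with controllable group effects.

The study data this pipeline targets (three groups of scans: betel-quid
chewers BQ, tobacco/alcohol controls TA, healthy controls HC) are not
openly available, so every downstream stage is exercised on generated
cohorts whose ground truth is known.

Signal model, per voxel::

    ts = base_amplitude * multiplier * (sqrt(c) * shared + sqrt(1-c) * private)
         + noise_sd * N(0, 1)

where ``shared`` is one band-limited oscillation common to all voxels of an
effect ROI (its weight ``c`` is the coherence fraction driving regional
homogeneity) and ``private`` is an independent oscillation per voxel.  Each
oscillation is a sum of ``n_sinusoids`` unit-amplitude sinusoids at random
in-band frequencies with uniform random phases: band-limited, aperiodic,
stationary, with known expected band power.  Voxels outside every ROI carry
an unmodulated private baseline oscillation plus noise.

Scans of the same subject reuse the subject's oscillation draws and differ
only in noise, so paired-scan designs (two phase-encoding acquisitions per
person) can be emulated and fold-leakage across train/test exposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import BrainMask, Fmri4DVolume, save_mask, save_volume

DEFAULT_GROUP_SIZES = {"BQ": 30, "TA": 30, "HC": 33}


@dataclass
class EffectRoi:
    """Axis-aligned box with group-dependent amplitude and coherence effects."""

    voxel_block: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
    amplitude_multiplier_per_group: dict[str, float]
    coherence_fraction_per_group: dict[str, float]
    oscillation_band_hz: tuple[float, float] = (0.01, 0.12)

    def __post_init__(self) -> None:
        for lo, hi in self.voxel_block:
            if hi <= lo or lo < 0:
                raise ValueError(f"degenerate voxel_block {self.voxel_block}")
        if any(m <= 0 for m in self.amplitude_multiplier_per_group.values()):
            raise ValueError("amplitude multipliers must be positive")
        if any(not 0.0 <= c <= 1.0 for c in self.coherence_fraction_per_group.values()):
            raise ValueError("coherence fractions must lie in [0, 1]")

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(lo, hi) for lo, hi in self.voxel_block)  # type: ignore[return-value]

    def check_grid(self, grid_shape: tuple[int, int, int]) -> None:
        for (lo, hi), n in zip(self.voxel_block, grid_shape):
            if hi > n:
                raise ValueError(f"voxel_block {self.voxel_block} exceeds grid {grid_shape}")


def default_effect_rois(grid_shape: tuple[int, int, int]) -> list[EffectRoi]:
    """Two boxes in the central half of the grid (inside an inscribed
    ellipsoid mask): one carries a pure amplitude (ALFF) effect, the other
    a pure coherence (ReHo) effect, each ordered BQ > TA > HC so all three
    default groups are pairwise separable.  On the default 24^3 grid the
    boxes are (6:12)^3 and (12:18)^3.
    """
    inner = tuple((n // 4, n // 2) for n in grid_shape)
    outer = tuple((n // 2, max(n // 2 + 1, 3 * n // 4)) for n in grid_shape)
    return [
        EffectRoi(voxel_block=inner,
                  amplitude_multiplier_per_group={"BQ": 2.0, "TA": 1.5, "HC": 1.0},
                  coherence_fraction_per_group={"BQ": 0.0, "TA": 0.0, "HC": 0.0}),
        EffectRoi(voxel_block=outer,
                  amplitude_multiplier_per_group={"BQ": 1.0, "TA": 1.0, "HC": 1.0},
                  coherence_fraction_per_group={"BQ": 0.9, "TA": 0.55, "HC": 0.2}),
    ]


@dataclass
class CohortSpec:
    """Conditions under which a synthetic cohort is generated.

    Defaults mirror the study design where applicable: TR 2 s, 240
    timepoints per scan, group map counts BQ 30 / TA 30 / HC 33.  The
    grid defaults to a desk-scale 24^3 (the study grid was 53x63x46 at
    3 mm); both are configurable.
    """

    grid_shape: tuple[int, int, int] = (24, 24, 24)
    n_timepoints: int = 240
    tr_seconds: float = 2.0
    voxel_size_mm: float = 3.0
    group_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    effect_rois: list[EffectRoi] | None = None  # None -> default_effect_rois(grid)
    noise_sd: float = 1.0
    base_amplitude: float = 1.0
    baseline_band_hz: tuple[float, float] = (0.01, 0.12)
    n_sinusoids: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(s < 1 for s in self.grid_shape):
            raise ValueError("grid_shape must be 3 positive integers")
        if self.n_timepoints < 8:
            raise ValueError("need n_timepoints >= 8")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if any(c < 1 for c in self.group_sizes.values()) or not self.group_sizes:
            raise ValueError("all group sizes must be >= 1")
        if self.noise_sd < 0 or self.base_amplitude < 0:
            raise ValueError("noise_sd and base_amplitude must be nonnegative")
        if self.n_sinusoids < 1:
            raise ValueError("need at least one sinusoid per oscillation")
        if self.effect_rois is None:
            self.effect_rois = default_effect_rois(self.grid_shape)
        nyq = 0.5 / self.tr_seconds
        for band in [self.baseline_band_hz] + [r.oscillation_band_hz for r in self.effect_rois]:
            lo, hi = band
            if not 0 < lo < hi <= nyq:
                raise ValueError(f"oscillation band {band} outside (0, Nyquist={nyq}]")
        for roi in self.effect_rois:
            roi.check_grid(self.grid_shape)


def make_mask(grid_shape: tuple[int, int, int], kind: str = "full") -> BrainMask:
    """Build an all-ones mask or an ellipsoid inscribed in the grid."""
    if kind == "full":
        return BrainMask(data=np.ones(grid_shape, dtype=bool))
    if kind == "ellipsoid":
        centers = [(n - 1) / 2.0 for n in grid_shape]
        radii = [n / 2.0 for n in grid_shape]
        grids = np.ogrid[tuple(slice(0, n) for n in grid_shape)]
        r2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, centers, radii))
        return BrainMask(data=r2 <= 1.0)
    raise ValueError(f"unknown mask kind {kind!r}; expected 'full' or 'ellipsoid'")


def _oscillations(rng: np.random.Generator, n_series: int, n_sin: int,
                  band_hz: tuple[float, float], times: np.ndarray) -> np.ndarray:
    """n_series independent sums of n_sin random in-band sinusoids, shape (n_series, t)."""
    freqs = rng.uniform(band_hz[0], band_hz[1], size=(n_series, n_sin))
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(n_series, n_sin))
    arg = 2.0 * np.pi * freqs[:, :, None] * times[None, None, :] + phases[:, :, None]
    return np.sin(arg).sum(axis=1)


def simulate_scan(spec: CohortSpec, group_label: str, seed,
                  noise_seed=None) -> Fmri4DVolume:
    """Generate one scan for ``group_label``.

    The oscillation draws depend only on ``seed`` (not on the group), so
    simulating two groups with the same seed yields signals that differ
    exactly by the configured multipliers/coherence fractions.
    ``noise_seed`` defaults to a stream derived from ``seed``; passing
    distinct noise seeds with one oscillation seed emulates repeated scans
    of the same subject.
    """
    if group_label not in spec.group_sizes:
        raise ValueError(f"unknown group label {group_label!r}; "
                         f"expected one of {sorted(spec.group_sizes)}")
    rng = np.random.default_rng(seed)
    noise_rng = np.random.default_rng(noise_seed if noise_seed is not None else [seed, 1])

    nx, ny, nz = spec.grid_shape
    nt = spec.n_timepoints
    times = np.arange(nt) * spec.tr_seconds
    n_vox = nx * ny * nz

    baseline = _oscillations(rng, n_vox, spec.n_sinusoids, spec.baseline_band_hz, times)
    data = spec.base_amplitude * baseline.reshape(nx, ny, nz, nt)

    for roi in spec.effect_rois:
        sl = roi.slices()
        box_shape = tuple(s.stop - s.start for s in sl)
        n_box = int(np.prod(box_shape))
        shared = _oscillations(rng, 1, spec.n_sinusoids, roi.oscillation_band_hz, times)[0]
        private = _oscillations(rng, n_box, spec.n_sinusoids, roi.oscillation_band_hz, times)
        mult = roi.amplitude_multiplier_per_group.get(group_label, 1.0)
        coh = roi.coherence_fraction_per_group.get(group_label, 0.0)
        signal = np.sqrt(coh) * shared[None, :] + np.sqrt(1.0 - coh) * private
        data[sl] = (spec.base_amplitude * mult * signal).reshape(*box_shape, nt)

    if spec.noise_sd > 0:
        data = data + spec.noise_sd * noise_rng.standard_normal(data.shape)
    return Fmri4DVolume(data=data, tr_seconds=spec.tr_seconds,
                        voxel_size_mm=spec.voxel_size_mm)


def simulate_cohort(spec: CohortSpec, scans_per_subject: int = 1
                    ) -> list[tuple[Fmri4DVolume, str, str]]:
    """Generate the full cohort as ``(volume, label, subject_id)`` triples.

    ``group_sizes`` counts scans (maps).  With ``scans_per_subject > 1``
    each subject contributes that many scans sharing one oscillation seed
    (group size must then be divisible by ``scans_per_subject``).
    """
    if scans_per_subject < 1:
        raise ValueError("scans_per_subject must be >= 1")
    cohort: list[tuple[Fmri4DVolume, str, str]] = []
    subject_counter = 0
    for label, n_scans in spec.group_sizes.items():
        if n_scans % scans_per_subject != 0:
            raise ValueError(
                f"group {label!r} size {n_scans} not divisible by "
                f"scans_per_subject={scans_per_subject}")
        for _ in range(n_scans // scans_per_subject):
            subject_id = f"sub{subject_counter:03d}"
            for scan_idx in range(scans_per_subject):
                vol = simulate_scan(spec, label,
                                    seed=[spec.seed, subject_counter],
                                    noise_seed=[spec.seed, subject_counter, scan_idx])
                cohort.append((vol, label, subject_id))
            subject_counter += 1
    return cohort


def write_cohort(cohort: list[tuple[Fmri4DVolume, str, str]], out_dir: str | Path,
                 mask: BrainMask | None = None) -> pd.DataFrame:
    """Write scans as 4D NIfTI plus a labels table (filename, label, subject_id)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (vol, label, subject_id) in enumerate(cohort):
        fname = f"scan{i:03d}.nii.gz"
        save_volume(vol, out / fname)
        rows.append({"filename": fname, "label": label, "subject_id": subject_id})
    labels = pd.DataFrame(rows)
    labels.to_csv(out / "labels.csv", index=False)
    if mask is not None:
        save_mask(mask, out / "mask.nii.gz",
                  voxel_size_mm=cohort[0][0].voxel_size_mm if cohort else 3.0)
    return labels
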