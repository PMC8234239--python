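import numpy as np
import pytest

from bqfmri.core import BrainMask, Fmri4DVolume
from bqfmri.synthgen import CohortSpec, EffectRoi


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def noise_volume(rng):
    """Independent Gaussian noise on a small grid, TR 2 s."""
    return Fmri4DVolume(rng.standard_normal((8, 8, 8, 64)), tr_seconds=2.0)


@pytest.fixture
def full_mask():
    return BrainMask(np.ones((8, 8, 8), dtype=bool))


def tiny_cohort_spec(**overrides):
    """Minimal valid cohort spec for structural tests (no effect ROIs)."""
    kwargs = dict(grid_shape=(6, 6, 6), n_timepoints=24, tr_seconds=2.0,
                  group_sizes={"BQ": 2, "TA": 2, "HC": 2}, effect_rois=[],
                  noise_sd=0.5, seed=7)
    kwargs.update(overrides)
    return CohortSpec(**kwargs)


def one_roi_spec(coherence, multiplier, grid=12, noise_sd=0.0, **overrides):
    """Spec with a single 4^3 effect ROI whose parameters differ by group."""
    roi = EffectRoi(
        voxel_block=((4, 8), (4, 8), (4, 8)),
        amplitude_multiplier_per_group=multiplier,
        coherence_fraction_per_group=coherence)
    kwargs = dict(grid_shape=(grid, grid, grid), n_timepoints=48, tr_seconds=2.0,
                  group_sizes={"A": 2, "B": 2}, effect_rois=[roi],
                  noise_sd=noise_sd, seed=3)
    kwargs.update(overrides)
    return CohortSpec(**kwargs)
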