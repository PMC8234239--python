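"""Frozen desk-scale study conditions for validation runs.

The reference cohort (three groups, 30/30/33 maps, 53x63x46 grid, 240
timepoints) is too large for routine desk-scale validation, so these
presets fix a scaled analogue used by the test suite and the results
script: 3 groups x 12 maps on a 24^3 grid with 120 timepoints (TR 2 s,
>= 6 DFT bins inside the 0.01-0.12 Hz band), with the default effect ROIs
(an amplitude box and a coherence box, each ordered BQ > TA > HC).  The
null variant keeps the same signal structure but gives every group
identical effect parameters, so any classification signal would indicate
leakage.
"""

from __future__ import annotations

from .autoencoder import AutoencoderConfig, desk_scale_config
from .pipeline import RunConfig
from .synthgen import CohortSpec, EffectRoi

DESK_GRID = (24, 24, 24)
DESK_TIMEPOINTS = 120
DESK_GROUP_SIZES = {"BQ": 12, "TA": 12, "HC": 12}


def effect_cohort_spec(seed: int) -> CohortSpec:
    """Scaled cohort with the default group effects (groups differ)."""
    return CohortSpec(grid_shape=DESK_GRID, n_timepoints=DESK_TIMEPOINTS,
                      group_sizes=dict(DESK_GROUP_SIZES), seed=seed)


def null_cohort_spec(seed: int) -> CohortSpec:
    """Same cohort structure with all group effects equal (no class signal)."""
    rois = [
        EffectRoi(voxel_block=((6, 12), (6, 12), (6, 12)),
                  amplitude_multiplier_per_group={g: 1.5 for g in DESK_GROUP_SIZES},
                  coherence_fraction_per_group={g: 0.0 for g in DESK_GROUP_SIZES}),
        EffectRoi(voxel_block=((12, 18), (12, 18), (12, 18)),
                  amplitude_multiplier_per_group={g: 1.0 for g in DESK_GROUP_SIZES},
                  coherence_fraction_per_group={g: 0.5 for g in DESK_GROUP_SIZES}),
    ]
    return CohortSpec(grid_shape=DESK_GRID, n_timepoints=DESK_TIMEPOINTS,
                      group_sizes=dict(DESK_GROUP_SIZES), effect_rois=rois,
                      seed=seed)


def desk_run_config(spec: CohortSpec, seed: int, output_dir: str,
                    feature_kinds: tuple[str, ...] = ("mreho", "mfalff"),
                    ae_config: AutoencoderConfig | None = None) -> RunConfig:
    """Leakage-safe end-to-end run over a desk-scale cohort."""
    return RunConfig(seed=seed, output_dir=output_dir, simulate=spec,
                     autoencoder=ae_config or desk_scale_config(seed=seed),
                     feature_kinds=tuple(feature_kinds),
                     write_feature_maps=False)
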