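"""End-to-end orchestration: simulate/load -> preprocess -> features ->
encode -> classify -> report.

Feature-path convention: the ALFF family is computed on detrended,
nuisance-regressed, spatially smoothed series *without* temporal bandpass
(the band lives inside the spectral statistic; filtering to the analysis
band first would force fALFF to 1 everywhere), while ReHo is computed on
detrended, nuisance-regressed, bandpassed but *unsmoothed* series
(smoothing would trivially inflate neighborhood concordance).  Both paths
are configurable.

Autoencoder fold policy: the default (``leakage_safe=True``) trains the
autoencoder inside each LOOCV fold on training-fold maps only, encodes all
maps with that fold's encoder, and evaluates multiclass and one-vs-one
tasks on those latents; ``leakage_safe=False`` (train-once mode) trains one
autoencoder on all maps before cross-validation, which leaks the held-out
map into feature selection and is provided for comparison only.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alff import feature_map as alff_feature_map
from .autoencoder import (Autoencoder3D, AutoencoderConfig, encode_matrix,
                          pad_to_cube, train_autoencoder)
from .classify import (ClassificationReport, CohortFeatures, binary_report,
                       confusion_matrix, evaluate_features, fit_predict_proba,
                       loocv_folds, multiclass_report, _argmax_label)
from .core import BrainMask, Fmri4DVolume, load_mask, load_volume, save_feature_map
from .preprocess import PreprocessConfig, preprocess_volume
from .reho import mreho, reho_map
from .synthgen import CohortSpec, EffectRoi, make_mask, simulate_cohort

logger = logging.getLogger(__name__)

ALFF_KINDS = ("alff", "falff", "malff", "mfalff")
REHO_KINDS = ("reho", "mreho")
DEFAULT_ALFF_STEPS = ("detrend", "nuisance", "smooth")
DEFAULT_REHO_STEPS = ("detrend", "nuisance", "bandpass")


@dataclass
class RunConfig:
    """One declarative description of a full run (see ``from_dict``)."""

    seed: int
    output_dir: str
    simulate: CohortSpec | None = None
    scans_per_subject: int = 1
    data_dir: str | None = None
    mask_path: str | None = None
    mask_kind: str = "ellipsoid"
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    alff_steps: tuple[str, ...] = DEFAULT_ALFF_STEPS
    reho_steps: tuple[str, ...] = DEFAULT_REHO_STEPS
    feature_kinds: tuple[str, ...] = ("mfalff", "mreho")
    autoencoder: AutoencoderConfig = field(default_factory=AutoencoderConfig)
    grouping: str = "map"
    leakage_safe: bool = True
    reho_k_min: int = 14
    write_feature_maps: bool = True

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.data_dir is None):
            raise ValueError("exactly one input source required: "
                             "'simulate' spec or 'data_dir'")
        bad = set(self.feature_kinds) - set(ALFF_KINDS) - set(REHO_KINDS)
        if bad:
            raise ValueError(f"unknown feature kind(s): {sorted(bad)}")

    @classmethod
    def from_dict(cls, cfg: dict) -> "RunConfig":
        cfg = dict(cfg)
        inp = cfg.pop("input", {})
        sim = inp.get("simulate")
        sim_spec = None
        if sim is not None:
            sim = dict(sim)
            rois = sim.pop("effect_rois", None)
            if rois is not None:
                sim["effect_rois"] = [
                    EffectRoi(voxel_block=tuple(tuple(b) for b in r["voxel_block"]),
                              amplitude_multiplier_per_group=r.get(
                                  "amplitude_multiplier_per_group", {}),
                              coherence_fraction_per_group=r.get(
                                  "coherence_fraction_per_group", {}),
                              oscillation_band_hz=tuple(r.get("oscillation_band_hz",
                                                              (0.01, 0.12))))
                    for r in rois]
            for key in ("grid_shape", "baseline_band_hz"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            if "group_sizes" in sim:
                sim["group_sizes"] = dict(sim["group_sizes"])
            sim_spec = CohortSpec(**sim)
        pre = cfg.pop("preprocess", {})
        if "band_hz" in pre:
            pre["band_hz"] = tuple(pre["band_hz"])
        ae = cfg.pop("autoencoder", {})
        for key in ("input_shape", "padded_shape", "latent_shape",
                    "channel_schedule", "decoder_channels"):
            if key in ae and ae[key] is not None:
                ae[key] = tuple(ae[key])
        classify_cfg = cfg.pop("classify", {})
        return cls(
            seed=cfg.pop("seed"),
            output_dir=cfg.pop("output_dir", "bqfmri_out"),
            simulate=sim_spec,
            scans_per_subject=inp.get("scans_per_subject", 1),
            data_dir=inp.get("data_dir"),
            mask_path=inp.get("mask"),
            mask_kind=cfg.pop("mask_kind", "ellipsoid"),
            preprocess=PreprocessConfig(**pre),
            feature_kinds=tuple(cfg.pop("features", ("mfalff", "mreho"))),
            autoencoder=AutoencoderConfig(**ae),
            grouping=classify_cfg.get("grouping", "map"),
            leakage_safe=classify_cfg.get("leakage_safe", True),
            reho_k_min=cfg.pop("reho_k_min", 14),
            write_feature_maps=cfg.pop("write_feature_maps", True),
            **cfg)


def load_run_config(path: str | Path) -> RunConfig:
    try:
        cfg = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise ValueError(f"cannot parse config {path}: {exc}") from exc
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} is not a mapping")
    return RunConfig.from_dict(cfg)


def validate_config(cfg: dict) -> list[str]:
    """Findings that make the config non-runnable; empty list iff runnable."""
    findings: list[str] = []
    if "seed" not in cfg:
        findings.append("seed: mandatory and missing")
        cfg = {**cfg, "seed": 0}
    try:
        run = RunConfig.from_dict(cfg)
    except (ValueError, TypeError, KeyError) as exc:
        findings.append(str(exc))
        return findings
    tr = run.simulate.tr_seconds if run.simulate is not None else None
    if tr is not None:
        nyq = 0.5 / tr
        if run.preprocess.band_hz[1] > nyq:
            findings.append(f"band_hz: high edge {run.preprocess.band_hz[1]} Hz "
                            f"exceeds Nyquist {nyq} Hz at TR {tr} s")
    try:
        run.autoencoder.__post_init__()
    except ValueError as exc:  # pragma: no cover - caught at from_dict already
        findings.append(f"latent_shape: {exc}")
    if run.simulate is not None:
        grid = run.simulate.grid_shape
        if any(p < g for p, g in zip(run.autoencoder.padded_shape, grid)):
            findings.append(f"padded_shape: {run.autoencoder.padded_shape} smaller "
                            f"than simulated grid {grid}")
    return findings


def compute_feature_map(vol: Fmri4DVolume, mask: BrainMask, kind: str,
                        config: RunConfig):
    """One feature map for one scan, via the kind-appropriate preprocessing path."""
    pre = config.preprocess
    if kind in ALFF_KINDS:
        clean = preprocess_volume(vol, pre, mask=mask, steps=config.alff_steps)
        return alff_feature_map(clean, mask, kind=kind, band_hz=pre.band_hz)
    clean = preprocess_volume(vol, pre, mask=mask, steps=config.reho_steps)
    fmap = reho_map(clean, mask, k_min=config.reho_k_min)
    if kind == "mreho":
        fmap = mreho(fmap, mask)
    fmap.band_hz = tuple(pre.band_hz)
    return fmap


def _leakage_safe_reports(padded: list[np.ndarray], labels: list[str],
                          subject_ids: list[str], config: RunConfig,
                          feature_kind: str) -> ClassificationReport:
    """Per-fold autoencoder + LR: the held-out unit never enters AE training.

    Each fold's encoder (trained on training-fold maps only) encodes all
    maps; the multiclass and each one-vs-one task are evaluated on that
    fold's latents, so one AE training per fold serves every task.
    """
    n = len(padded)
    class_order = sorted(set(labels))
    y = np.asarray(labels)
    pairs_keys = [(c1, c2) for i, c1 in enumerate(class_order)
                  for c2 in class_order[i + 1:]]
    mc_pred: list[str] = [""] * n
    mc_scores = np.zeros((n, len(class_order)))
    pair_pred: dict = {p: {} for p in pairs_keys}
    pair_scores: dict = {p: {} for p in pairs_keys}
    folds = loocv_folds(n, subject_ids, config.grouping)
    for fold_idx, (train, test) in enumerate(folds):
        missing = set(class_order) - set(y[train])
        if missing:
            raise ValueError(f"fold {fold_idx}: class(es) {sorted(missing)} "
                             "absent from training data")
        model, _ = train_autoencoder([padded[i] for i in train], config.autoencoder,
                                     seed=config.seed)
        latents = encode_matrix(padded, model)
        proba = fit_predict_proba(latents[train], y[train], latents[test],
                                  class_order, seed=config.seed)
        for row, idx in zip(proba, test):
            mc_scores[idx] = row
            mc_pred[idx] = _argmax_label(row, class_order)
        for c1, c2 in pairs_keys:
            test_pair = [i for i in test if y[i] in (c1, c2)]
            if not test_pair:
                continue
            train_pair = [i for i in train if y[i] in (c1, c2)]
            proba2 = fit_predict_proba(latents[train_pair], y[train_pair],
                                       latents[test_pair], [c1, c2],
                                       seed=config.seed)
            for row, idx in zip(proba2, test_pair):
                pair_scores[(c1, c2)][idx] = row
                pair_pred[(c1, c2)][idx] = _argmax_label(row, [c1, c2])
        logger.info("%s fold %d/%d done", feature_kind, fold_idx + 1, len(folds))

    conf = confusion_matrix(list(y), mc_pred, class_order)
    pair_reports: dict[str, dict] = {}
    for c1, c2 in pairs_keys:
        idxs = sorted(pair_pred[(c1, c2)])
        yt = [y[i] for i in idxs]
        yp = [pair_pred[(c1, c2)][i] for i in idxs]
        sc = [pair_scores[(c1, c2)][i][1] for i in idxs]  # P(c2)
        pair_reports[f"{c1}_vs_{c2}"] = binary_report(yt, yp, sc, positive_class=c2)
        pair_reports[f"{c1}_vs_{c2}"]["positive_class"] = c2
    fold_df = pd.DataFrame({
        "subject_id": subject_ids, "true": list(y), "predicted": mc_pred,
        **{f"p_{c}": mc_scores[:, j] for j, c in enumerate(class_order)}})
    return ClassificationReport(
        feature_kind=feature_kind, class_order=class_order, confusion=conf,
        multiclass=multiclass_report(conf), pairs=pair_reports,
        fold_predictions=fold_df,
        settings={"grouping": config.grouping, "seed": config.seed,
                  "fold_policy": "autoencoder retrained per fold (leakage-safe)"})


def run_loocv(padded: list[np.ndarray], labels: list[str], subject_ids: list[str],
              config: RunConfig, feature_kind: str
              ) -> tuple[ClassificationReport, Autoencoder3D | None]:
    """Classification for one feature kind; returns the shared encoder in train-once mode."""
    if config.leakage_safe:
        return _leakage_safe_reports(padded, labels, subject_ids, config,
                                     feature_kind), None
    model, _ = train_autoencoder(padded, config.autoencoder, seed=config.seed)
    latents = encode_matrix(padded, model)
    features = CohortFeatures(matrix=latents, labels=labels,
                              subject_ids=subject_ids, feature_kind=feature_kind)
    report = evaluate_features(features, seed=config.seed, grouping=config.grouping)
    report.settings["fold_policy"] = "autoencoder trained once on all maps (train-once mode)"
    return report, model


def _load_cohort(config: RunConfig):
    if config.simulate is not None:
        cohort = simulate_cohort(config.simulate, config.scans_per_subject)
        mask = make_mask(config.simulate.grid_shape, config.mask_kind)
        return cohort, mask
    data_dir = Path(config.data_dir)
    labels_csv = data_dir / "labels.csv"
    if not labels_csv.exists():
        raise FileNotFoundError(f"input stage: missing labels table {labels_csv}")
    table = pd.read_csv(labels_csv)
    cohort = []
    for _, row in table.iterrows():
        path = data_dir / row["filename"]
        if not path.exists():
            raise FileNotFoundError(f"input stage: missing scan {path}")
        cohort.append((load_volume(path), str(row["label"]),
                       str(row.get("subject_id", row["filename"]))))
    if config.mask_path:
        mask = load_mask(config.mask_path)
    elif (data_dir / "mask.nii.gz").exists():
        mask = load_mask(data_dir / "mask.nii.gz")
    else:
        mask = make_mask(cohort[0][0].grid_shape, config.mask_kind)
    return cohort, mask


def run_pipeline(config: RunConfig) -> dict[str, ClassificationReport]:
    """Execute all stages and write maps, reports and a manifest to output_dir."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []

    cohort, mask = _load_cohort(config)
    labels = [lab for _, lab, _ in cohort]
    subject_ids = [sid for _, _, sid in cohort]
    logger.info("cohort: %d scans, groups %s", len(cohort),
                {c: labels.count(c) for c in sorted(set(labels))})
    if config.simulate is not None:
        labels_df = pd.DataFrame({"filename": [f"scan{i:03d}" for i in range(len(cohort))],
                                  "label": labels, "subject_id": subject_ids})
        labels_df.to_csv(out / "labels.csv", index=False)
        artifacts.append("labels.csv")

    reports: dict[str, ClassificationReport] = {}
    for kind in config.feature_kinds:
        maps = [compute_feature_map(vol, mask, kind, config) for vol, _, _ in cohort]
        if config.write_feature_maps:
            kind_dir = out / f"maps_{kind}"
            kind_dir.mkdir(exist_ok=True)
            for i, fmap in enumerate(maps):
                save_feature_map(fmap, kind_dir / f"map{i:03d}.nii.gz")
                artifacts += [f"maps_{kind}/map{i:03d}.nii.gz",
                              f"maps_{kind}/map{i:03d}.json"]
        padded = [pad_to_cube(m, config.autoencoder.padded_shape) for m in maps]
        report, model = run_loocv(padded, labels, subject_ids, config, kind)
        reports[kind] = report
        report.save(out / f"report_{kind}.json")
        artifacts += [f"report_{kind}.json", f"report_{kind}.predictions.csv"]
        if model is not None:
            model.save(out / f"autoencoder_{kind}.npz")
            latents = encode_matrix(padded, model)
            pd.DataFrame(latents).to_csv(out / f"latents_{kind}.csv", index=False)
            artifacts += [f"autoencoder_{kind}.npz", f"latents_{kind}.csv"]

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": _config_snapshot(config),
        "n_scans": len(cohort),
        "outputs": artifacts + ["manifest.json"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return reports


def _config_snapshot(config: RunConfig) -> dict:
    def _clean(obj):
        if isinstance(obj, (CohortSpec, PreprocessConfig, EffectRoi)):
            return {k: _clean(v) for k, v in obj.__dict__.items()}
        if isinstance(obj, AutoencoderConfig):
            return obj.to_dict()
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return obj
    return {k: _clean(v) for k, v in config.__dict__.items()}
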