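# bqfmri

Resting-state fMRI (rs-fMRI) analysis pipeline for discriminating
betel-quid (BQ) chewers from tobacco/alcohol-user controls (TA) and
healthy controls (HC): voxel-wise spectral and regional-homogeneity
feature maps, 3D convolutional-autoencoder compression, and
leave-one-out cross-validated logistic-regression classification with a
full metric suite.  Because cohort scans of this kind are typically
restricted, the package ships a synthetic-cohort generator with known
ground truth so the whole pipeline is testable end to end.

Intended users: neuroimaging researchers who want a reproducible,
library-grade implementation of the mfALFF/mReHo + autoencoder + LOOCV
classification workflow, and methodologists who want to probe its
behavior (fold leakage, null calibration) on simulated cohorts.

## The method

For each scan (4D BOLD volume, TR = 2 s, 240 timepoints at full scale):

- **ALFF / fALFF.**  Each voxel's detrended series is taken to the
  frequency domain by FFT.  ALFF is the mean of the one-sided amplitude
  spectrum (square root of power per bin) over the low-frequency band
  0.01–0.12 Hz; fractional ALFF divides the in-band amplitude sum by the
  amplitude sum over the whole detectable range (DC excluded):

      ALFF = mean_{f in band} a(f),   fALFF = sum_{band} a(f) / sum_{f>0} a(f)

  The map-level variants mALFF/mfALFF divide each map by its in-mask
  mean, so the standardized map has mean 1.

- **ReHo / mReHo.**  Regional homogeneity is Kendall's coefficient of
  concordance W between a voxel's bandpassed time series and its 26
  nearest neighbors (K ≤ 27 series over n timepoints):

      W = 12 S / (K² (n³ − n)),   S = Σ_t (R_t − K(n+1)/2)²

  with R_t the rank sum across the K series at timepoint t.  mReHo
  divides the map by its in-mask mean.

- **Compression.**  Feature maps are zero-padded to a 64³ cube and
  passed through a 3D convolutional autoencoder (nine 3×3×3 convolution
  layers with ReLU, three of them stride 2; three stride-2 transpose
  convolutions decode).  The latent block (8, 8, 8, 128) is flattened to
  a 65,536-long feature vector per map.  Training: Adam, learning rate
  1e−4, MSE reconstruction loss, 100 epochs.  The conv/transpose-conv
  engine is implemented in NumPy inside the package (`bqfmri.nn`).

- **Classification.**  L2-regularized logistic regression under
  leave-one-out cross-validation, three-class and one-vs-one; metrics:
  confusion matrix, accuracy, per-class correct classification rate
  (CCR), Cohen's kappa, precision/recall/F1, and ROC/AUC pooled over the
  held-out fold probabilities.  The default fold policy retrains the
  autoencoder inside every fold on training maps only (leakage-safe);
  `leakage_safe=False` reproduces the train-once-on-everything variant.

## Worked example

Desk-scale synthetic study: 3 groups × 12 scans on a 24³ grid with 120
timepoints.  Group effects live in two central boxes — one with higher
low-frequency amplitude (BQ 2.0× > TA 1.5× > HC 1.0×), one with higher
local coherence (BQ 0.9 > TA 0.55 > HC 0.2) — on top of unit Gaussian
noise.

```python
from bqfmri.presets import desk_run_config, effect_cohort_spec
from bqfmri.pipeline import run_pipeline

spec = effect_cohort_spec(seed=11)
config = desk_run_config(spec, seed=11, output_dir="out",
                         feature_kinds=("mreho", "mfalff"))
reports = run_pipeline(config)
for kind, rep in reports.items():
    mc = rep.multiclass
    print(kind, round(mc["accuracy"], 3), round(mc["kappa"], 3))
```

Output:

```
mreho 1.0 1.0
mfalff 0.667 0.5
```

The coherence effect is strong at this noise level, so mReHo latents
separate the three groups perfectly under leave-one-out (accuracy 1.0,
kappa 1.0); the amplitude effect expressed through mfALFF is harder
(accuracy 0.667 against a chance level of 1/3).  `out/` receives the
per-kind report JSON/CSV and a manifest describing the run.

The same pipeline is scriptable from the shell:

```bash
bqfmri simulate --out cohort --seed 3 --grid 24 --timepoints 120
bqfmri run-all run.yaml --seed 11
bqfmri validate run.yaml
```

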