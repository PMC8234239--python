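# Methods

## Scope and data model

The package analyzes resting-state BOLD scans represented as 4D arrays
(x, y, z, t) with a repetition time (TR, seconds) and isotropic voxel
size (mm), restricted to a binary brain mask.  Scanner-side corrections
(slice timing, realignment, spatial normalization, resampling) are
assumed already done; the synthetic generator produces data directly in
aligned grid space, so those steps are out of scope by construction.

## Preprocessing

Four in-scope operations, each shape-preserving and mask-respecting
(out-of-mask voxels are never modified):

- **Linear detrending** removes each voxel's least-squares line
  (intercept + slope); the residual series has mean ~0.
- **Bandpass filtering** is an *ideal* filter: the series is taken to
  the DFT domain and every bin with frequency outside the closed
  interval [low, high] is zeroed (default 0.01–0.12 Hz).  This choice
  makes the filter's bookkeeping identical to the ALFF band bookkeeping
  (bin-for-bin), and on-bin gains are exactly 1 (passband) and 0
  (stopband), so filter contracts are testable without tolerance
  gymnastics.  The trade-off — modest time-domain ringing for broadband
  inputs — is irrelevant to the rank- and amplitude-based statistics
  computed downstream.
- **Gaussian smoothing** uses σ = FWHM / (2√(2 ln 2) · voxel size)
  voxels (default FWHM 6 mm at 3 mm voxels → σ ≈ 0.85 voxels), applied
  per timepoint with reflecting boundaries, after which the mask is
  re-applied.  Reflection avoids intensity bleed at mask edges
  dominating small test grids.
- **Nuisance regression** projects each voxel's series onto the
  orthogonal complement of the confound columns plus an always-included
  intercept.  Rank-deficient designs drop dependent columns (judged by
  QR diagonal magnitude) with a logged warning.  With no confounds the
  step reduces to mean-centering.

**Per-feature preprocessing paths.**  The ALFF family is computed on
detrended, nuisance-regressed, smoothed but *unfiltered* series: the
analysis band is selected inside the spectral statistic itself, and
bandpassing to the same band first would force fALFF ≡ 1 and destroy the
feature.  ReHo is computed on detrended, nuisance-regressed, bandpassed
but *unsmoothed* series: spatial smoothing mixes neighboring series and
would inflate neighborhood concordance trivially.  Both paths are
configurable (`RunConfig.alff_steps`, `RunConfig.reho_steps`).

## Spectral features (ALFF, fALFF, mALFF, mfALFF)

The one-sided amplitude spectrum is normalized so that a pure sinusoid
of amplitude A landing on DFT bin k has amplitude A at bin k.  Under
this convention Parseval's identity reads
`mean(ts²) = a₀² + Σ_interior a_k²/2 (+ a_Nyq²)`, which the test suite
checks to 1e−6 relative error.

- ALFF = mean per-bin amplitude over band bins (closed interval on bin
  frequencies).  The alternative reading "square root after averaging
  the power" is available via `sqrt_after_mean=True`; the default
  follows the convention of the ALFF literature (mean of square-rooted
  power).
- fALFF = in-band amplitude sum / full-range amplitude sum, excluding
  the DC bin from the denominator (detrending removes DC; including it
  would let an arbitrary offset dominate the normalization).  fALFF is
  scale-invariant and lies in [0, 1]; ALFF is scale-equivariant.
- mALFF/mfALFF divide the raw map by its in-mask mean (in-mask mean
  exactly 1).  The "m"-standardization by the in-mask mean is the
  standard reading of the m-prefix convention.

Note that fALFF carries group information only relative to broadband
noise: for a noiseless narrowband signal fALFF is 1 regardless of
amplitude, so amplitude effects appear in mfALFF through the in-band
signal-to-noise ratio, not through amplitude per se.

## Regional homogeneity (ReHo, mReHo)

Kendall's W over each voxel plus its in-mask 26-connected neighbors
(K ≤ 27 series, n timepoints), with mid-ranks under ties and, by
default, *no* tie-correction term in the denominator — matching the
original ReHo formulation; a tie-corrected denominator is available
(`tie_correction=True`).  Neighborhood sizes 7/19/27 are selectable.

Mask-edge policy: W is computed over the available in-mask neighbors,
and voxels with fewer than `k_min = 14` contributing series are set to
0.  Discarding edge voxels entirely (`require_full=True`) is available
but would zero a large shell on desk-scale grids.  If every series in a
neighborhood is constant, W is defined as 0 (warned).

Under independence E[W] = 1/K, which anchors the white-noise
calibration test (interior mean ≈ 1/27 ± 0.01 over ≥ 500 voxels).  For
untied data W equals ((K−1)ρ̄ + 1)/K with ρ̄ the mean pairwise Spearman
correlation; the suite verifies this identity to 1e−10 against a
brute-force oracle.

mReHo divides a ReHo map by its in-mask mean; voxels zeroed by the
`k_min` rule stay in the mask and therefore enter that mean.

## Autoencoder compression

Reference architecture: input maps zero-padded (centered) to 64³; nine
3×3×3 convolutions with ReLU, channel schedule
16→16→32→32→64→64→128→128→128, strides 2 at layers 3, 6, 9 (64→8 via
three halvings, ending at 128 channels); decoder of three stride-2
transpose convolutions back to (64, 64, 64, 1).  The latent block
(8, 8, 8, 128) flattens (C-order: spatial-major, channel-minor) to
65,536 features.  Kernel sizes, channel widths and stride placement
beyond the layer counts and latent size are design choices here and are
configurable (`channel_schedule`, `stride_placement`,
`decoder_channels`).

Numerics: the conv engine is pure NumPy (im2col + matmul; the transpose
convolution is implemented as the exact adjoint of the strided
convolution, verified by finite differences to ~1e−8 in float64).
Training uses float32, per-map scaling by the map's max absolute value
(MSE stability; recorded in the model metadata), Adam (β₁ 0.9, β₂
0.999), MSE loss, batch size 8, 100 epochs at learning rate 1e−4 for
the reference configuration.  All randomness (weight init, batch
shuffling) flows from one seeded generator, so the train→encode path is
bit-reproducible; a non-finite loss aborts with diagnostics.  ReLU is
used on every layer including the output, which is consistent because
inputs are nonnegative and scaled to [0, 1].

**Fold policy.**  Training a single autoencoder on all maps before
cross-validation leaks every held-out map into feature selection.  The
default is therefore leakage-safe: inside each LOOCV fold the
autoencoder is retrained on training-fold maps only, that fold's encoder
encodes all maps, and the multiclass and one-vs-one tasks for that
fold's held-out unit are all evaluated on those latents (the encoder is
unsupervised, so sharing it across tasks within a fold leaks nothing
about the held-out unit).  `leakage_safe=False` (train-once mode) trains
once on all maps and is provided for comparison.

Whether the two feature kinds share one autoencoder was an open design
point; here each feature kind gets its own encoder, since the two maps
live on different value scales and carry different spatial structure.

## Classification and metrics

Logistic regression with L2 penalty at unit inverse-strength (C = 1),
deterministic lbfgs solver, iteration cap 5,000, multinomial objective
for the 3-class task; features are standardized per fold using
training-fold mean/SD only.  Predicted class = highest held-out
probability, exact ties broken to the lexicographically first label.
LOOCV holds out one map per fold, or one subject (`grouping="subject"`)
when paired scans of a person must stay together.

Metrics from the pooled held-out predictions: confusion matrix
(entry (i, j) = true i predicted j), accuracy = trace/total, CCR_c =
diagonal/row sum (per-class recall), Cohen's kappa
κ = (p_o − p_e)/(1 − p_e) with p_e from the confusion marginals,
precision/recall/F1 per one-vs-one pair, and AUC as the trapezoidal area
under the ROC built from the n pooled held-out probabilities (per-fold
ROC curves are degenerate at one test sample; pooling is the only
well-defined LOOCV construction).  AUC equals the normalized
Mann–Whitney U statistic with mid-rank ties, verified to 1e−10.  No
multiple-testing correction is applied across the three pairs.  Degenerate
cells are reported as missing (CCR of an empty class; precision/F1 when
nothing is predicted positive).

**LOOCV null behavior.**  Under permuted labels, LOOCV is pessimistic,
not unbiased: removing a map leaves its class as the training minority,
so null accuracy falls *below* chance — markedly for small balanced
cohorts (pooled accuracy ≈ 0.14 at n = 18 in our permutation test).
The permutation test therefore asserts the one-sided no-leakage bound
(observed correct ≤ upper 95% binomial bound of chance); the larger
end-to-end null cohort (n = 36) is additionally checked against the
central 95% binomial interval, where the bias is mild.

## Synthetic cohorts

Per voxel: `ts = base·m·(√c·shared + √(1−c)·private) + σ·N(0,1)`, where
each oscillation is a sum of 5 unit-amplitude sinusoids at uniformly
random in-band frequencies (default band 0.01–0.12 Hz) with uniform
phases — band-limited, aperiodic, stationary signals with known expected
band power.  Inside an effect ROI the amplitude multiplier m and the
coherence fraction c depend on the group; elsewhere m = 1, c = 0.
`shared` is drawn once per ROI per scan, so c directly controls
neighborhood concordance (c = 1 → identical series → W = 1).  Scans of
one subject reuse the subject's oscillation draws and differ only in
noise, which lets tests expose fold leakage when paired scans are split
across train/test.

Default desk-scale study conditions (`bqfmri.presets`): 3 groups × 12
maps, 24³ grid, 120 timepoints at TR 2 s (≥ 6 in-band DFT bins), noise
SD 1, base amplitude 1, and two central 6³ ROIs — amplitude multipliers
BQ 2.0 / TA 1.5 / HC 1.0 in one, coherence fractions BQ 0.9 / TA 0.55 /
HC 0.2 in the other — chosen as clearly separated but noise-dominated
effects of the kind the full-scale analysis presumes.  The full-scale
defaults (group sizes 30/30/33, 240 timepoints) match the reference
study design.  The matched null cohort gives every group identical
parameters (amplitude 1.5, coherence 0.5).

The desk-scale autoencoder preset keeps the reference depth (9 + 3
layers) on a 32³ padded grid with narrow channels
(4, 8, 8, 8, 8, 8, 8, 8, 8), early downsampling (strides at layers 1,
3, 5), latent (4, 4, 4, 8) → 512 features, 6 epochs at learning rate
1e−3.  Early downsampling is what keeps fold-wise retraining (36 folds
per feature kind) in the seconds-per-fold range; the latent size stays
an order of magnitude above the sample count, preserving the
high-dimensional-features/small-n character of the full-scale problem.

What the generator does **not** emulate: anatomical structure,
hemodynamic response shapes, scanner artifacts, head motion, slice
timing, physiological (cardiac/respiratory) rhythms, spatial
autocorrelation outside the effect ROIs, or realistic between-subject
variability.  Passing tests therefore demonstrate that the pipeline
recovers the statistical structure it targets (band-limited amplitude
and local coherence differences) and that its cross-validation is
leakage-free — not that the classifier would reach any particular
accuracy on real cohorts.

## Known limitations

- The NumPy conv engine is CPU-bound and desk-scale; the reference 64³
  configuration builds and encodes fine but trains slowly compared to a
  GPU framework.
- LOOCV accuracy estimates on 36 maps have wide confidence intervals;
  single-seed accuracies (e.g. the worked example's 1.0) should be read
  as "well above chance", not as a stable effect size.
- The one-vs-one AUCs pool held-out probabilities across folds whose
  classifiers differ; this is standard for LOOCV but makes the ROC a
  composite object.
- Subject-grouped LOOCV is implemented and tested structurally, but the
  desk-scale presets use one scan per subject.
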