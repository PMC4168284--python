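# Methods

`restpredict` implements a longitudinal resting-state fMRI multi-variate
pattern analysis (MVPA): from BOLD-like voxel time series it derives two
feature families — the amplitude of low-frequency fluctuation (ALFF) per
voxel and the Pearson functional-connectivity (FC) matrix between atlas
regions — selects a sparse informative subset of each by a bootstrapped
minimum-L1 procedure, and uses the selected features to classify trauma
survivors against controls (linear SVM) and to predict anxiety/depression
symptom severity (linear SVR) under leave-one-out cross-validation (LOOCV).
Statistical significance and informative-feature identification use
permutation tests with max-statistic family-wise error (FWE) correction.

## Signal conditioning

Each voxel (and nuisance) series is linearly detrended, then band-pass
filtered to 0.01–0.08 Hz with a Chebyshev type-I design (order 4, 0.5 dB
passband ripple) applied forward-backward (`sosfiltfilt`) for zero phase.
The filter family and band are fixed by the analysis design; the order and
ripple are this package's documented defaults (type I vs II, order and
ripple are otherwise unconstrained choices) and are exposed in
`PipelineConfig`. Detrending precedes filtering. With TR = 2 s the Nyquist
frequency is 0.25 Hz, so the band sits comfortably inside the valid range;
the design is rejected with a clear error if the band or order produce an
unstable filter.

## ALFF

The per-voxel ALFF is the mean of the square-root one-sided power spectrum
over FFT bins whose frequency lies in [0.01, 0.08] Hz, both edges
inclusive. The scaling convention is `P_k = c_k |X_k|^2 / T` with `c_k = 2`
except at DC and Nyquist, under which summed power equals time-domain
energy (Parseval); a test asserts that downstream results are invariant to
this convention because each subject's map is divided by its global mean
(mask = all voxels for synthetic data; a brain mask may be supplied for
NIfTI input). There is no fractional-ALFF variant.

## Functional connectivity

Voxel series are averaged within each of the R atlas regions (R = 116 at
full scale, giving R(R−1)/2 = 6670 upper-triangle features). The regional
series are residualised by OLS against the nuisance design: six motion
series, the global mean, CSF and white-matter series, first-order backward
differences (leading element zero) of the global/CSF/WM columns only, and
an intercept. Motion columns receive no derivative terms. All-zero or
constant nuisance columns are dropped (they duplicate the intercept); a
rank-deficient design is an error naming the collinear columns. Raw Pearson
correlations (no Fisher z) between residual series form the FC matrix; the
feature vector enumerates the strict upper triangle row-major. Regional
means are extracted from the detrended + filtered data — whether filtering
should precede extraction is genuinely ambiguous in this analysis family,
and this ordering is the package's documented choice.

## Sparse-representation feature selection

ALFF features are first reduced univariately (top 4000 by |two-sample t|
for classification, by |Pearson r| with the score for prediction; ties
break toward the lower index, and degenerate features score 0). The FC
block (6670 features) skips pre-reduction. The core selector then runs
`l0 = 200` bootstrap repeats: each draws `L = round(0.3 · M0)` distinct
subject rows without replacement and solves the basis-pursuit problem
min ‖x‖₁ s.t. `A_k x = y_k`, converted to a standard LP by the split
x = u − v (solved with HiGHS; constraint residual tolerance 1e-6).
Absolute coefficients are summed across repeats into a weight vector
(sum vs. mean is ranking-invariant), and the top 500 features per modality
are selected, ties toward the lower index. Repeats whose subsample yields
an infeasible system are redrawn up to 5 times. The equality constraint is
enforced exactly (no noise-tolerant variant): the selection statistic is
the magnitude of minimum-L1 interpolators, not a regression fit.

## LOOCV drivers

`GroupClassifier.fit()` and `SymptomPredictor.fit()` run a fold per
subject. In each fold the held-out subject is excluded from ranking,
sparse selection, and training; selected ALFF then FC features are
concatenated (1000-dimensional at full scale), z-scored using training-fold
statistics (applied unchanged to the test vector; standardisation is this
package's choice — zero-variance features get unit scale), and fed to
`SVC(kernel="linear", C=1)` or `SVR(kernel="linear", C=1, epsilon=0.1)`.
Hyperparameters are exposed in the config; no nested tuning is done.
Labels are +1 (survivor) / −1 (control). Classification reports accuracy,
sensitivity (survivor recall) and specificity (control recall); prediction
reports Pearson r and MSE between predicted and actual scores at Time 1,
at Time 2 (the fold's Time-1 model applied to the held-out subject's
Time-2 features whenever that session exists), and for the change, which
is computed by applying the model's linear part to the Time1 − Time2
feature difference — identical, for a linear model, to the difference of
the two predictions. Per-fold selection RNG is derived from
(master seed, fold index) so runs are reproducible and restartable.

## Permutation inference

Each permutation shuffles the labels (or scores) and reruns the complete
LOOCV including feature selection. The p-value defaults to the add-one
form (k+1)/(n_perm+1), which cannot be zero and is exact under
exchangeability; the plain proportion is available via `plain_p=True`.
For informative-feature identification, each fold's absolute SVR weights
per modality are min-max normalised to [0, 1] (a fold with all-equal
weights maps to all ones), scattered into a full-length map with zeros for
unselected features, and averaged over folds. The per-permutation maximum
of the averaged map forms the null; the FWE threshold is the (1 − α)
empirical quantile with "higher" interpolation (conservative). Thresholds
are computed per modality. Post-hoc, flagged features are correlated with
the scores (or feature changes with score changes) and classed as
significant-positive / significant-negative / non-significant at p < 0.05.

A note on null behaviour: LOOCV with in-fold feature selection on
label-balanced null data is *pessimistically* biased — in each fold the
held-out subject's class is the training minority, so null accuracies
concentrate below 50 %. This is a well-known artifact, it does not
invalidate the permutation test (observed and null statistics share the
bias, so exchangeability and p-value calibration hold — verified by
simulation), but raw null accuracies should not be read as "chance = 50 %".

## Synthetic cohorts

The generator emulates the data model the analysis assumes. Each voxel
series is `amp · (√0.5 · private + √0.5 · regional)` + linear drift +
white noise, where private and regional signals are unit-variance sums of
12 random-phase sinusoids with frequencies uniform in the band (variance-
normalised so amplitude — hence ALFF — is controlled exactly). Regions
share a cohort-wide latent (loading² = 0.2) for baseline inter-regional
correlation. A subject-level severity variable `m = 1{survivor} + 0.5 z`,
`z ~ N(0,1)` for survivors, shifts the amplitude of the informative voxels
(`amp = 1 + alff_effect · gain · m`) and the loading of an edge-specific
shared series on informative region pairs
(`λ = 0.3 + fc_effect · gain · m`), with per-feature gains ~ U(0.8, 1.2)
so planted features are not collinear. SAS/SDS scores are a fixed linear
function of the planted feature values plus Gaussian noise; the weights
are scaled so the Time-1 survivor moments match the study population
(SAS 48.4 ± 11.4, SDS 46.8 ± 10.8), and Time-2 sessions (a follow-up
subset) regenerate features at `z₂ = z₁ + δ`, `δ ~ N(−1, 0.6)`, with a
score-specific intercept shift so Time-2 means land at 34.1 / 37.7 —
feature change and score change therefore remain coupled and change
prediction is learnable. Nuisance series are six smoothed random-walk
motion channels plus global/CSF/WM as noisy mixtures of the latent
signals, so nuisance regression is non-trivial. Geometry, scanner
artifacts, motion spikes and spatial smoothness are deliberately absent:
passing tests demonstrate the statistical machinery, not robustness to
real-scanner structure, and the true joint distribution of real symptom
scores is unknown beyond the matched moments.

Default cohort constants: 44 survivors + 44 controls at Time 1, 22
follow-ups, 200 volumes at TR = 2 s, 116 regions; the voxel count defaults
to a reduced 2000 (the pipeline is voxel-count-agnostic).

## Reduced problem sizes

The test suite and `scripts/acceptance.py` run the same code at sizes a
single CPU handles comfortably, chosen once as part of the study design:

* high-SNR end-to-end runs: 20 + 20 subjects, 2000 voxels, 30 regions,
  `alff_effect = 1.5`, `fc_effect = 1.0`, `noise_sd = 0.3`, noiseless
  scores; selection at init 500 → 100 + 100 with `l0 = 50`;
* null-calibration runs: 5 + 5 subjects, 40 voxels, 6 regions, 60 volumes,
  all effects zero, `l0 = 4`, 99 permutations per cohort, 20 cohorts;
* FWE-control runs: 8 survivors, null scores, 19 permutations, 20
  repetitions per modality;
* planted-support recovery: M0 = 60, K0 = 100, 5-sparse, noiseless,
  `l0 = 200`, `L = 18`.

Full-scale parameters (4000/500/500, `l0 = 200`, 1000 permutations) remain
the config defaults.

## Known limitations

* The LP is solved exactly per repeat; at full scale (88 folds × 200
  repeats × 2 modalities) a classification LOOCV is minutes-to-hours of
  CPU, and a 1000-permutation test multiplies that — the reduced `l0` and
  permutation counts exist for this reason and are jointly configurable.
* The equality-constrained selector is noise-intolerant by construction;
  heavy measurement noise degrades support recovery gracefully (weights
  spread) but no noise-aware variant (e.g. basis-pursuit denoising) is
  provided.
* Whether Time-2 transfer should pool per-fold models or refit on all
  Time-1 survivors is ambiguous; per-fold pooling is implemented.
* `correlate_informative` reports raw two-sided p-values at α = 0.05 with
  no multiple-comparison correction (the FWE step already restricted the
  feature set).
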