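# Methods

`prestim` reimplements, as a tested library, a multivariate single-trial
analysis that predicts whether a threshold-level electrical stimulus will be
reported as painful from the EEG recorded *before* the stimulus. Because no
public recordings exist for this paradigm, the package pairs the analysis
with a synthetic cohort generator that plants the statistical structure the
analysis is designed to detect, so every stage can be validated end to end
at desk scale.

## The analysis pipeline

**Epoching and windows.** Continuous recordings are cut into 4-s epochs
(−2 s to +2 s around stimulus onset). All sample arithmetic is 0-based with
half-open `[start, end)` windows; a window of duration `T` at rate `fs`
contains `rint(T * fs)` samples (round-half-even). Two analysis windows are
used: pre-stimulus −1500…−250 ms (312 samples at 250 Hz) and post-stimulus
0…1000 ms (250 samples).

**Artifact handling.** Three per-trial metrics are z-scored across trials:
1–15 Hz band power (ocular proxy), 100–120 Hz band power (muscle proxy) —
both computed as zero-phase 4th-order Butterworth bandpass, per-channel
variance, summed over channels — and the maximum absolute successive-sample
difference over channels and samples. A trial whose any metric exceeds a
configurable z-threshold (default 4) is removed in its entirety. The
threshold replaces an interactive per-dataset choice in the original
procedure; a fixed scalar keeps runs reproducible. Whether the original
metrics were accumulated over channels before or after z-scoring is not
documented anywhere we could find; we summarize per trial first, then
z-score.

**Condition split and balancing.** Ratings use a 0–100 visual analog scale
whose midpoint (50, the pain threshold) cannot be selected; > 50 is pain,
< 50 no-pain. Classes are balanced by sorting trials by rating and taking
equal numbers from both ends of the list — the `m` lowest-rated no-pain and
`m` highest-rated pain trials, `m = min(class counts)`. Ties are broken by
original trial order (stable sort). The procedure is idempotent and keeps
the most confidently-rated trials.

**Spectral features.** Each windowed trial/channel is mean-removed, tapered
with 9 DPSS tapers at ±4 Hz half-bandwidth, and transformed by evaluating
the tapered DFT *exactly* on an integer 1-Hz grid from 4 to 120 Hz (117
features per channel); power is the taper-average of the squared magnitude
divided by the sampling rate. The grid is evaluated directly (not read off
FFT bins), so window length and grid are decoupled. For the post-stimulus
window (NW = 4) nine tapers exceed the well-concentrated count
round(2NW−1) = 7; the request is honored with a logged warning, trading
extra variance reduction for leakage. Power is averaged over the window —
pre-stimulus states are not time-locked, so no time-resolved output is
kept. Named bands: theta 4–7, alpha 8–12, beta 13–24, low gamma 30–59,
high gamma 60–120 Hz; 25–29 Hz belongs to no band and is excluded from band
attribution but retained in full-spectrum decoding.

**Decoding.** Per subject, a linear soft-margin SVM (C = 1) with stratified
five-fold cross-validation on flattened channel × frequency features.
Standardization (x − mean)/SD is fitted per fold on the training portion
only (default; a `global` mode exists because the original one-line
description does not resolve the question). Accuracy is pooled over
held-out folds and tested against chance with the exact one-sided binomial
tail P[X ≥ k], X ~ Bin(n, 0.5). The weight map is the fold-mean linear
coefficient vector reshaped to channels × frequencies, signed so positive
weights favor the pain class. Weights are raw discriminant coefficients,
not activation patterns; see "Limitations" for what that implies.

**Group inference.**
* *Permutation test*: condition labels are permuted within each subject and
  the full per-subject decoding (identical settings, fresh fold seeds) is
  rerun; the group-mean accuracy per iteration forms the null. The p-value
  uses the add-one rule (1 + #{null ≥ observed}) / (1 + n_iterations) and
  is never zero. The original description of the permutation construction
  is ambiguous; within-subject label exchange is the standard valid null
  under exchangeability. Default 500 iterations (3300 mirrors the original
  count). The pipeline driver permutes the headline analysis (pre-stimulus,
  full spectrum); `permutation_null` can be pointed at any window/range
  combination directly.
* *Band attribution*: for each subject passing the individual significance
  filter (binomial p < 0.05), the band containing the global argmax of
  |weight|; ties go to the lower-frequency band and are logged.
* *Lateralization ANOVA*: mixed two-way ANOVA of per-subject mean
  high-gamma weights at C5 and C6 (electrode within-subject, stimulation
  site between-subject), computed from the sums-of-squares decomposition;
  the site × electrode interaction has df (1, N−2). A zero within-cell
  error with a nonzero interaction returns F = ∞, p = 0 explicitly. For a
  two-level within factor the interaction F equals the squared two-sample
  t on C6−C5 difference scores, which the tests exploit as an oracle.
* *Correlations*: Pearson r (two-sided t-based p, Fisher 95% CI) across
  subjects for pre- vs post-stimulus accuracies and for mean 60–120 Hz
  power at FCz; per-frequency coupling uses a Bonferroni threshold
  α / n_frequencies (0.05 / 117 on the default grid).
* *Trial-series autocorrelation*: sample acf of the per-trial pre-stimulus
  FCz high-gamma power at lags 1–20, flagged where |acf| > 1.96/√N. The
  series uses all artifact-clean trials in chronological order (balancing
  would break the trial sequence). FCz is the default channel, matching
  the univariate power analyses; it is configurable.

## The synthetic cohort generator

Each subject is a continuous multichannel recording at 250 Hz on a montage
that must contain FCz, Cz, C5 and C6 (default: a 60-channel extended 10–20
subset; a 16-channel subset is provided for desk-scale work). Stimuli are
spaced 5.5 s apart (4-s epoch plus rating time), 2 × n_trials_per_condition
events per subject.

**Background.** Gaussian noise with power spectral density ∝ 1/f^α above
1 Hz (α = `background_exponent`, default 1.0), flat below, scaled to 8 µV
broadband RMS. The log–log PSD slope over 4–120 Hz recovers −α within ±0.2.

**Latent state and report.** A per-trial scalar state g_t follows an AR(1)
with lag-1 coefficient `trial_ar1_phi` (default 0, matching the observed
trial-specificity of the pre-stimulus state) and unit stationary variance.
The report is drawn through a logistic link P(pain) = σ(2 g_t), so the
gamma state genuinely predicts the report rather than being painted on
afterwards. Ratings are class-conditional truncated normals on [0, 50) and
(50, 100]; the underlying location/scale are solved (by a nested
grid/Brent search over the truncated-moment equations) so that the *emitted*
class means equal the behavioral targets (40 and 55.2) exactly; the target
SDs (12 and 6.4) are matched as closely as the truncated-normal family
allows on those supports (≈ 9.0 and ≈ 5.0 at the mean constraint — the
family's supremum). A rating of exactly 50 cannot occur; violations are
resampled, never clipped.

**Gamma bursts.** Both analysis windows receive amplitude-modulated
bandpass-noise bursts (Hann envelope; FIR bandpass) in six narrow sub-bands
tiling 66–102 Hz — broadband high-gamma, not sinusoids, so multitaper
smoothing behaves realistically. Burst amplitude per trial/channel/sub-band
is `base · exp(0.2 · x)` with state `x = u + e·g_t`, u i.i.d. standard
normal. The loading `e` is solved from the logistic-link conditional
moments (by quadrature) so that the standardized pain/no-pain difference of
x equals the configured target exactly: `effect_size_d` (default 0.8) at
the fronto-central focus (FCz, Cz, FC1, FC2), half that on a neighbor ring,
and a smaller randomly-signed projection elsewhere — how a cortical source
projects to distant electrodes varies across heads. The lateral central
pair carries the site effect: +`lateralization_delta` contralateral to the
stimulated hand, −`lateralization_delta` ipsilateral (default 0.4 d). The
class effect loads on a small subject-specific subset of sub-bands,
reflecting individual gamma peak frequency variability; all sub-bands carry
bursts regardless, so the effect-free sub-bands are spectrally
indistinguishable at the power level.

**Pre/post coupling.** Subject-level pre- and post-stimulus log base
amplitudes are a bivariate normal pair with correlation
`pre_post_coupling_rho` (default 0.85), producing the across-subject
coupling of mean high-gamma power between windows; with a 0.15 log-SD the
lognormal attenuation of the power-scale Pearson r is below 1%, and the
power-scale estimate stays close to its normal-theory sampling behavior.

**Free parameters.** The source study does not report per-trial gamma
effect sizes or SNRs, so burst amplitude (18 µV pre / 20 µV post at
envelope peak vs 8 µV broadband background), modulation depth (0.2 log-SD)
and the number of effect sub-bands are free constants. They were fixed once
to place the simulated cohorts in the study's *observed* operating regime —
group decoding accuracy near 0.68, roughly three quarters of subjects
individually significant, and the large majority of significant subjects
showing their maximal weight in the high-gamma band — and are module
constants, not config fields.

**Ground truth.** g_t, the class draws, the per-channel effect targets and
all burst amplitudes are stored under `ground_truth` in the recording
container for recovery tests; no pipeline stage reads them.

## Numerical choices

* Exact binomial tail via the regularized incomplete beta (scipy's
  `binom.sf`); agrees with exact rational summation to < 1e−12 up to
  n = 200.
* DPSS tapers from scipy with unit-energy normalization; taper-count
  warning threshold round(2NW) − 1.
* The multitaper transform chunks trials to bound the
  (trials × channels × tapers × frequencies) intermediate near 160 MB.
* Fold seeds are derived by hashing (base seed, subject, window, range), so
  every decoding is reproducible independently of execution order.
* JSON outputs are written with sorted keys and atomic rename; reruns with
  the same config are byte-identical.
* Weight maps use sklearn's convention that `coef_` points toward the
  positive class; labels are encoded with pain = 1.

## What the synthetic cohorts do and do not show

The generator reproduces the *statistical* structure the analysis assumes:
a latent pre-stimulus gamma state that drives the report, fronto-central
topography with site-dependent C5/C6 asymmetry, pre/post coupling confined
to the gamma range, and near-threshold rating distributions. It does not
emulate volume-conducted field patterns from a realistic head model, ocular
or muscular artifact morphology (beyond what the artifact metrics need),
line noise, electrode drift, or non-stationarities within a session.
Passing recovery tests therefore shows the pipeline is correct and
well-calibrated — not that real pre-stimulus EEG contains such signals;
that evidence belongs to the source study.

## Limitations

* Raw discriminant weights are reported, as in the source analysis. On
  data whose class signal rides one globally shared latent factor, the
  soft-margin dual solution partially whitens that factor and the weight
  map can understate it badly — we observed exactly this regime in early
  generator drafts. Per-subject idiosyncratic effect structure (as planted
  here, and as the source study's within-gamma variability suggests) is
  what makes raw weights interpretable. Haufe-style activation patterns
  would remove the caveat but are deliberately out of scope.
* The permutation test reruns the full decoding per iteration; its cost is
  n_iterations × n_subjects × k_folds SVM fits. Desk-scale defaults
  (500 iterations, ≤ 33 subjects, 16 channels) run in minutes on one core.
* EDF export is not provided (no EDF writer in the dependency set); EDF and
  BrainVision reading are available behind the optional `eeg` extra.
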