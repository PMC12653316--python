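# Methods

## Problem

Resting-state quantitative EEG summarizes cortical dynamics with band
power ratios: the theta-alpha ratio (TAR = relative theta power /
relative alpha power) and the theta-beta ratio (TBR = theta / beta).
Elevated values indicate cortical slowing, a candidate marker of
amyloid-related neurodegeneration.  This package implements the full
chain from raw multichannel EEG to lobar log ratios and their
covariate-adjusted linear association with plasma oligomeric
amyloid-beta (OAb, ng/mL), together with a synthetic cohort generator
that serves as ground truth because the clinical data this design
targets are not public.

## Processing model

Fixed order, identical parameters for every subject:

1. **Average reference.** Each channel minus the instantaneous mean of
   all 19 channels (10-20 montage Fp1...O2).  Idempotent and linear.
2. **Bandpass 0.5-100 Hz.** 4th-order Butterworth applied
   forward-backward (zero phase), even (reflective) padding of at least
   three time constants of the low corner to contain edge transients.
3. **Epoching.** Consecutive non-overlapping 4 s epochs; trailing
   partial segments dropped; epochs never span a trial boundary when
   the recording is a concatenation of trials.
4. **Artifact rejection.** An epoch is rejected iff any channel's
   peak-to-peak amplitude exceeds 100 uV.  This deterministic rule
   replaces manual/ICA cleaning, which cannot be reproduced without the
   original operator; `reject_artifacts` accepts a plug-in rejector for
   ICA-based alternatives.
5. **Minimum clean data.** A subject x condition enters the analysis
   only with >= 60 s of retained epochs (boundary inclusive, i.e. 15
   epochs of 4 s suffice).  Exclusion is per condition.
6. **Welch PSD.** Per retained epoch: 2 s Hamming windows, 50% overlap
   (three segments per 4 s epoch), mean detrend, one-sided density
   scaling; epoch estimates averaged.  Frequency resolution 0.5 Hz.
7. **Relative band power.** Band power is the sum of PSD bins whose
   center frequency lies in [f_low, f_high) — half-open, so 8 Hz
   belongs to alpha, not theta — divided by the same sum over 0.5-100
   Hz (endpoints included).  Bands: delta [0.5, 4), theta [4, 8),
   alpha [8, 13), beta [13, 30); the 30-100 Hz residual counts in the
   denominator only.
8. **Lobar ratios.** Per lobe (frontal, central, parietal, occipital,
   temporal), relative band powers are averaged over the lobe's
   electrodes first, then TAR = theta/alpha and TBR = theta/beta are
   formed and log-transformed (base 10 by default; base e available).
   The alternative order (per-channel ratios, then averaged) is exposed
   via `per_channel_first` for sensitivity analysis.

## Statistical layer

Subjects are dichotomized at the 0.78 ng/mL OAb cutoff (boundary counts
as high).  Shapiro-Wilk on each log-ratio cell is a logged diagnostic,
not a gate.  Group contrasts use Student's pooled-variance two-sample
t-tests (Welch variant by config) with Cohen's d = (low - high) /
pooled SD.  Pearson correlations and ordinary least squares relate OAb
to each lobar log ratio: the unadjusted model is intercept + OAb; the
adjusted model adds age, education years, and K-MMSE.  Coefficients are
reported raw (log-ratio per ng/mL) with classical SEs; a standardized
variant (beta x sd(x)/sd(y)) is emitted alongside because the raw/
standardized convention is genuinely ambiguous in this literature.
Education-stratified models (<= 6, 7-12, > 12 years) adjust for age and
K-MMSE only — education is the stratification variable; empty strata
are reported with an explicit flag.  Bonferroni correction uses a
family of 10 (5 lobes x 2 indices) within each condition by default
(pooled m = 20 by config); nominal p values are always kept alongside.
Missing data are handled complete-case per model with `n_used`
reported.

## Synthetic cohort

**Metadata.** Age ~ N(74.87, 8.52) clipped to [55, 95]; 70.7% female;
education drawn from a four-level mixture (below elementary 24%, middle
27%, high 16%, college 33%) mapped to years; K-MMSE ~ N(23.4, 4.85)
rounded and clipped to [0, 30]; OAb lognormal with median at the 0.78
cutoff (log-sd 0.55, giving roughly 0.2-2.5 ng/mL and a near-even
high/low split).  Covariates are independent of OAb by default;
`age_coupling`/`kmmse_coupling` switch confounding on for testing
covariate adjustment.

**Signal.** Per channel: a 1/f pink background over 0.5-100 Hz plus
independent band-limited Gaussian oscillators (delta, theta, alpha,
beta) drawn in the frequency domain and normalized to exact per-trial
variances, plus optional artifact transients.  Oscillators occupy band
interiors (e.g. theta 4.25-7.75 Hz) so window leakage across band
edges is negligible.  Defaults: ten 30 s trials per condition at
250 Hz.

**Planted coupling.** The expected lobar log10 TBR is set directly:

    log10 TBR = level(lobe) + slope(lobe, cond) * (oab - E[oab]) + eps,
    eps ~ N(0, ratio_noise_sd),  ratio_noise_sd = 0.33 by default.

Theta and beta band-power targets are placed symmetrically around a
fixed geometric mean (2.5 uV^2), so the ratio is exact while total
power stays bounded; alpha follows from a per-lobe TAR level (own noise
sd 0.25), lower by 0.2 log10 units with eyes closed so alpha power is
strictly larger in EC than EO (enforced per subject).  Per-lobe levels
are calibrated to the magnitudes reported for elderly cohorts (log10
TBR 0.55-0.77, log10 TAR -0.15-0.21); they are a plausible operating
point, not a reconstruction of any particular cohort.  Because the
average reference mixes channels, per-channel band-power targets are
pre-multiplied by the inverse of the induced linear map on powers
(p' = (1 - 2/N) p + S/N^2), making the planted ratios exact after
re-referencing; the pink background's band share is computed from its
1/f integral and subtracted from the oscillator budget.

**Amplitude budget.** Spectral scales (geomean 2.5 uV^2, delta 3,
background 1.5) keep a typical epoch's peak-to-peak near 35 uV so that
clean data essentially never cross the 100 uV rejection threshold even
at +/-3 sigma ratio-noise draws; subjects in the extreme joint tail can
still lose epochs and are then handled by the ordinary exclusion rule.

**Artifacts.** Blinks: biphasic Gaussian-derivative deflections, peak
400 uV, frontal-polar topography with smooth falloff, default 3/min.
EMG: Hann-windowed 35-95 Hz bursts (0.5 s, 45 uV RMS) on a temporal
channel, default 2/min.  These rates leave ~45 artifact-free epochs of
70 per 5 min condition.  Every injected event is logged with its
parameters, giving tests exact ground truth.

**Determinism.** Every stream derives from
(master seed, CRC-32(subject id), condition, trial), so recordings are
bit-reproducible and cohorts extend without reshuffling existing
subjects.

**What the generator does not emulate.** Volume conduction and
inter-channel correlation (channels are independent before
referencing), non-stationarity within trials, line noise, real blink
kinematics, assay measurement error, and any nonlinear OAb-EEG
relationship.  Passing tests therefore demonstrate correctness of the
pipeline's estimators under the stated generative model, not clinical
validity on real recordings.

## Simulation studies and problem sizes

* **Planted-slope recovery**: 100 replicate cohorts of n = 174 with a
  parietal eyes-closed slope of -0.06 log10-TBR per ng/mL and residual
  sd 0.33, run through the full signal pipeline at one 64 s trial per
  condition (16 epochs; the smallest geometry satisfying the 60 s
  min-clean rule).  Checks: adjusted estimate within 2 reported SEs of
  the planted slope in >= 95/100 replicates; replicate-mean within
  0.01.  Note the first check's nominal coverage is ~95.5%, so it sits
  close to its own threshold by construction.
* **Type-I calibration**: 200 replicate null cohorts at the ratio level
  (`simulate_ratio_records`, the generating equation without signal
  synthesis — the statistics are under test there, not spectral
  estimation); the nominal rejection rate must lie in the exact
  binomial 95% interval around 0.05 and Bonferroni must control the
  family-wise error across the 10-cell grid.
* The acceptance script repeats the recovery with 40 replicates and
  reports the same quantities.

## Numerical choices

* Butterworth order 4; `sosfiltfilt` with even padding,
  padlen = 3 fs / (2 pi f_low).
* Bin-membership tolerances of 1e-9 avoid floating-point edge flips at
  band boundaries.
* Degenerate inputs raise: zero total spectral power, non-positive
  ratios, constant vectors in Shapiro-Wilk/Pearson, rank-deficient OLS
  designs (the error names the collinear columns), groups under 2
  observations.
* EDF output quantizes to 16 bits over a symmetric physical range;
  round-trip error is bounded by the quantization step.

## Limitations

* The peak-to-peak rule is a surrogate for the original manual + ICA
  cleaning; on real data it will miss low-amplitude artifacts.
* Lobar averaging assumes all electrodes of a lobe are equally
  informative (unweighted mean).
* The planted linear OAb coupling is on log TBR only; TAR carries no
  planted slope by default.
* No interaction (moderation) tests of education x OAb are provided —
  stratified models are descriptive, mirroring the analysis plan this
  package implements.
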