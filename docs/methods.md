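# Methods

`resteeg` implements a complete low-density (8-channel) resting-state
EEG analysis for discriminating Alzheimer's disease (AD) from healthy
controls (HC), together with a synthetic cohort generator that carries
the statistical structure the analysis is designed to detect. This note
documents the models, the numerical choices, and what the synthetic
data does and does not establish.

## Analysis chain

### Preprocessing

Raw multichannel recordings (microvolts) pass through, in order:

1. **Zero-phase band-pass 0.1–45 Hz** — order-4 Butterworth applied
   forward–backward (`sosfiltfilt`), split into a low-pass and a
   high-pass stage. The 0.1 Hz high-pass has an impulse response of
   roughly 1/0.1 = 10 s, so its stage is padded with ~2/lo seconds of
   reflected signal; without this, filtfilt edge transients leak far
   into the recording. Attenuation is ≥ 20 dB one octave outside the
   band; at 50 Hz the order-4 response passes ~30% amplitude (a
   line-noise notch is not part of the chain; the synthetic data
   contains no line noise).
2. **Polyphase resampling to 250 Hz** (downsampling only).
3. **Average reference** — subtract the instantaneous across-channel
   mean; per-sample linear, hence commutes with epoching.
4. **Epoching into consecutive non-overlapping 4-s segments** (1000
   samples at 250 Hz); the trailing remainder is dropped. A 300-s
   block yields 75 epochs.
5. **Artifact rejection** — an epoch is dropped if any channel exceeds
   ±100 µV or any channel's within-epoch SD falls below 0.01 µV
   (flat-channel guard). This amplitude/flatness rule is a deliberately
   simple surrogate for wavelet-ICA-based artifact pipelines, which are
   out of scope; both thresholds are configurable. Rejection is
   idempotent and order-preserving.
6. **Middle retention** — of the M surviving epochs, keep the 30
   contiguous-by-survivor-index epochs starting at floor((M−30)/2)
   (2 min of data), equalizing data quantity across subjects and
   conditions. Fewer than 30 survivors excludes the subject-condition;
   the floor rule is a deterministic tie-break for odd remainders.

### Power spectrum

The 30 retained epochs are concatenated and mirror-padded at both ends
with a reflected copy of the first/last epoch. A 250-sample (1 s)
Hamming window slides in 100-sample (0.4 s) steps; each window gets a
1024-point FFT (bin width 250/1024 ≈ 0.244 Hz). Only windows whose
centers fall inside the unpadded span enter the average, so the padding
conditions the edge windows without biasing the estimate. Density
normalization divides by fs·Σw², which makes the integral of the PSD
equal the (window-weighted) signal variance; a unit-amplitude sinusoid
integrates to 0.5 µV².

Band powers integrate the PSD by the trapezoidal rule over half-open
intervals [f_lo, f_hi) — delta 0.1–4, theta 4–8, alpha 8–13, beta
13–30 Hz share endpoints, and the half-open convention prevents double
counting. Relative power divides by the 1–45 Hz integral as the
denominator convention; because delta starts at 0.1 Hz the four
relative powers need not sum to 1. Gamma is excluded (muscle
contamination dominates above 30 Hz in scalp EEG).

**Alpha peak frequency** is estimated on the all-channel mean spectrum:
the maximum bin in 8–13 Hz refined by 3-point parabolic interpolation
(clamped to ±half a bin). The estimate carries a `has_peak` flag that
is false when the maximum sits on the range boundary or lacks
prominence (max < 1.10 × the range median); a flat or monotone spectrum
has no credible alpha peak and the prominence guard encodes that. The
1.10 factor sits above the chi-squared fluctuation band of the averaged
estimator (hundreds of windows × channels keep per-bin noise to a few
percent) while any real oscillatory peak exceeds it by an order of
magnitude.

**Theta/beta ratio** (power-to-power frequency coupling) is relative
theta over relative beta per channel; values above 1 indicate energy
concentrated below the alpha band, the shift expected with cortical
slowing.

### Phase synchrony

**PLV.** Each epoch is band-pass filtered (order-4 zero-phase
Butterworth at the band edges), mirror-padded by a full epoch length on
both sides, and Hilbert-transformed; the padding is discarded. Per
epoch, PLV = |mean over samples of exp(j·Δφ(t))|, then averaged over
the 30 epochs (resting data has no stimulus-locked trials, so the
averaging index is the epoch, and the magnitude is taken per epoch over
time). PLV is amplitude-blind and invariant to constant phase offsets
— including zero offset, which makes it sensitive to volume conduction.
Mirror padding leaves ~1% phase ripple through the epoch interior (the
reflection point is a derivative discontinuity), so PLV of a pure
constant-offset tone measures ~0.99 rather than 1.0 exactly.

**wPLI.** The retained epochs are concatenated (windows spanning epoch
boundaries are kept; boundary transients are negligible after
zero-phase filtering) and cut into 10-s Hamming windows with 50%
overlap — 23 windows for 120 s. Each window's FFT has exactly 0.1 Hz
bin spacing; cross-spectra S_xy = conj(X)·Y per window. Per bin,
wPLI = |mean_t Im S_xy| / mean_t |Im S_xy|, with 0/0 defined as 0 (no
evidence of lagged synchrony); the band value is the unweighted mean
over the band's bins. The numerator/denominator inequality guarantees
wPLI ∈ [0, 1]. Because only the imaginary cross-spectrum enters,
zero-lag coupling is invisible and near-zero-lag noise is down-weighted
by its own magnitude.

**Sampling floors.** Both estimators have positive nulls: with 30 × 4-s
epochs, band-limited phases decorrelate over ~1/bandwidth ≈ 0.25 s,
leaving ~16 effective phase samples per epoch and a PLV null near
0.25–0.28; wPLI's null scales as 1/√n_eff with 50%-overlap windows
giving n_eff ≈ n/2, i.e. ≈ 0.2 at 120 s. Group comparisons are
unaffected (both groups share the floor), but absolute values must be
read against these floors, and demonstrations that wPLI rejects
zero-lag coupling below 0.1 need ≥ ~30 min of signal.

### Group statistics

Each feature is residualized by ordinary least squares on [intercept,
age, sex (F=1), education (ordinal 1–5 treated as numeric — a 5-level
ordered scale at small n)] pooled over both groups; group membership is
deliberately excluded from the design so group differences survive in
the residuals. A collinear covariate is dropped with a warning.
Residuals are compared with the two-sided Mann–Whitney U test
(midranks; exact by enumeration when n1+n2 ≤ 16 and tie-free, else the
normal approximation with tie and continuity corrections). Bonferroni
correction runs within a family, by default one (metric, band,
condition) block — e.g. the 28 pairs of one connectivity matrix — with
the family size recorded per result; the family definition is
configurable (`metric_band_condition`, `metric_condition`, `global`)
because no single convention is canonical. EC−EO difference features
are built by subtracting each subject's EO value from the EC value and
form their own condition block.

### Classification

Two-round screening: round 1 keeps features with Mann–Whitney p < 0.05
between groups; round 2 keeps survivors whose *single-feature*
stratified 10-fold linear-SVM accuracy reaches 70%. The surviving set
feeds a linear-kernel SVM (C = 1, configurable) under stratified
10-fold CV, with standardization fitted inside each training fold to
avoid scale leakage. Metrics pool the held-out predictions: accuracy,
sensitivity (AD positive), specificity, and AUC from the pooled
decision values (threshold sweep + trapezoid; AUC equals U/(n1·n2) on
tie-free scores). Screening on the full dataset before CV follows the
described protocol and is optimistically biased; a nested mode
(screening refit inside each training fold) is available for honest
error estimates. The paradigm comparison builds an EC-only pool and a
combined pool (screened EC features ∪ screened EC−EO features; if no
difference feature survives, the combined paradigm degenerates to
EC-only). A default random-forest comparator (500 trees, untuned) runs
under the same CV protocol.

## Synthetic cohort generator

Each channel is the sum of:

* **1/f background** — spectrally shaped Gaussian noise with PSD ∝
  1/f^1, 5 µV RMS broadband;
* **oscillators** — cos of a random-walk-perturbed phase with Lorentzian
  FWHM equal to the configured bandwidth (theta 6 Hz / 1.5 Hz FWHM,
  3 µV; alpha at the subject's peak / 1.0 Hz, 10 µV; beta 20 Hz /
  4 Hz, 2 µV). Each rendered component is band-limited to its nominal
  band with a zero-phase filter applied identically across channels:
  the random-walk model's heavy Lorentzian tails would otherwise leak
  alpha energy into the theta band (real rhythm peaks have no such
  tails), degrading theta-phase estimation;
* per-subject lognormal amplitude jitter (σ = 0.1) and a per-subject
  alpha peak ~ Normal(10.09, 0.4) Hz.

**Group effects (eyes-closed only, by default):** AD alpha amplitude
×0.7 and peak shifted −0.33 Hz; theta coupling injected by mixing each
designated channel's theta with a single shared phase-diffusing source;
AD theta amplitude ×1.6 at F3, F4, C4. Eyes-open recordings attenuate
alpha by ×0.5 in everyone and carry no group effects, reproducing the
alpha-reactivity contrast that makes EC−EO features informative.

**Coupling calibration.** The mixing weight w (channel theta =
w·shared + √(1−w²)·independent) maps nonlinearly to measured PLV, so a
lookup table is computed once per parameter family: for a grid of
weights, two full synthetic channels are rendered and their theta PLV
measured with the package's own estimator over 120 s; the monotone
curve is inverted by interpolation. Targets above the attainable
ceiling (~0.65 under the default noise levels) saturate at w = 1.
Pairs meant to be wPLI-visible receive the shared source with a π/4
phase offset propagated through the pair graph; zero-offset pairs are
PLV-visible only. Because the average reference subtracts the
across-channel mean, a shared source carried near-in-phase by several
channels would be partially stripped; offsets are therefore flipped by
π where free (a π flip is invisible to PLV, and wPLI's absolute values
cancel sign flips) to minimize the source's common mode.

**Demographics** are drawn to match the target population in
distribution: ages Normal(69.35, 10.08) for AD and Normal(64.17, 10.64)
for HC, floored at 50 (a floor rather than rejection sampling keeps the
group mean difference near its nominal 5.2 years); sex 11:15 / 12:17
and five-level education 4/2/13/2/5 / 5/2/15/3/4 proportions;
handedness all right. No individual subject is replicated.

**Sampling rate.** The generator renders at 250 Hz, the analysis rate:
all synthetic content lives below 45 Hz, so nothing is lost relative to
a 1 kHz acquisition, and the resampling stage is exercised separately
with 1 kHz test inputs.

**Determinism.** A cohort is a pure function of its `CohortSpec`
(including the seed). Subject traits derive from the subject seed
independently of condition; the calibration lookup uses a fixed
internal seed so identical specs give bit-identical cohorts across
processes.

### What the generator does not emulate

Real EEG artifacts (EMG, EOG, electrode pops), line noise,
non-stationarity across the session, volume-conduction mixing of *all*
sources (only the injected theta source is shared), realistic
covariance between demographics and EEG features, and any physiological
AD mechanism. Effect sizes are chosen for comfortable recovery at
n = 26/29 and are configuration, not claims about AD physiology.
Passing the recovery suite therefore shows the estimators and
statistics detect the structure they target at the study's sample
sizes — not that they would perform equally on clinical recordings.

## Problem sizes used by tests and the acceptance script

Monte-Carlo ensembles are sized for a single CPU: effect recovery and
paradigm comparison use 12 seeded default cohorts (26 AD / 29 HC,
300 s per condition) in the test suite and 6 in the acceptance script;
null calibration uses 20 (tests) / 8 (script) cohorts of 10 vs 10;
volume-conduction checks use 50 (tests) / 12 (script) seeds of 1800-s
pairs; spectral calibration uses 50 / 25 noise seeds. Thresholds are
the design targets (recovery in ≥ 80% of seeds, combined paradigm
non-inferior in ≥ 60%, uncorrected null flag rate ≤ 7%) regardless of
ensemble size.

## Known limitations

* The EDF writer is minimal (16-bit, 1-s records, integer sampling
  rates, symmetric physical range); BDF/BrainVision/EEGLAB formats and
  annotations are out of scope.
* Artifact rejection is amplitude/flatness only; no ICA, channel
  interpolation or line-noise removal.
* Mirror-padded Hilbert phases carry ~1% interior ripple; PLV values
  saturate near 0.99, not 1.0.
* Pre-CV screening inflates accuracy estimates; use the nested mode for
  unbiased figures.
* Connectivity nulls are positive and size-dependent (see sampling
  floors above); compare values only across identical epoch/window
  counts.
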