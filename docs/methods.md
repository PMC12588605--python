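# Methods

`rhythmoscan` implements a complete pipeline for asking whether auditory
perceptual judgements fluctuate rhythmically with the delay between a
reference event (background-noise onset) and a monaural target, together with
the simulation machinery needed to calibrate and validate every statistical
step without any real data.

## Data model and preparation

A trial table holds one row per trial: participant, experiment (`exp1`-`exp4`),
block, trial index, ear (`L`/`R`), condition (`f1`/`f2`; tone frequency or
pitch order), target delay in seconds from noise onset, response
(`opt1`/`opt2`/`none`), correctness, reaction time, stimulus level, and
dual-task flags. Preparation is a fixed chain:

1. `filter_outliers` removes trials with responses outside the task's keys
   (including no response) and reaction times below 0.15 s or above 2.5 s.
   It is the single filtering entry point, applied once, globally, before any
   metric is computed. Per-reason removal counts land in the table metadata.
2. `transform_rt` adds `rt_sqrt = sqrt(rt_s)`; the square-root transform
   symmetrises the right-skewed RT distribution so Gaussian-family models of
   RT are defensible. Single-trial RT analyses use the transformed value.
3. `reference_delays` maps delays to the target-uncertainty window:
   `delay_ref_s = delay_s - 0.3` in [0, 1.2] s. All rhythmicity analyses run
   on this axis.

## Binned signal-detection metrics

Window-relative delays are partitioned into 20 bins of 60 ms (half-open, the
last bin closed at 1.2 s so the full window is covered). Within each bin,
condition `f1` is treated as the signal class and `opt1` as the signal
response; with the log-linear correction (add 0.5 to each cell count, 1 to
each denominator — defined for every count, nearly unbiased at mid-range
rates),

    d' = z(H) - z(FA),   c = -(z(H) + z(FA)) / 2.

The sign convention makes positive `c` a conservative tendency toward `opt2`.
Metrics are computed per ear and for both ears pooled (a pooled computation,
not an average of per-ear values). A bin lacking one condition yields missing
values, handled downstream by interpolation (spectra) or listwise exclusion
(GLMs). With ~35 trials per bin (700 trials), empty cells are essentially
impossible; at ~19 trials per bin per ear they occur occasionally and are the
reason the handling is explicit.

## The three statistical approaches

All three test the same question — is there rhythmicity at any frequency of a
grid — at the group level, assuming a common frequency but *not* a common
phase across participants.

**Spectra.** Each participant's 20-bin series (d', bias, or mean sqrt-RT) is
linearly detrended, zero-padded by 30 points on each side, and the amplitude
spectrum |DFT| taken on the padded grid (step 1/(80x0.06) ~ 0.208 Hz). The
retained band is the set of DFT bins within half a grid step of 1.05-8.1 Hz,
i.e. bins 5-39 (~1.042-8.125 Hz, 35 frequencies); the nominal band edges are
read as rounded descriptions of the outermost retained bins. Amplitude rather
than power is used; the choice cancels in percentile tests because actual and
surrogate data pass through the identical transform. No taper is applied.
The null model is an AR(1) process fitted to each series by least squares on
the demeaned values (coefficient clipped to [-0.99, 0.99] on pathological
short-series fits); surrogates are simulated from the fit, passed through the
same detrend/pad/|DFT| transform, averaged index-wise across participants, and
the group p-value per frequency is the add-one percentile of the actual group
spectrum in that distribution: p = (1 + #{surrogate >= actual}) / (1 + n).

Surrogate initialisation: the reference procedure burns in 2000 samples; the
package also offers (and uses in calibration) an exact stationary start,
x0 ~ N(0, s^2/(1-a^2)), which is the same distribution the burn-in converges
to (a^2000 < 1e-8 within the clipped stationarity region) at 1 % of the cost.
A distributional-equivalence test (KS) covers the two paths.

**Binned / Trials GLMs.** The outcome is modelled per participant as

    y ~ b0 + b1 t + b2 uv(t) + b3 sin(2 pi f t) + b4 cos(2 pi f t),

with `uv(t) = cos(2 pi 0.5 (t - 0.6))` — a slow half-cycle symmetric about the
window midpoint capturing non-rhythmic rise-and-fall (the phase convention is
a package choice; it is configurable in spirit by supplying custom designs).
Predictors are left unstandardised so betas keep interpretable units; vector
strengths are only ever compared like-for-like. The rhythmic effect size is
the vector strength VS = (b3^2 + b4^2)/2, phase-free and quadratic in the
modulation amplitude. The binned approach fits the 20 bin means
(Gaussian/identity) on the grid 1.2-4.0 Hz step 0.1 plus 4.2-8.0 Hz step 0.2
(49 frequencies); the trials approach fits single-trial outcomes — binomial
with logit link for correctness, Gaussian for sqrt-RT — on the grid extended
by 8.8-12.0 Hz step 0.8 (54 frequencies).

Significance per frequency comes from a permutation null: the delay <-> outcome
assignment is shuffled within participant, the model refitted, surrogate
vector strengths averaged index-wise across participants, and the add-one
percentile p computed for the group mean. One permutation stream per
participant is drawn once and reused across grid frequencies (a single
shuffle-then-refit pass, as the scan is one family of tests). Binomial refits
use a batched Newton/IRLS with a small ridge (1e-6) so separation can never
abort a null distribution; a refit stopping at the iteration cap is flagged
and its ridge-stabilised value used. The single-fit API uses statsmodels for
binomial fits and flags separation (|linear predictor| > 15) before falling
back to the ridge fit.

## Calibration of the family-wise false-positive rate

First-level p-values are deliberately not taken at face value: each approach
has different effective multiplicity across its grid, and the AR-surrogate
p-values are additionally biased by parameter estimation (below). Instead the
operating characteristics are measured by simulation. Virtual experiments of
25 participants x 700 trials are drawn from a Gaussian-beta linear model —
per-participant betas from Gaussians with (mean, SD): offset (1, 0.1), linear
slope (0.1, 0.1), u/v (0.1, 0.1), sine and cosine at 4 Hz (0.2, 0.1); trial
outcome = model + Gaussian noise, delays uniform on [0, 1.2] s. Null runs
zero the sine/cosine betas for every participant. Simulated outcomes are
continuous and are analysed with the Gaussian family in all three approaches.

For each approach, the first-level cutoff is the largest value whose
family-wise rate (fraction of null runs with min-over-frequency p <= cutoff)
stays <= 0.05, pooled across noise SDs {2, 4, 6} — and separately for 0.01.
The realised rate is then measured on freshly seeded held-out null runs, so
the reported specificity carries no selection optimism. Sensitivity on effect
runs is reported per noise SD, both as any-frequency detection and as
detection within +-0.3 Hz of the true 4 Hz.

Problem sizes: the package defaults run 200 selection and 100 validation null
runs per noise SD (600 + 300 runs) with 2000 surrogates/permutations per
approach. The reference analysis used 1000 runs per SD and 10,000 surrogates;
the defaults are the package's desk-scale choice, with Monte-Carlo error on a
realised rate of 0.05 of about +-0.013 (one SE at 300 runs). The
surrogate/permutation count is a resolution requirement: attainable cutoffs
are multiples of 1/(n+1), and the family-wise rate moves in steps of roughly
m_eff/(n+1) per cutoff step, with m_eff ~ 20-35 effectively independent
frequencies per grid; n = 2000 keeps that step at ~0.01-0.017 so the selected
cutoff can sit near the target instead of jumping across it. A 0.01 target
needs finer resolution than n = 2000 provides at the trials grid
(floor rate ~ m_eff/(n+1) > 0.01); in that case a sub-floor cutoff is
returned with a warning — reaching 0.01 requires ~10,000 permutations, as in
the reference analysis.

A fast path vectorises the calibration: bin means by `bincount`; a fixed
2-row least-squares projector per frequency yields the sine/cosine betas for
all permutations in one matrix product; AR surrogates use the stationary
initialisation; and one permutation-index matrix is shared across the
simulated participants within a run (drawn fresh per run). Sharing is valid
under the null because participants' data are independent, so vector
strengths under a common permutation remain independent across participants
and the group-mean surrogate distribution is unchanged; the real-data
estimators use independent per-participant streams. The float32 inner
products affect only rank comparisons of vector strengths, orders of
magnitude below any meaningful difference.

## Known miscalibration of first-level AR-surrogate p-values

With AR(1) parameters re-fitted from 20-point series, the surrogate test's
first-level p-values are *not* uniform under an AR null: the small-sample fit
bias (Kendall, ~ -(1+3a)/n) makes surrogates slightly whiter than the data,
and group averaging amplifies the resulting shift (noise shrinks with
sqrt(P), bias does not). This is inherent to the method, grows with cohort
size, and is precisely what the simulation calibration absorbs — it is the
reason the calibrated cutoffs are not 0.05/m. The test-suite therefore checks
uniformity under the procedure's exact null (data and surrogates from the
same known AR process), where it holds, and treats the fitted-parameter case
via the calibrated family-wise rate.

## Prevalence, co-occurrence, contrasts

**Bootstrap prevalence.** Cohorts are resampled with replacement (resample
size = pool size, whatever the pool is); for each resample the group mean and
the index-wise group surrogate distribution are rebuilt from the drawn
participants' precomputed statistics and each frequency re-tested at the
calibrated cutoff. Prevalence is the fraction of resamples significant per
frequency. No refitting happens inside the bootstrap: under participant
exchangeability this is the same computation as a full refit that reuses the
per-participant permutation streams (tested as an exact equality), and agrees
with a fresh-permutation refit within Monte-Carlo error (also tested).
Default 5000 resamples. Prevalence curves from several experiments with
identical grids are combined by an unweighted mean.

**Ear co-occurrence.** Presence of any significant frequency within two
ear/frequency bands (e.g. right ear 1.5-2 Hz vs left ear 5.5-6 Hz) is coded
per resample as paired binary flags; their Pearson correlation with the
two-sided t-approximation p (df = n-2) quantifies whether effects in the two
ears co-occur in the same resampled cohorts. The flags share bootstrap
samples, so the p-value is descriptive rather than an exact test — the same
caveat applies to the reference analysis.

**Condition contrasts.** For paired trial sets (dual-task vs not; median
splits on trial-wise pupil size or fixation stability), each participant's
binned-approach vector strength is computed per condition and frequency;
conditions are compared with paired t-tests per frequency,
Benjamini-Hochberg-corrected across the grid only; bootstrap resampling of
participants gives the prevalence of significant differences. Median splits
are within-participant; ties at the median go to the low half; participants
with fewer than 400 valid trials per half are excluded (the inclusion rule is
read as per-half).

**Eye metrics.** Traces (time, gaze x/y in degrees, pupil, validity) are
epoched at -0.4 to +1.5 s around noise onset; an epoch with any invalid
sample (blink, missing, or gaze beyond +-14 deg on either axis) is rejected
whole. Pupil samples are z-scored within participant over all retained
epochs (a constant pupil yields z = 0 with a warning); per trial, the pupil
value is the mean z and fixation stability the mean of SD(x) and SD(y), both
over [noise onset, target onset]. Participants need >= 600 valid trials.

## Synthetic data

The generator module defines the study conditions end to end:

- **Designs**: exp1-3 are 8 blocks x 190 trials (380 trials per ear x
  condition); exp4 is 16 blocks x 130 trials with the dual task in half the
  blocks (260 per ear x condition x task) and a fixation-dot change in half
  the dual-task trials at a time uniform in [onset + 0.1 s, target]. Delays
  are independent uniform draws on [0.3, 1.5] s; ear x condition cells are
  exactly balanced per session (and per task half in exp4).
- **Observers**: equal-variance Gaussian SDT with symmetric placement,
  P(opt1|f1) = Phi(d'/2 - c), P(opt1|f2) = Phi(-d'/2 - c) — the standard
  convention, since no observer model is prescribed. Sensitivity, criterion
  and RT can each carry additive sinusoidal modulations (target metric, ear
  scope, frequency, amplitude, phase) on the window-relative time axis.
  Lapses (default 2 %) respond uniformly. RTs are generated in sqrt-seconds
  (base 0.75 ~ 0.56 s, drift, rhythm, Gaussian noise SD 0.12, truncated at
  zero) and squared, so the analysis-side transform recovers approximately
  Gaussian residuals.
- **Staircases**: four interleaved 3-down-1-up tracks (ear x condition),
  initial step 4 dB halved at each of the first two reversals to a 1 dB
  floor, stop after 10 reversals, threshold = mean of the last 5 (the
  reversal count to average is prescribed; the step schedule is the package's
  choice). The simulated psychometric function is 0.5 + 0.5 Phi((x - theta)/
  slope), so the staircase converges near the 79.4 % point (0.5^(1/3)).
- **Adaptive difficulty**: accuracy over the last 30 trials above 80 % makes
  the task 4 % harder, below 69 % makes it 4 % easier, tracked per ear x
  condition.
- **Eye traces**: 500 Hz over -0.4 to +1.5 s; gaze = white fixation jitter
  (per-trial SD drawn from a participant-level Gaussian, default mean 0.3
  deg) plus a per-trial linear drift; pupil = moving-average-smoothed noise
  (0.4 s window) plus a per-trial offset; blinks are Poisson-placed missing
  segments (default rate 0.05/s, 0.2 s each). The generator emulates
  fixation-quality statistics, not saccade dynamics — no saccade sequences,
  no pupil light/arousal response, no eyelid dynamics. Tests passing on
  these traces validate the metric and split machinery, not any physiological
  claim.

What the simulated observers do not capture: learning and fatigue trends
beyond a linear drift, sequential dependencies across trials, non-stationary
criterion shifts, and any coupling between eye state and behaviour (the
eye generator is independent of the observer unless composed deliberately).
Passing recovery tests therefore demonstrates that the analyses detect what
they model — not that real data contain such rhythms.

## Numerical choices and degenerate inputs

- Missing bins: linear interpolation over bin centers before detrending
  (spectra; series with > 50 % missing are excluded with a warning), listwise
  row exclusion in GLM fits.
- Extreme SDT rates: log-linear correction keeps d'/c finite at 0 % / 100 %.
- AR(1) on constant series raises a degenerate-fit error; |coefficient| is
  clipped to 0.99 with a warning when a short-series fit leaves the
  stationarity region.
- Add-one p-values everywhere, so p = 0 is impossible and the smallest
  attainable p is 1/(n+1).
- Threshold selection with an unreachable target returns a sub-floor cutoff
  with a warning (nothing significant) rather than failing the whole
  calibration; a fully degenerate p distribution is an error.
- RNG: a single master seed; per-participant substreams are spawned
  deterministically (`numpy.random.SeedSequence`), so results are independent
  of participant order and reproducible bit-for-bit.
- Tie at the permutation floor: with strong effects several neighbouring
  frequencies can saturate at p = 1/(n+1); the group vector strength (or
  amplitude) localises the effect among the tied frequencies.

## Limitations

- The AR-surrogate first-level p is miscalibrated under fitted parameters
  (see above); only the calibrated family-wise procedure is interpretable.
- Calibration analyses simulated continuous outcomes with the Gaussian family
  in all three approaches, including the trials approach that uses a binomial
  family on real accuracy data; the calibrated cutoff for binomial trials
  scans therefore inherits the Gaussian calibration.
- No mixed-effects variants, no cross-participant phase statistics (by
  design: the approaches test amplitude only), no unequal-variance SDT, no
  alternative spectral estimators (single fixed detrend+pad+DFT pipeline),
  and AR surrogate order fixed at 1.
- The co-occurrence p-value treats bootstrap samples as independent
  observations, which they are not; it is reported as descriptive.
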