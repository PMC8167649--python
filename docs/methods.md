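# Methods

## Signal model and assumptions

The package treats an incremental-exercise RR series as a slowly varying
mean interval (the work-rate trend) plus beat-to-beat fluctuation whose
*correlation structure* — not its amplitude — carries the physiological
signal. The short-term detrended-fluctuation exponent alpha1 summarises
that structure over 4–16-beat box sizes: ~1.0 for persistent fractal
fluctuation at easy intensity, 0.5 for uncorrelated (white) fluctuation,
< 0.5 for anticorrelated fluctuation at severe intensity. The working
hypothesis embodied by the tool is that the heart rate at which rolling
alpha1 crosses 0.75 / 0.5 approximates the aerobic / anaerobic
threshold. The tool assumes the input is a beat-accurate RR list from an
ECG-grade recording; it corrects isolated detection artifacts but is not
an arrhythmia classifier, and heavily ectopic recordings should be
excluded by the analyst (the artifact report flags loads above 5 %).

## Pipeline parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `window_s` | 120 | s | shortest window giving enough beats for a stable short-term exponent |
| `step_s` | 5 | s | dense sampling of the alpha1-vs-HR curve |
| `min_beats` | 100 | beats | windows with fewer beats (HR < ~50 bpm) are skipped, not padded |
| `detrend_lambda` | 500 | – | standard smoothness-priors setting for short-term HRV |
| `detrend_mode` | `window` | – | see below |
| `scale_min..scale_max` | 4..16 | beats | the short-term DFA box range |
| `artifact.rel_threshold` | 0.25 | – | relative deviation from the local median that marks a beat suspect |
| `artifact.win` | 11 | beats | local-median neighbourhood |
| `artifact.abs_floor` | 50 | ms | keeps very steady series from flagging physiological jitter |
| `hi`, `lo` | 1.0, 0.5 | alpha1 | decline boundaries ("close to 1.0" to "approximately 0.5") |
| `min_points` | 4 | – | below 4 points r² of the decline fit is uninformative |
| `max_extrap_bpm` | 10 | bpm | crossings far outside the fitted HR range are unsafe and refused |

Units are fixed package-wide: RR intervals in ms, cumulative time in s,
heart rate in bpm. Mean window HR is `60000 / mean(RR)` — the rate
implied by the mean interval — rather than the mean of instantaneous
rates; the two differ slightly for variable series and a single
convention is required.

## DFA normalisation

`F(n)` pools the squared residuals of per-box line fits over all
`m = floor(N/n)` forward boxes and normalises by `m·(n−1)` rather than
the raw point count `m·n`. The difference matters at 4–16-beat boxes:
the expectation of the classic estimator can be computed exactly for a
Gaussian process with covariance `C` as `tr(MCM')`, `M = (I−P)L`
(`L` = cumsum, `P` = line projector), and with the raw-count
normalisation the expected log–log slope for *white* input over these
scales is 0.583 — an estimator that would systematically misplace the
"uncorrelated = 0.5" landmark on which the whole threshold definition
rests. With the residual-degrees-of-freedom normalisation the exact
expected slopes are 0.508 for white noise, 1.427 for integrated white
noise, and {0.254, 0.508, 0.790, 0.939} for fractional Gaussian noise
at H ∈ {0.2, 0.5, 0.8, 0.95} — centred on the nominal exponents across
the working range. The acceptance suite verifies these calibrations by
simulation. Boxes are taken forward from the first beat with the
remainder discarded (the classic convention); a `reverse_pass` option
additionally pools boxes from the series end but is off by default.
Constant windows raise "zero fluctuation"; windows shorter than
`4·scale_max` are refused with the required length in the message.

## Detrending

The smoothness-priors trend is `(I + λ²D₂'D₂)^{-1} x` with `D₂` the
second-difference operator; the system is pentadiagonal
symmetric-positive-definite and solved with a banded Cholesky solver.
The operation is linear and, at λ = 500, leaves the variance of white
noise essentially untouched (< 5 % change at N = 200) while removing
the within-window work-rate trend. By default detrending is applied
per analysis window immediately before DFA (`detrend_mode="window"`):
window-local removal of the local trend mirrors how the exponent is
meant to see only beat-to-beat fluctuation, and avoids one global
detrend leaking ramp structure across windows. `global` and `off`
modes are provided because HRV packages differ in where (and whether)
they detrend before short-term DFA, and the choice is not universally
standardised.

## Artifact correction

Detection: beat *i* is suspect when
`|RR_i − median_win(i)| > max(abs_floor, rel_threshold · median_win(i))`
with the median taken over the `win`-beat neighbourhood excluding the
beat itself. Correction then pattern-matches the flagged beats:

* adjacent flagged pair summing to ≈ 2× the local median — a premature
  beat with compensatory pause — is redistributed into two equal
  intervals (both flagged `corrected_ectopic`);
* adjacent pair summing to ≈ 1× the median — a spuriously inserted
  detection — is merged into one interval (`corrected_extra`);
* a single interval ≈ 2× the median — a missed detection — is split
  into two halves; the first carries `corrected_missed` and the second
  stays `ok`, so the report counts one detected artifact for one
  physical dropout while remaining consistent with "corrected beats =
  flagged beats";
* anything else is replaced by cubic-spline interpolation over the
  neighbouring normal beats.

All structured corrections preserve cumulative time exactly, so window
boundaries defined in seconds are unaffected; spline replacements may
move it by ~1 ms each. More than 50 % flagged beats aborts with
"series unusable"; a corrected fraction above 5 % emits a warning. The
exact correction recipe of commercial HRV software is unpublished;
this detector is an independent design whose contract — detect
ectopic/missed/extra beats, report a faithful corrected fraction — is
exercised against the injector's ground truth (100 % recall at 3 %
contamination in the seeded acceptance runs).

## Decline selection and threshold solving

The alpha1-vs-HR curve of a ramp is reverse-sigmoidal; the threshold
regression must use only the near-linear drop. Anchors are located on
a 7-point running-median smoothing of the curve (raw points are always
what is fitted): the start is the *last* smoothed point at or above
`hi` — on noisy curves the plateau dips below 1.0 transiently long
before the true decline, so "first drop" anchoring is not robust — and
the base end is the first smoothed point at or below `lo`. The end is
then extended forward while successive points (raw or smoothed)
continue within a fixed band of the running fit — two base-fit
residual SDs, floored at 0.04 alpha1 units so an exactly linear base
segment still tolerates estimator jitter — implementing "continues in
a straight fashion". Among candidate windows (small jitter around the
anchors) with negative slope and ≥ `min_points` points, the highest-r²
window wins; ties go to the longer window, then the earlier start. A
manual override (`--segment-hr lo:hi` / `--segment-time lo:hi`)
reproduces the analyst-marked workflow exactly.

The threshold is the closed form `HR* = (target − intercept)/slope`
with alpha1 regressed on HR (alpha1 dependent, matching how the curve
is constructed and plotted). Estimates outside the fitted HR span are
marked extrapolated; beyond `max_extrap_bpm` they raise with the raw
crossing in the message. Degenerate inputs fail loudly: a curve that
never drops below `hi`, or no negative-slope run of sufficient length,
raises "no decline found" (a noiseless ramp, alpha1 ≈ 2 everywhere, is
the canonical example).

## Agreement statistics

Differences are estimate − reference throughout; SDs use the n−1
denominator; limits of agreement are bias ± 1.96·SD(diff); SEE is
`sqrt(SS_res/(n−2))` from the OLS regression of the estimate on the
reference (that direction is the convention for validating a new
method against an established one). The paired t statistic is
`bias/(SD(diff)/√n)` with n−1 df. When either column has zero
variance, correlation and regression are undefined (reported NaN with
an explanatory note) while the Bland–Altman block is still returned.
Column SDs are reported with the n−1 convention; at typical printed
rounding the n vs n−1 choice is not distinguishable, so a single
documented convention is used. The bundled 15-runner treadmill cohort
(`load_treadmill_vt2_pairs`) is the canonical numeric check.

## Synthetic data

`generate_fgn` draws exact fractional Gaussian noise by circulant
embedding (Davies–Harte): the autocovariance is embedded in a
circulant matrix whose eigenvalues (non-negative for fGn) shape a
Hermitian random spectrum; output is zero-mean, unit-variance and
bit-reproducible per seed.

`generate_ramp` lays beats down sequentially: the mean interval tracks
`60000/HR(t)` with HR rising linearly (default 70 → 190 bpm over
1200 s), and the fluctuation around it is fractionally integrated
Gaussian noise — MA(∞) weights truncated at 300 lags,
variance-normalised per beat, scaled to `noise_sd_ms` (default 10 ms;
the exponent is amplitude-invariant so this only needs plausibility).
The per-beat integration order is set by inverting the *exact*
expected-slope map of the DFA estimator (the `tr(MCM')` computation
above, tabulated over d and interpolated), so the expected measured
alpha1 profile equals the programmed one: flat at `alpha_hi` (1.1)
below `hr_decline_start` (140 bpm), linear in HR through 0.5 at
`hr_crossing` (172 bpm, the ground-truth HRVT2), floored at `alpha_lo`
(0.3). At the crossing the order is the white-noise point of the map,
so "alpha1 = 0.5 at the programmed HR" holds by construction, not by
per-seed calibration. An earlier design that amplitude-mixed two
fixed-H fGn streams was rejected: the realized exponent of such a
mixture is not the programmed interpolation, and the estimator's
short-scale compression at high exponents would bend the measured
profile away from linearity.

The generator emulates the correlation structure and trend of a ramp
test, not its full physiology: no respiratory sinus arrhythmia, no HR
on-kinetics or cardiovascular drift, constant fluctuation amplitude,
and a strictly linear HR trend. Passing the end-to-end recovery test
therefore shows that the pipeline inverts the stated signal model
accurately; it does not certify performance on real recordings, which
is what the bundled validation cohort's agreement statistics address.

`inject_artifacts` contaminates a series at a site rate ≤ 20 % with
sum-preserving ectopic couplets, merged (missed) beats and inserted
(extra) beats, default mix {missed 0.7, extra 0.2, ectopic 0.1}: in
ECG-grade exercise recordings detection dropouts dominate and rise
with intensity, spurious detections come second, and frank ectopy is
rare once ectopy-heavy subjects are screened out. Sites are spaced ≥ 3
beats apart so corrections cannot interact; ground-truth onset times
are returned for recall scoring. Note the reported corrected fraction
counts *beats*, and an ectopic couplet flags two beats, so the
expected fraction is `rate · (1 + p_ectopic)` — at the default mix a
3 % site rate reads back as ≈ 3.3 %.

## Problem sizes and determinism

The test and acceptance runs use 20-minute default ramps (~2 600
beats, 217 curve points), 50-replicate noise calibrations at N = 1000,
100 oracle-comparison windows of 100–300 beats, and 20-seed recovery
batches — sizes at which every quantity is stable yet the full suite
runs in well under a minute of compute per block. All generators are
pure functions of an explicit seed; there is no global random state.
The end-to-end recovery rate is itself a binomial observable (per-seed
success ≈ 0.9–0.95 at the default conditions), so 20-seed batches
fluctuate by a few seeds across different master seeds.

## Known limitations

* The artifact detector approximates, but is not, the unpublished
  recipe of commercial HRV software; corrected series from different
  tools will differ in detail.
* The decline boundaries `hi = 1.0` and `lo = 0.5` are engineering
  defaults for rules stated qualitatively ("close to 1.0",
  "approximately 0.5"); curves that never reach the plateau or never
  approach 0.5 need the manual segment override.
* No confidence interval accompanies the threshold estimate; the
  segment r² and the extrapolation flag are the only built-in quality
  signals.
* Device-specific file formats (HRM/FIT/EDF) and QRS detection are out
  of scope; the plain-text RR list is the input boundary.
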