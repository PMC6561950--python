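# Methods

circakit implements the quantitative analysis stack used in circadian mouse
phenotyping — rhythmicity scoring of activity/bioluminescence/temperature
time series, period estimation, circular phase statistics and re-entrainment
kinetics — together with synthetic-data generators that emulate each
recording type with known ground truth, so every estimator is validated by
parameter recovery.

## Data model and conventions

All recordings travel as `UniformSeries`: uniformly sampled values with a
per-sample validity mask, time in hours from recording start. Day boundaries
sit at multiples of 24 h from lights-on (ZT0 = lights-on under LD). Angles
are radians internally; hours convert to angles via the cycle length of the
plot (24 h unless a free-running period is supplied). Activity onset of a
nocturnal rodent defines CT12.

Typical sampling follows the telemetry hardware being emulated: 1-min
passive-infrared activity counts, 30-min luminometer readings, 20-min
temperature-logger samples.

## Preprocessing

Luminescence and temperature traces are smoothed with a centred 2 h moving
average and detrended by subtracting a centred 24 h running average. Two
deliberate numerical choices:

* **Window discretisation.** A window of `w` hours spans the nearest odd
  number of samples, so it centres exactly on a sample. At 30-min sampling a
  24 h window is 49 samples (24 h inclusive of both endpoints). A centred
  odd window whose span is an integer number of cosine cycles double-counts
  one endpoint; exact cancellation therefore occurs for a cosine whose
  period equals the window's sample count x step, which is how the
  "detrending leaves a window-period cosine untouched" property is verified.
* **Edge policy.** Windows are never shrunk: a sample whose window leaves
  the record, or whose window holds fewer than 90% valid samples, is marked
  invalid. Truncated windows would bias edges in a way that is hard to test;
  invalidation is explicit and conservative.

The above-mean mask uses a strict inequality (a constant record has no
points above its mean). The top-quantile phase extraction takes the
`round(q*n)` largest valid detrended samples and maps their times onto the
cycle circle.

## Spectral rhythmicity score

A detrended, mean-subtracted segment (at least three cycles of the range
midpoint) is tapered with the 4-term minimum-sidelobe Blackman–Harris window
(a0=0.35875, a1=0.48829, a2=0.14128, a3=0.01168), zero-padded to the next
power of two >= 4x the segment length, and Fourier transformed. The squared
magnitudes are normalised to unit sum over the positive-frequency bins (DC
excluded after mean subtraction), making the spectrum a dimensionless
distribution of signal power. Rhythmicity is the relative density at the
peak within the circadian range — 20–30 h for tissue explants, 20–36 h for
behaviour — and band power sums the density within a fixed frequency band
(0.009 or 0.006 cycles/h) centred on the peak frequency. The band value is
interpreted as a width in cycles per hour; that is the only unit consistent
with a dimensionless relative power at these sampling rates. Zero-padding
refines peak localisation only; the unit-sum normalisation is applied to the
computed bins, so the contract `sum(density) = 1` holds exactly.

The sliding FFT-power time course (used to trace rhythm loss in constant
light) applies the same score to 10-day windows stepped by 1 day — window
and step are package choices sized to resolve a three-week record into a
smooth trend — stamping each score at the window centre.

Properties verified in the tests: scale invariance of the normalised
spectrum, Parseval consistency of the raw one-sided powers, agreement with a
literal DFT-sum oracle, and monotone erosion of peak power under added white
noise.

## Chi-square periodogram

For a trial period spanning K data bins the record is folded modulo K and

    Qp = N * sum_h n_h (M_h - M)^2 / sum_i (x_i - M)^2

computed from the K phase-bin means `M_h`, the grand mean `M` and the N data
points. Under the no-rhythm null Qp is asymptotically chi-square with K-1
degrees of freedom; the per-period significance line is the chi-square
quantile at 1-alpha (default 0.05). Null calibration is checked empirically
(the fraction of trial periods above the line stays near alpha), and Qp is
affine-invariant in the data by construction.

Implementation decisions:

* Trial periods are integer multiples of the bin width, keeping the fold
  exact; 1-min counts are rebinned to 6-min sums first (variance
  stabilisation, tractable bin counts), giving a 0.1 h period grid.
* The reported period maximises `Qp - significance_line` rather than raw Qp,
  correcting the degrees-of-freedom drift across trial periods; ties break
  toward the shorter period.
* The standard long-record protocol (`estimate_period`) analyses a 40-day
  span starting 3 days into constant darkness, searching 20–28 h.
* A record counts as arrhythmic when no trial period clears a
  Bonferroni-corrected line across the ~81 trial periods. With the raw
  per-period line, pure noise would show a spurious crossing more often than
  not, making "no detectable rhythm" meaningless. The per-period alpha line
  is still reported for plotting.
* A zero-variance record raises "no rhythm detectable": the statistic is
  0/0 there, so no finite Qp is defined.

## Circular statistics

For phase angles theta_j, the mean resultant length `r = |sum exp(i
theta_j)|/n`, the mean direction, the Rayleigh statistic `z = n r^2` and
Zar's second-order series p-value (accurate for n >= 10) are reported.
Uniformity calibration (P(p<0.05) ~ 0.05) and rotation invariance are
property-tested.

Simulated phase sets are drawn from a von Mises distribution whose
concentration kappa is found by Brent inversion of A(kappa) =
I1(kappa)/I0(kappa) using exponentially scaled Bessel functions. Two
calibration modes exist because the sample statistic r-hat is biased upward
at small n (exactly, `E[r-hat^2] = 1/n + (1-1/n) rho^2`):

* population mode (default): A(kappa) = r_target, so the *distribution* has
  the target resultant length;
* expected-sample mode (`match_sample_size=n`): kappa solves
  `rho + (1 - alpha2(kappa))/(4 n rho) = r_target` (delta-method bias, with
  alpha2 = I2/I0), so the *expected sample statistic at size n* hits the
  target. This is the right mode when the target value is itself a
  small-sample estimate, e.g. an r computed from ~14 daily phases; at n=14
  the bias is 0.02–0.06 and matters.

CT12 extrapolation fits a least-squares line through the activity onsets of
days 3–6 of constant conditions; the fitted slope estimates (period - 24)
h/day. Supplying a period instead fixes the slope and fits only the
intercept.

## Onset detection and re-entrainment

Daily activity onsets are detected by step-template correlation: the onset
score at a sample is the mean activity of the following 6 h minus the mean
of the preceding 6 h, and the day's onset maximises that score, searched
within ±4 h of the previous day's onset once one exists. Days with no
activity, or no positively scoring candidate (e.g. constant activity), are
invalid. The detector is checked against a literal per-sample scan and is
exact on noiseless square waves.

Re-entrainment speed after an 8-h phase advance is summarised by PS50, from
the variable-slope sigmoid

    Y = Bottom + (Top - Bottom) / (1 + 10^((logPS50 - X) * HillSlope)),

with X = log10(day since the shift) — the conventional log-abscissa
dose-response form, equivalent to a Hill function in linear days, with
Y(day = PS50) = (Top+Bottom)/2 exactly. Onset shifts are unwrapped (no
mod-24 jumps) and advances counted positive. Fitting uses bounded
least-squares (PS50 in [0.1, 30] days), initialised at Bottom=0, Top=the
imposed shift, HillSlope=2 and logPS50 at the first day reaching half-shift.

All four parameters are free by default, and on noiseless data the fit is an
exact-recovery fixed point across a PS50 x HillSlope grid. On realistic
14-day noisy trajectories, however, the four-parameter fit is not reliably
identifiable: a near-linear trajectory can be fitted *better* (lower
residual) by an absurd Top with a shallow slope, driving PS50 to its bound.
Cohort analyses therefore fix the asymptotes to their known values (Bottom =
0, Top = the imposed 8 h), which `fix_top`/`fix_bottom` expose; this cut
cohort-mean scatter by an order of magnitude in the recovery tests.

The phase-shift magnitude for a single advance followed by release into
darkness is the gap at the transition day between the pre- and post-shift
onset regression lines, both drawn with slope (period - 24) h/day; advances
are positive, and the measure is antisymmetric under exchanging pre and
post.

## Synthetic data: what it emulates and what it does not

* **Activity**: a phase-only oscillator advancing at 2*pi/tau per hour;
  expected counts `mesor * (1 + amplitude cos psi) * (1 -
  masking_strength * light)`; realised counts Poisson (event counts from a
  passive-infrared sensor). On light-dark days, while lights are on, the
  phase relaxes toward the entrained phase (activity peak at mid-dark) at
  `resetting_rate` per day. Defaults: mesor 5 counts/min, amplitude 0.8,
  masking 0.5 — values producing records on which the periodogram behaves
  like it does on real long-term PIR data.
* **Bioluminescence**: damped cosine + linear baseline + Gaussian noise;
  the daily max-to-min of the envelope halves every `ln2/damping_rate`
  hours, giving closed-form expectations for the pipeline tests.
* **Temperature**: sinusoid around a mesor (defaults 36.8 ± 0.8 °C, noise
  s.d. 0.15 °C) with Gaussian noise.
* **Onset shifts**: the sigmoid above plus daily Gaussian jitter (0.3 h in
  the recovery suites).

Deliberate simplifications: the oscillator is phase-only (no amplitude
dynamics), so a single advance can never overshoot the 8 h target — the
generator reproduces fast-vs-slow re-entrainment phenotypes but not
overshoot phenomena, which would need a limit-cycle model with a radial
degree of freedom. Activity noise is exactly Poisson (no ultradian bouts,
no behavioural autocorrelation), temperature ignores activity-evoked
transients, and bioluminescence damping is a single exponential. Passing
recovery tests therefore demonstrates correctness of the estimators under
these idealised conditions, not robustness to every pathology of real
recordings.

All generators are deterministic given their seed (property-tested), and
multi-stage pipeline runs derive per-step streams from one master seed.

## Problem sizes in the validation suites

Recovery suites use the cohort sizes of the emulated study design: 5
replicate 43-day activity records per genotype-analog (periodogram), 7- and
9-animal onset cohorts over 14 days (PS50), and 3 sets of 14 phases averaged
over 100 seed repetitions (Rayleigh). Oracle-equivalence suites use 100
random records up to 2000 points; null-calibration suites pool ~3000 trial
periods across 40 noise records. These sizes make the whole test suite and
the acceptance script each finish in seconds.

## Known limitations

* Irregular sampling and gap imputation are out of scope; invalid samples
  are masked, never interpolated.
* The FFT score's band width and the periodogram's search resolution are
  configurable but their defaults encode the conventions above; comparing
  scores across different configurations is not meaningful.
* `fit_ps50` reports non-convergence with best-so-far parameters rather
  than silently returning them.
* The Rayleigh p-value series approximation degrades below n ~ 10.
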