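# circakit

Circadian time-series analysis for chronobiology: spectral rhythmicity
scoring, chi-square periodogram period estimation, Rayleigh circular phase
statistics, and sigmoidal PS50 re-entrainment fitting — plus synthetic-data
generators that emulate activity, bioluminescence and temperature recordings
with known ground truth, so every estimator can be validated by parameter
recovery.

It is written for researchers analysing long-term mouse (or other rodent)
recordings: passive-infrared locomotor activity counts, ex vivo
bioluminescence reporter traces, and implanted-logger core body temperature.

## What it computes

* **Rhythmicity score** — a 4-term Blackman–Harris windowed FFT power
  spectrum, normalised to unit sum, summarised as the relative power at the
  peak within a circadian range (20–30 h for tissue, 20–36 h for behaviour)
  and the band power within 0.009 (or 0.006) cycles/h of that peak; also as
  a sliding-window time course to trace rhythm loss in constant light.
* **Free-running period** — the chi-square periodogram
  `Qp = N * sum_h n_h (M_h - M)^2 / sum_i (x_i - M)^2`, chi-square(K-1)
  under the null, applied to a 40-day span of constant-darkness activity
  rebinned to 6 min and searched over 20–28 h.
* **Phase clustering** — the Rayleigh mean resultant length
  `r = |sum exp(i theta)| / n` with mean direction, `z = n r^2` and Zar's
  series p-value, applied to e.g. the phases of top-20% detrended body
  temperature; plus CT12 extrapolation from early activity onsets.
* **Re-entrainment speed** — daily activity onsets by step-template
  correlation, and PS50 (days to half of an imposed phase shift) from the
  variable-slope sigmoid
  `Y = Bottom + (Top - Bottom)/(1 + 10^((logPS50 - X) HillSlope))`,
  X = log10(day); plus the phase-shift magnitude for a single advance
  followed by constant darkness.
* **Preprocessing and display** — 2 h moving average, 24 h running-average
  detrend, above-mean and top-quantile masks, and double-plotted actogram
  grids.

See `docs/methods.md` for the models, conventions, and numerical choices.

## Worked example

Simulate two 43-day constant-darkness activity records — one with a
free-running period of 23.71 h, one with 23.50 h — and recover the periods
from the counts alone (`examples/period_estimation.py`):

```python
from circakit import ActivitySimParams, LightSchedule, estimate_period, generate_activity

for label, tau, seed in [("wild-type-like", 23.71, 1), ("mutant-like", 23.50, 2)]:
    params = ActivitySimParams(intrinsic_period_h=tau, mesor=5.0, amplitude=0.8,
                               duration_days=43.0, seed=seed)
    record = generate_activity(params, LightSchedule.dd(43))
    est = estimate_period(record)  # 40-day window starting day 3, 20-28 h search
    print(f"{label}: true tau = {tau:.2f} h, periodogram estimate = {est:.2f} h")
```

```
wild-type-like: true tau = 23.71 h, periodogram estimate = 23.70 h
mutant-like: true tau = 23.50 h, periodogram estimate = 23.50 h
```

The estimates sit on the periodogram's 0.1 h trial-period grid; the 0.20 h
estimated difference between the two records matches the 0.21 h difference
in generating periods to grid precision. The other scripts under `examples/`
walk through PS50 fitting (cohort means 5.32 d and 1.27 d for generating
values 5.33 d and 1.26 d), Rayleigh analysis of temperature phases,
sustained-versus-damped bioluminescence scoring, and onset
detection/actogram export, each printing the numbers it computes.

## Command line

A thin CLI wraps the same functions for shell use:

```sh
circakit simulate --kind activity --params params.yaml --seed 1 --out act.csv
circakit periodogram act.csv --pmin 20 --pmax 28
circakit fft-power trace.csv --range 20:30 --band 0.009
circakit rayleigh phases.txt
circakit ps50 onsets.csv --fix-top 8 --fix-bottom 0
circakit biolum trace.csv
circakit actogram act.csv --out grid.csv
circakit run --config run.yaml --out results/
```

`circakit run` executes a declarative YAML pipeline and writes data
products, a log, and a byte-reproducible `summary.json` alongside the
effective config and seed.

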