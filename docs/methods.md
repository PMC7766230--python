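# Methods

This note documents the models, conventions and numerical choices behind
`airseq`, in the spirit of a statistical-software methods appendix.  It
states no empirical result beyond what the test suite and
`scripts/acceptance.py` compute themselves.

## 1. Data model

A station record is an hourly, timezone-naive, strictly contiguous series of
six pollutant channels (PM2.5, PM10, NO2, O3, SO2 in µg/m³; CO in mg/m³) and
six meteorological channels (temperature °C, relative humidity %, pressure
hPa, wind speed m/s, wind direction °, precipitation mm).  "Wind" is carried
as two columns (speed, direction), so the five meteorological factors map to
six channels.  Missingness is `NaN`; an empty CSV cell means missing, never
zero.  A "day" is the 24 hours sharing a calendar date in local clock time —
diurnal analyses of traffic-driven pollution only make sense in local time.

## 2. Periodicity diagnostics

The autocorrelation estimator is the classical biased form with a single
global mean:

    c_k = (1/T) Σ_{t=1..T−k} (y_t − ȳ)(y_{t+k} − ȳ),   r_k = c_k / c_0.

Dividing by `T` (not `T−k`) keeps |r_k| ≤ 1 by Cauchy–Schwarz at the price of
an O(k/T) downward edge bias.  Missing values are removed listwise (the
non-missing subsequence is concatenated) rather than imputed — imputation
would manufacture autocorrelation.  The white-noise 95% band is the lag-0
Bartlett approximation ±1.96/√T.

`detect_period` returns the candidate lag with maximal `r_k` provided it
clears the band, else nothing.  Two consequences worth knowing:

- any weekly pattern is also 14-periodic, so on daily means `r_7 ≈ r_14` up
  to the edge bias; with a weak weekly cycle the detector can tie-break to 14
  on noise;
- a *strong* weekly cycle decorrelates adjacent days, which can push hourly
  `r_24` below `r_12` (lag 12 stays mostly within one day and keeps the
  day's weekly weight).  Neither is a defect of the estimator; both are
  properties of the max-`r` rule the detector implements.

Weekly analysis operates on daily means (mean of the non-missing hours of a
day), not on hourly lag-168, matching how weekly variation is usually
reported.

## 3. Windowing

One training example per forecast day `T`: a 24×F input matrix stacking, hour
for hour, (a) the air-quality channels of day `T−1`, (b) the meteorology of
day `T−1`, (c) optionally the target pollutant of day `T−7` (the weekly
channel); the target is day `T`'s 24 hourly values of the target pollutant.
Feature sets mirror the usual ablation ladder: `target_only` = {PM2.5, CO},
`pol` = all six pollutants, `meo` = {PM2.5, CO} + meteorology, `all` = both.

Two conventions deserve emphasis:

- **Causality.** Using the forecast day's own air quality as an input leaks
  the answer; all day offsets default to history (`−1`, `−1`, `−7`).  A
  leaky day-0 configuration exists behind `allow_leakage=True` strictly for
  reproduction studies.  Day-`T` *meteorology* (forecast-style covariates)
  can be configured without leakage of the target.
- **Fair comparison.** The weekly variant cannot form windows for the first
  seven days of any split.  `WindowSpec.require_weekly_history` makes the
  non-weekly variants drop those same days (it never changes their features
  or targets), so every model in a comparison trains and is scored on
  identical forecast days.  The comparison protocols always set it.

Windows touching any unresolved gap are dropped whole — the 24-step decoder
contract admits no partial targets.  Windows advance by whole days, not by a
sliding hourly stride.

Scaling is per-feature min-max (z-score available), fitted on the training
split only and inverted before metrics are computed.  Small gaps (≤ a
configurable number of hours, default 3) are linearly interpolated before
windowing; longer gaps remain missing.  Splits are chronological and
day-aligned, default 70/15/15.

## 4. Models

All four variants are implemented in NumPy (float64) with hand-written
backpropagation; the repository's test suite validates the gradients against
central finite differences and the cell against a literal scalar-loop oracle.

The gated cell is the standard LSTM: input/forget/output gates with logistic
activation, tanh candidate, Hadamard state update, `h_t = o_t ∗ tanh c_t`.

- `seq2seq_weekly` — LSTM encoder over the 24×F window (weekly channel
  included); the context is the encoder's final `(h_T, c_T)`, handed to the
  decoder as its initial state.  The decoder LSTM consumes the previous
  output `y_{t′−1}` (a learned scalar start value at the first step) and a
  linear head maps `s_{t′}` to `y_{t′}`; exactly 24 steps.
- `seq2seq` — identical, weekly channel excluded.
- `bilstm` — forward and backward LSTM encoders, concatenated final hidden
  states, dense 24-output head.
- `lstm` — unidirectional encoder, dense 24-output head.

**Context rule.** A "weighted sum of all encoder hidden states" admits many
realizations; absent an attention mechanism the minimal choice is the final
state, which is the default here.  A uniform mean over all hidden states is
available (`context_rule="mean"`).  Encoder and decoder hidden sizes are kept
equal so the state hand-off needs no projection.

**Training.** Adam (lr 1e-3, β = 0.9/0.999, global-norm gradient clip 5.0)
on the MSE of scaled targets; metrics are always reported on unscaled
concentrations.  Teacher forcing feeds the observed `y_{t′−1}` into the
decoder with per-step probability 0.5 during training and never at inference.
Early stopping monitors validation loss (patience 10, default ≤ 200 epochs)
and restores the best parameters.  Defaults: hidden size 64, batch 32.  All
randomness (initialization, shuffling, teacher-forcing draws) flows from one
integer seed; runs are reproducible on a single device (bit-identity across
platforms/BLAS builds is not promised).

## 5. Evaluation

RMSE (concentration units), NMSE = mean((P−O)²)/(P̄·Ō) (scale-free), and
Pearson r, pooled over **all test hours** (not averaged per day); a
per-horizon (1–24 h) breakdown is available.  NMSE's denominator uses the
means of the pooled evaluation set.  Because near-tied deep models reorder
between seeds, the comparison protocols train every (variant, target) cell
over several seeds and report per-seed rows plus medians; a failed cell
carries its error message rather than disappearing.

## 6. The synthetic generator

The generator emulates the temporal anatomy of a traffic-adjacent monitor:

    value(t) = w[dow(t)] · (baseline + Σ Gaussian diurnal bumps(hour)
               + coupling · meteorology(t)) + AR(1) noise(t),  clipped at 0.

- **Diurnal bumps**: circular Gaussians; CO defaults to peaks at 08:00 and
  18:00 (the rush hours), amplitudes 0.45/0.35 mg/m³, width 2.5 h.  PM2.5's
  peaks are derived from CO's, shifted by `pm25_lag_hours` (default 1 h, the
  particle-growth delay) and rescaled by the baseline ratio; O3 gets a single
  midday photochemical peak.
- **Weekly weights** (Monday first): default
  (1.00, 0.92, 0.96, 1.02, 1.08, 1.00, 1.06) — valley Tuesday, peaks Friday
  and Sunday, ≈15% swing (≈10 µg/m³ peak-to-valley on the PM2.5 default
  baseline of 50 µg/m³).
- **Meteorology** is exogenous: annual + diurnal sinusoids plus slow synoptic
  AR(1) noise (hourly coefficient 0.98, so weather persists across days —
  which is exactly what makes yesterday's meteorology an informative
  covariate).  Coupling into pollutants is linear and small by default
  (ventilation and humidity-growth effects).
- **Residual noise**: stationary AR(1), default coefficient 0.7, per-channel
  innovation sd (PM2.5 8 µg/m³, CO 0.08 mg/m³, …).  No variance figures are
  published for the motivating stations, so these are chosen to make the
  periodic structure clear but not dominant; they are free parameters of the
  world, not calibrations.
- **Missingness**: per-cell i.i.d. Bernoulli (default 0, tests use 1–10%).
  Real gap structure is bursty; i.i.d. is a declared simplification.

What a green test on this world does establish: the pipeline's contracts,
the exact numerics, and the *qualitative* claims (the weekly channel helps
when and only when a weekly cycle exists; informative meteorology helps).
What it does not establish: performance on real monitoring data, whose noise
is heavier-tailed, whose gaps are structured, and whose meteorology-pollution
coupling is nonlinear.  Published error levels from real two-year records are
not reproducible from synthetic data and are not claimed.

Determinism: one integer seed drives meteorology, per-channel noise and the
missingness mask through a fixed draw order; identical config + seed gives
bit-identical output, and a fleet derives station `i`'s seed as `seed + i`
(station 0 reproduces the single-station call exactly).

## 7. Degenerate inputs and numerical edges

- Constant series: autocorrelation raises a degenerate-variance error; a
  constant scaler feature gets unit scale so the transform stays invertible.
- Logistic inputs are clipped at ±60 before exponentiation (indistinguishable
  from exact in float64, overflow-safe).
- Negative synthetic concentrations are clipped to zero (resampling would
  break determinism); with default parameters clipping is rare.
- Gaps at the edges of a record are never interpolated (no anchor on one
  side).
- CSV values are written as shortest-repr floats and parsed with correctly
  rounded conversion, so a write/read cycle is bit-exact including the mask.

## 8. Known limitations

- No attention, GRU, convolutional or graph/spatial variants; stations are
  modelled independently.
- No spectral period estimation (the max-`r_k` detector inherits the
  harmonic ambiguity described in §2).
- The NumPy training loop is CPU-bound and intended for the daily-data scale
  (hundreds of windows); it is not a framework replacement.
- Cross-platform bit-identical training is not guaranteed; within one
  machine, seeded runs reproduce exactly.
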