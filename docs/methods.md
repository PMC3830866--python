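# Methods note

This note records the model, the statistical procedures, the numerical
choices, and the known limitations of the `mitoabc` package. Everything
here is implemented in `src/mitoabc/` and exercised by the test suite.

## 1. The stochastic model

A single cell carries `Y1` healthy and `Y2` mutant (deletion-bearing)
mitochondrial-DNA copies. Five reaction channels act on the pair
`(Y1, Y2)` with per-day propensities

| # | reaction            | propensity                  |
|---|---------------------|-----------------------------|
| 1 | mutation Y1 → Y2    | `c1 · Y1`                   |
| 2 | synthesis of Y1     | `1000 · c3 · Y1 / (Y1+Y2)`  |
| 3 | degradation of Y1   | `c3 · Y1`                   |
| 4 | synthesis of Y2     | `1000 · c3 · Y2 / (Y1+Y2)`  |
| 5 | degradation of Y2   | `c3 · Y2`                   |

The synthesis coefficients `c2 = c4 = 1000·c3` are treated as known
multiples of the degradation rate, so the free parameter vector is
`theta = (c1, c3, tau)`. The factor 1000 acts as a soft carrying
capacity: near `Y1+Y2 = 1000` total synthesis balances total
degradation.

**Death rule.** Once per day the mutant fraction `Y2/(Y1+Y2)` is
checked; the cell dies when it *strictly* exceeds the lethal threshold
`tau` (ties survive). An empty population (`Y1+Y2 = 0`) is dead by
convention. The state on the death day is recorded but cannot be
measured (the cell is gone).

**Defaults.** Initial state `(Y1, Y2) = (400, 600)`, horizon 36,500
days (100 years), independent uniform priors `c1 ∈ [1e-6, 1e-3]`,
`c3 ∈ [3e-5, 1e-3]`, `tau ∈ [0.5, 1]`. Units: rates are per copy per
day; `tau` is dimensionless.

### Simulators

Two engines produce a `Trajectory` recorded on the integer-day grid:

* `simulate_ssa` — exact Gillespie simulation: exponential waiting
  times with rate equal to the total propensity, channels chosen
  proportionally to their propensities.
* `simulate_daily` — Poisson leap with a fixed 1-day step: each
  channel fires a Poisson(`propensity × 1 day`) number of times per
  step, and removals are clamped to availability in channel order
  (1–5) so counts never go negative. This is the default engine for
  the calibration study; at the default rates (≤ 1e-3/day per copy)
  the expected number of events per copy per step is tiny and the two
  engines agree in death-time distribution (checked by a location test
  in the acceptance suite).

Both engines are compiled with numba; the measurement layer is
vectorised numpy, which keeps a full calibration study (see §5)
within minutes on one CPU.

## 2. Measurement model

At each scheduled day a laboratory-style measurement is emulated:

1. **Subsampling** — `min(300, Y1+Y2)` copies are drawn without
   replacement (hypergeometric split into healthy/mutant).
2. **Quantification noise** — multiplicative lognormal noise with a
   standard deviation of 0.20 on the log10 scale.

Two noise readings are implemented (`MeasurementModel(noise_on=...)`):

* `"counts"` (default): independent noise factors `10^eps_i` on each
  subsampled count, re-rounded to integers. The measured counts
  `Z1, Z2` then carry independent errors, and `Z1 + Z2` varies around
  the draw size.
* `"fraction"`: a single noise factor on the healthy fraction
  `Z1/(Z1+Z2)`, clipped to (0, 1], then re-integerised so
  `Z1 + Z2` equals the draw size exactly.

The `"counts"` reading is the default because under the `"fraction"`
reading `Z1 + Z2` is constant, which makes the predictors of the
regression summaries (a count and the corresponding fraction) exactly
collinear: the `b2` slopes become unidentified and summary set 3
degenerates into set 1 (see §3). The default reading also reproduces
the intended overall measurement error: over visited states of a
typical run the RMSE of the measured healthy fraction is ≈ 0.13.

Schedules: `"daily"` (every observable day) or an integer `k`
(`k` distinct days drawn uniformly at random without replacement; if
fewer than `k` days are observable the schedule is truncated and
flagged/logged).

## 3. Summary statistics

From a measured series the package computes a seven-component vector:

| index | name             | definition |
|-------|------------------|------------|
| 0 | `avg_rate`        | mean over consecutive pairs of `(f_{i+1}-f_i)/(t_{i+1}-t_i)`, with `f = Z1/(Z1+Z2)` |
| 1–2 | `b1_Z1`, `b2_Z1` | OLS slopes of `ΔZ1/Δt` on (current `Z1`, current `f`); intercept fitted and discarded |
| 3 | `max_ratio`       | maximum observed healthy fraction |
| 4 | `steps_to_death`  | death day of the generating run; the horizon when censored |
| 5–6 | `b1_Z2`, `b2_Z2` | the same regression for `Z2` |

The three candidate sets are set 1 = {0,1,2}, set 2 = {0,1,2,3,4},
set 3 = {0,1,2,5,6}.

Numerical choices:

* Differences are divided by the actual time gaps, so daily and sparse
  schedules are comparable; with daily data `avg_rate` telescopes to
  `(f_last - f_0)/(t_last - t_0)`.
* Regressions use `numpy.linalg.lstsq` with `rcond = 1e-9`. A
  predictor whose relative spread is below 1e-10 is dropped and its
  slope reported as 0, with a rank flag; residual collinearity
  resolves to the least-norm solution and is flagged.
* Degenerate series (< 2 points, e.g. death before the second
  measurement) yield a sentinel vector of zeros (with `max_ratio`
  equal to the lone observed fraction when one point exists) and a
  degeneracy flag; such runs stay in the reference table so the
  simulated and observed data are treated identically. Series with
  2–3 points get zero slopes plus rank flags.

## 4. Rejection ABC and the ridge adjustment

Given a reference table of `n_sim` prior draws with simulated
summaries, and the observed summary vector:

* Summaries are standardised by their per-column median absolute
  deviation over the table (fallback: standard deviation, then 1, for
  constant columns), and distances are Euclidean in that standardised
  space. The same scaling is applied to the observed vector, making
  distances invariant to rescaling any summary.
* The `accept_fraction · n_sim` smallest-distance rows are accepted —
  exactly 100 of 1000 at the default 10%, ties broken by row order.
* Point estimate: coordinate-wise posterior mean of the accepted
  draws. Intervals: equal-tailed empirical quantiles
  (`numpy.quantile`, linear interpolation; the rule is recorded in the
  results since coverage with ~100 draws is sensitive to it).

**Ridge adjustment (optional).** A locally weighted linear regression
of the (transformed) accepted parameters on the standardised summary
discrepancies `S_i − S_obs`, with Epanechnikov weights
`w_i = 1 − (d_i/T)^2` (T = acceptance threshold) and ridge penalty
`lambda = 1e-3` on the slopes (intercept unpenalised via weighted
centering). Parameters are moved to an unconstrained scale first —
log for `c1`, `c3`; scaled logit on the prior range for `tau` — and
the adjusted draws are clipped to the prior box after back-transform.
The adjustment is refused (flagged, raw draws kept) when fewer than
`k + 2` draws are accepted for `k` summaries. On a noiseless linear
model the adjustment is exact; with an infinite penalty or identical
summaries it reduces to the raw draws (both properties are tested).

## 5. Coverage calibration and summary-set selection

The calibration procedure repeats, `n_rep` times:

A. build a fresh reference table of `n_sim` prior draws;
B. draw one further "true" `theta` from the prior, simulate and
   observe it once, and run rejection ABC against the table;
C. record the posterior-mean estimate and whether the truth falls in
   the equal-tailed interval at nine nominal levels
   (95, 90, 80, 60, 50, 40, 20, 10, 5%).

One full seven-column table per replication serves all three candidate
sets (restriction to a set is a column selection), which is
statistically identical to building three tables and three times
cheaper.

Figures of merit, per parameter:

* `RMSE_1` — RMS over the nine levels of (observed coverage −
  nominal), where observed coverage aggregates the containment
  indicators across replications. A per-indicator variant (averaging
  squared deviations of the binary indicators) is available behind a
  flag for comparison.
* `RMSE_2` — RMS of (posterior mean − truth) across replications, on
  the natural scale by default; log10 and prior-range-scaled variants
  are reported alongside, since the natural scale makes the rate
  errors look tiny (the prior widths are ~1e-3).

**Majority rule.** Candidate sets are compared cell-by-cell over the
3 parameters × 2 criteria grid; a set wins a cell when it attains the
smallest value (ties count for every tied set). The chosen set wins
the most cells; a tie at the top is reported, never silently broken.
An optional calibration screen excludes sets whose worst `RMSE_1`
exceeds a threshold before counting. `repeat_and_rank` repeats the
whole study to gauge ranking stability and flags runs with fewer than
10 repetitions as underpowered.

Reproducibility: replications use independent `SeedSequence`
substreams spawned from the study seed, so results are deterministic
given (config, seed) and independent of execution order; a
replication that raises is re-drawn with the next substream and the
event is counted and logged.

## 6. Generator realism and limitations

* The model is a single-cell caricature: no between-cell or
  between-patient structure, fixed known synthesis multiplier (1000),
  and a hard threshold death rule checked once per day.
* The daily Poisson-leap engine clamps removals to availability in
  channel order; at the default rates clamping is vanishingly rare,
  but at rates near 1/copy/day the leap approximation and the clamp
  ordering would bias the dynamics — use the SSA engine there.
* `steps_to_death` uses the *latent* death day of the generating run.
  For simulated table rows this is always known; for real data it
  would correspond to observing the cell until death or censoring.
* The measurement noise reading is ambiguous (see §2); both readings
  are implemented and the default is the one under which all three
  candidate summary sets remain distinguishable.
* Natural-scale `RMSE_2` for `c1` and `c3` is dominated by the prior
  width and is nearly identical across candidate sets; the log10 and
  range-scaled variants are more informative for the rates.
* Equal-tailed intervals from ~100 accepted draws carry O(1/n)
  quantile bias; at a 10% acceptance fraction this is visible as a
  small systematic under-coverage at the extreme levels.
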