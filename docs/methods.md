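# Methods

## The generative model

The synthetic generator implements the distributed-lag nonlinear model
(DLNM) as a simulator.  For each day t,

    log μ_t = α + s(x_t, l; β) + β_O3·O3_t + β_PM2.5·PM2.5_t + f(t; θ)
    death_t ~ Poisson(μ_t)

with all covariate and basis columns centered over the valid days, so α is
the mean log-rate (default log 61.4 ≈ 4.117, the daily all-cause mortality
level of the Taipei 2012–2016 series the model emulates).

**Cross-basis.**  s is the tensor-product ("cross-basis") surface over
temperature and lag: a quadratic B-spline in temperature with three
interior knots at the 10th/75th/90th percentiles of the series (boundary
knots at its min/max, intercept column dropped, v_x = 5) crossed with a
natural cubic spline in lag with an intercept column (boundary knots at 0
and l = 30, three interior knots at exp of equally spaced points between
log 1 and log 30, v_l = 5).  Row t of the 25-column basis is
Σ_k T(x_{t−k}) ⊗ L(k) over k = 0..30; a brute-force double-sum oracle
checks this construction exactly on small instances.  For l ≤ 2 the
log-spaced knots degenerate and the lag basis falls back to {1, k}.
Natural cubic splines use the classic truncated-power construction (linear
beyond the boundary knots); the temperature B-spline is evaluated with
scipy's `BSpline.design_matrix`.

**Seasonal spline.**  f is a natural cubic spline over the sequential day
index with 8 degrees of freedom per calendar year in the span (40 columns
over five years), boundary knots at the series ends and interior knots
equally spaced.  One spline spans the whole period rather than separate
per-year pieces — the smoother and more conventional reading of "8 df per
year".  Its default coefficient vector θ is the least-squares projection
of a winter-peaked cosine with log-scale amplitude 0.09 onto the basis, so
the seasonal effect is deterministic, smooth and overridable.

**Default effect surface.**  β defaults to a U-shaped cumulative
temperature–mortality response: a cold excess (cumulative log-RR 0.12)
loading on the low-temperature basis functions with a lag profile decaying
over weeks (exp(−k/15), normalized), and a heat excess (0.10) loading on
the high-temperature functions concentrated at short lags (exp(−k/2)).
Lag profiles are projected onto the lag basis by least squares.  Pollutant
effects default to β_O3 = 0.0012 per ppb and β_PM2.5 = 0.0015 per µg/m³.

**Environment.**  Temperature is an annual cosine (mean 23.6 °C,
amplitude 6.5 °C, peak mid-July) plus AR(1) noise (ρ = 0.7, innovation SD
2.2 °C); O3 and PM2.5 are linear in the temperature deviation (couplings
+0.9 and −0.6) plus a shared factor and private noise, truncated at zero.
With the defaults the simulated series lands near the target descriptive
statistics (≈61 ± 9.6 deaths/day, temperature ≈23.6 ± 5.5 °C, O3 ≈28 ppb,
PM2.5 ≈20 µg/m³, day-to-day temperature autocorrelation ≈0.9) — steering
targets, not assertions.  The first l days are a burn-in simulated before
the nominal start date, so `simulate()` returns exactly `n_days` complete
rows without shifting the calendar.

What the generator does **not** emulate: day-of-week and holiday effects
on mortality (the calendar indicators are pure noise inputs here),
lagged pollutant effects, influenza epidemics and heat-wave/cold-spell
clustering beyond AR(1), measurement gaps, and overdispersion beyond what
the covariate structure induces.  Passing tests therefore demonstrate the
machinery's correctness and its statistical behavior under a DLNM-faithful
data-generating process, not performance on the restricted real series.

## Feature matrix

Every predictor is one input neuron: one-hot year (one column per calendar
year present), 12 month columns, three day-type indicators
(weekday/weekend/holiday, kept as three columns despite their
collinearity; holidays come from a user-supplied list), temperature lags
0..30, mortality lags 1..30 (never the same-day outcome), and current-day
O3 and PM2.5 — 83 columns for a five-year series.  The leading `max_lag`
days are dropped, not zero-padded.  Lags are positional (rows, not
calendar days), which matches series that had incomplete days omitted.
Each feature group can be switched off independently; a published
alternative description counts 54 inputs (24 "independent" + 30 lag
temperatures), but its exact composition is not enumerable from the text —
dropping mortality lags here gives 53 columns, and the discrepancy is left
visible rather than papered over.

## Cross-validation schemes

The chronological split takes the first floor(0.7·n) rows as the training
region.  Within it:

* five-fold: day-level random shuffling (seeded), k near-equal validation
  sets, each fold training on the other k−1;
* LOBO: k contiguous blocks (earlier blocks take the remainder days);
  fold i validates block i and trains on all other blocks;
* TB: k+1 contiguous blocks; fold i trains on blocks 1..i and validates
  block i+1.  This forward-chaining geometry is chosen so that exactly
  k = 5 validation errors exist, consistent with averaging five validation
  errors; a `drop-first` mode (k blocks, k−1 folds) is available.

Validation rows may use lag features computed from earlier observed days:
lags are observed predictors, not fitted values, so this is not leakage —
fold construction operates on feature-matrix row indices and never
re-derives lags per fold.  CV error is the exact arithmetic mean of the
per-fold validation MSEs.

## The network and its training defaults

A fully connected network with 1–3 logistic hidden layers and one linear
output, trained by full-batch Adam (scikit-learn `MLPRegressor`) to
minimize MSE on the raw deaths/day scale for a fixed iteration budget
(default 50,000) with no early stopping — every hyperparameter cell gets
identical training effort.  Continuous input columns are standardized with
statistics from the fold's training rows only; the outcome is centered at
its training mean (equivalent to initializing the output bias at the mean
level), so the budget is spent on structure rather than on climbing to the
count scale.  Step size defaults to 3e-4 with L2 penalty 1e-4: larger
steps let the network fit noise under the permuted-outcome null, pushing
its validation error far above the outcome variance, whereas the reference
permuted grids sit essentially *at* the outcome variance — the defaults
reproduce that regime.  Every grid cell derives its own seed from the base
seed and the layout (CRC32 mix, kept below 2³¹), so cells are reproducible
in isolation; predictions use the package's own forward pass over the
extracted weights, making saved models portable and runs bit-reproducible.

`count_parameters` uses the standard dense count Σ (fan_in+1)·fan_out plus
the output layer — e.g. 553 parameters for 83 inputs and layout (6,6).

## Permutation ratio

PR = min(1, CV_error(observed)/CV_error(permuted)), with
(1 − PR)·100 the model's contribution to prediction accuracy.  Only the
outcome vector is permuted over the training region; the feature matrix —
including the lagged-mortality columns — stays fixed.  Rebuilding lag
features from a shuffled series would also destroy the predictors'
internal time structure and change the null hypothesis being tested; the
fixed-feature permutation is the minimal exchange that breaks the
outcome–predictor association.  One permutation replicate per cell matches
how the reference permuted grids read; ≥20 replicates are recommended for
stable PRs (replicate seeds derive from the base seed).  PRs are rendered
at 3 decimals (half-away-from-zero), full precision kept internally.

## Reference grids and their summaries

The published two-layer grids (36 width combinations per scheme, observed
and permuted) and the three-layer grid ship as transcribed CSVs; they are
inputs for the summary arithmetic, since the mortality data behind them is
restricted.  Two transcription notes: the three-layer table's printed
column labels start at (12,12,12) although the accompanying text announces
(6,6,6) — labels are stored as printed and the arithmetic is
label-agnostic; and the narrative quotes two-layer minima of 61.192
(five-fold) and 54.442 (LOBO) at cells that the printed tables themselves
undercut — both tables' true minimum sits at (36,24) with 60.954 and
53.66, and the printed PR table is consistent with the (36,24) values, so
`best_cell` reports the genuine minima.  Recomputing all 108 PRs from the
error grids reproduces the printed PR table exactly at 3 decimals.

## Problem sizes and numerical choices

The stochastic experiments run at desk scale as the package's own test
conditions: parameter recovery uses 100 replicates of 1,818 days with a
Poisson GLM on the true design (95% Wald intervals; coverage is assessed
per parameter — requiring all three parameters jointly would have nominal
rate ≈0.86 and could not meet a 90% bar); the PR experiment uses a (12,12)
network at a 2,000-iteration budget on 1,818 simulated days; the
end-to-end smoke grid runs {(6,6),(12,12)} under all three schemes on 400
days at a 1,000-iteration budget, twice, and checks bit-identical results.
Ties in `best_cell` break row-major-first and are logged.  Table rendering
rounds half away from zero at the printed precision.  The 70/30 split uses
floor(); block remainders go to the earlier blocks.  Degenerate inputs
(empty grids, k exceeding the region, sub-year seasonal spans, fewer
distinct temperatures than knots, non-finite training data) raise
informative errors rather than producing silent results.

## Known limitations

Absolute CV errors of the reference grids cannot be regenerated without
the restricted mortality series and the original (unstated) training
details; the package reproduces their summary arithmetic exactly and
their qualitative behavior (permuted error ≈ outcome variance, PR well
below 1 under signal) on synthetic data.  The day-type indicators carry no
simulated effect; holiday lists must be user-supplied.  Training is CPU
single-threaded full-batch — large budgets on long series are slow by
design (budget parity), so scaled studies should reduce the iteration
budget, not the fold structure.
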