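# lagcv

Cross-validation machinery for neural-network prediction of daily mortality
from distributed-lag environmental exposures.

## The problem

Daily death counts depend on environmental exposures — most prominently
temperature — through effects spread over the preceding days: a cold spell
raises mortality for weeks, a heat wave within days.  The distributed-lag
nonlinear model (DLNM) captures this with a Poisson regression

    log μ_t = α + s(x_t, l; β) + β_O3·O3_t + β_PM2.5·PM2.5_t + f(t; θ)

where s(x_t, l; β) is a cross-basis surface over temperature and lag
(quadratic B-spline in temperature, knots at the 10th/75th/90th
percentiles; natural cubic spline in lag with 5 df, interior knots equally
spaced on the log-lag scale, maximum lag l = 30) and f is a seasonal
natural cubic spline with 8 df per year.

When the same predictors (plus lagged mortality) feed a feed-forward
neural network instead, the network's hyperparameters must be chosen by
cross-validation — and naive CV on time series lets the future leak into
the past.  `lagcv` implements and compares three schemes over the
chronological training region (the first 70% of days):

* **5-Fold-CV** — days shuffled at random into k = 5 validation sets;
* **LOBO-CV** (Leave-One-Block-Out) — k contiguous blocks; each block
  validates a model trained on all the others, earlier *and* later;
* **TB-CV** (Temporal-Block, forward chaining) — only blocks strictly
  before the validation block train, so no future data predicts the past.

The CV error is the mean of the per-fold validation MSEs.  To judge how
much a trained network actually learns, the **permutation ratio**

    PR = min(1, CV_error(observed) / CV_error(permuted outcomes))

compares the CV error against the same procedure run on outcome-shuffled
training data (a no-association null, whose CV error is essentially the
outcome variance).  PR plays the role of 1 − R²: (1 − PR)·100 is the
percentage of prediction accuracy contributed by the model.

The package bundles, as analysis inputs, the published two- and
three-layer CV-error/PR grids from the motivating temperature–mortality
study (Taipei, 2012–2016; 36 two-layer width combinations from
{6,12,24,36,48,60}²), together with the summary arithmetic used to compare
the schemes — grid minima, row and grand averages, cell-wise winner
counts, PR tables.  Because the underlying mortality series is
IRB-restricted, a DLNM-structured synthetic generator stands in for it:
seasonal AR(1) temperature, temperature-coupled pollutants, and Poisson
deaths drawn from the model equation above.

## Worked example

```python
import lagcv

# five years of DLNM-structured synthetic data
series = lagcv.simulate(lagcv.SimulationConfig(n_days=1818, seed=3))
fm = lagcv.build_feature_matrix(series)          # 83 input neurons
train_idx, test_idx = lagcv.chronological_split(fm.n_rows, 0.7)

plan = lagcv.make_plan("lobo", train_idx, k=5)
spec = lagcv.NetworkSpec(hidden_layout=(12, 12), max_iterations=2000, seed=0)
res = lagcv.run_cv(fm.X, fm.y.to_numpy(), plan, spec, continuous=fm.continuous)
perm = lagcv.permuted_cv_error(fm.X, fm.y.to_numpy(), plan, spec,
                               seed=7, continuous=fm.continuous)
print(f"CV error {res.cv_error:.1f}  permuted {perm:.1f}  "
      f"PR {lagcv.permutation_ratio(res.cv_error, perm):.3f}")
```

prints

```
CV error 66.3  permuted 95.5  PR 0.694
```

i.e. the network's leave-one-block-out CV error (66.3 squared deaths/day)
is clearly below the no-association null (95.5 ≈ the outcome variance);
the PR of 0.694 says the model contributes about 30% of the prediction
accuracy.  The packaged reference grids are summarized the same way:

```python
grids = {s: lagcv.load_reference_grid(s) for s in ("five_fold", "lobo", "tb")}
print(lagcv.best_cell(grids["lobo"]))        # ((36, 24), 53.66)
print(lagcv.winner_counts(*grids.values()))  # LOBO lowest in 28 of 36 cells
```

A `lagcv` command-line tool exposes the same steps
(`lagcv simulate`, `validate`, `features`, `folds`, `grid`, `summarize`,
`permute`, `train`, `predict`); see `lagcv --help`.

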