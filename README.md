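# asymu — asymmetric measurement-uncertainty intervals from validation precision data

`asymu` computes measurement-uncertainty intervals for analytical test results
(e.g. residue concentrations in food) from the precision profile of an
in-house validation study. It is aimed at method-validation statisticians and
analytical chemists who have factorial validation data at known concentrations
and need defensible uncertainty intervals for routine results — especially
when the dispersion grows with concentration, where the classical symmetric
interval *y ± U* is misleading.

## The model

A validation study measures samples of known concentration *x* at *m* levels
across *n* blocks (factor-level combinations of a two-level factorial design:
operator, batch, storage, ...) with *p* replicates. The mixed linear model is

    Y_ijk = α + β·x_ij + Σ_f (A_f + B_f·x_ij) + A_j + B_j·x_ij + a_ijk + b_ijk·x_ij

where every random term has a **constant** (absolute, units²) and a
**proportional** (relative, dimensionless) variance component. Pooling the
components gives the in-house reproducibility variance function

    σ²(x) = C + P·x²,

and the *mean curve* α + β·x describes the method bias. Variance components
are estimated by constrained REML (boundary zeros are reported exactly);
α and β by generalized least squares.

From a fitted model, a **prediction range** `f_{L,U}(y) = α + βy ∓ k·σ(y)`
is inverted at a routine result `ym`: the uncertainty limits solve
`f_U(y_L) = ym` and `f_L(y_U) = ym`, and the best estimate of the measurand is
`y_corr = (ym − α)/β`. Under heteroscedasticity the interval
`[y_L, y_U]` is asymmetric around `y_corr` — wider above than below — and, with
the exact normal quantile, its coverage is exact by construction. For a
constant relative SD `σ_rel` and no bias there is a closed form
`[ym/(1 + k·σ_rel), ym/(1 − k·σ_rel)]`; for log-normal data with stable
log-scale SD σ, the interval is `[ym/e^{kσ}, ym·e^{kσ}]`.

## Worked example

Two complete validation studies ship with the package: Thiamphenicol in milk
(4 levels × 8 blocks) and Clopidol in egg (6 levels × 8 blocks), both in μg/kg.

```python
>>> import asymu
>>> res = asymu.UncertaintyModel(asymu.load_fixture("clopidol_egg")).fit()
>>> print(res.uncertainty_table([0.2, 2.0, 6.0], k=2.0).iloc[:, :7].to_string(index=False))
 measured  lower  upper  best_estimate  best_minus_lower  upper_minus_best  expanded_uncertainty
      0.2   0.00   0.39           0.14              0.14              0.25                  0.23
      2.0   1.45   2.75           1.93              0.47              0.82                  0.62
      6.0   4.56   8.30           5.90              1.33              2.41                  1.76
```

Read across the `2.0` row: a routine result of 2 μg/kg supports measurand
values from 1.45 to 2.75 μg/kg; the bias-corrected best estimate is 1.93, and
the interval extends 0.82 above it but only 0.47 below — clearly asymmetric,
whereas the y±U half-width would be a flat 0.62 either side. At 0.2 μg/kg the
lower limit is truncated at zero (flagged in the table's `truncated_low`
column).

The same pipeline from the shell:

```sh
asymu fit --fixture clopidol_egg --out out/          # summary + variance/precision tables
asymu interval --fixture clopidol_egg --ym 2 --k 2   # interval table as above
asymu interval --closed-form --rsd 0.4 --ym 100      # closed form: [55.56, 500]
asymu coverage --rsd 0.4 -R 10000                    # empirical coverage ≈ 0.95
asymu report --fixture clopidol_egg --ym 2 --out out/  # tables + SVG plots
```

`asymu simulate` draws synthetic studies from the generative model;
`asymu.recovery_experiment` / `asymu.coverage_experiment` drive Monte-Carlo
checks of estimator quality and interval coverage.

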