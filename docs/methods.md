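# Methods

## Statistical model

A validation study measures samples of known concentration at `m` levels, in
`n` blocks (rows of a two-level factorial plan varying `q` in-house factors),
with `p` replicates. The response model is linear with heteroscedastic random
effects: each random term — one per design factor, one for the block, one for
repeatability — contributes an absolute effect and a relative effect scaling
with concentration, giving the marginal covariance

    V = Σ_t [ σ²_{A,t} Z_t Z_tᵀ + σ²_{B,t} (x∘Z_t)(x∘Z_t)ᵀ ] + diag(σ²_a + σ²_b x²)

with `Z_t` the indicator matrix of term *t*'s levels. The fixed part is the
mean curve `α + β·x` (absolute bias `α`, relative bias `β − 1`). Pooling all
components yields the reproducibility variance function `σ²(x) = C + P·x²`,
which is the only part of the fit the interval machinery needs. Assumptions:
normal effects, independence between all terms and between the constant and
proportional parts of one term, and a strictly positive slope `β`.

With `p = 1` (as in both packaged studies) the repeatability pair acts as the
residual term; it remains separable from the block pair because block effects
are shared across the `m` levels of a block.

## Estimation

Variances are estimated by numerically maximising the restricted
log-likelihood with `scipy` L-BFGS-B under `v ≥ 0` bounds, on a per-parameter
relative scale (constant components scaled by the OLS residual variance,
proportional ones additionally by the mean squared concentration) so the
optimiser works on O(1) quantities. Four deterministic starting points
(constant-dominant, proportional-dominant, balanced, residual-dominant) guard
against local optima; the best restricted likelihood wins. Components pinned
at the boundary are reported as exact zeros — boundary zeros are common and
meaningful in these designs. Fixed effects and their standard errors come
from generalized least squares at the estimated covariance. Convergence uses
a 1e-8 relative function tolerance with at most 500 iterations; fitting is
fully deterministic. Two terms inducing the same partition of observations
are completely confounded and rejected with both names in the error message.

Identifiability: a two-level factor contributes only two realised effects per
study, so *individual* factor components are extremely noisy at `n = 8`; the
well-identified quantities are the aggregates `C` and `P` (and the mean
curve), and Monte-Carlo recovery is judged on those. The packaged milk study
refits to the published component table to all five printed decimals; for the
egg study our optimum differs in the third decimal of `C` while attaining a
slightly higher restricted likelihood — downstream interval limits agree with
the published tables within 0.02 μg/kg either way.

A singular covariance (all variances numerically zero, e.g. noise-free data)
is handled by a diagonal jitter of order 1e-12 of the data scale, applied
only when the Cholesky factorisation fails.

## Intervals

The prediction range is `f_{L,U}(y) = α + β·y ∓ k·σ(y)`. Default coverage
factor is `k = 2`; a prediction-probability mode converts through the exact
normal quantile (1.959964 for 95%), and the two conventions are never mixed
in one report. Inversion solves `f_U(y_L) = ym` and `f_L(y_U) = ym` with a
bracketed Brent solver (bracket grown geometrically from the best estimate;
absolute f-tolerance 1e-9·max(1, ym)). `f_U` is strictly increasing, so the
lower limit is unique; when `f_U(0) ≥ ym` it is truncated to 0 and flagged.
`f_L` is strictly increasing iff its asymptotic slope `β − k√P` is positive;
otherwise no finite upper limit exists and the interval is flagged unbounded
rather than raising. The best estimate `(ym − α)/β` is floored at zero.

Bias handling: by default the fitted mean curve enters the prediction curves
(bias-corrected intervals); a no-bias mode substitutes the identity curve.
The uncertainty of the bias correction itself is not formulated here; a user
can fold an extra constant/proportional component into the profile if an
external estimate exists (off by default).

Consistency: the inverted interval satisfies the duality
`y ∈ interval(ym) ⇔ ym ∈ [f_L(y), f_U(y)]` by construction. Note that the
naive cross-containment "ym₂ ∈ interval(ym₁) ⇔ ym₁ ∈ interval(ym₂)" is *not*
a property of asymmetric intervals (nor should it be); `consistency_check`
reports plain cross-containment by default and the band duality when the
prediction band is supplied.

## Synthetic data

`simulate_study` draws from exactly the model above: one effect pair per
factor level, per block, and per observation; lognormal mode draws log
responses around `log(α + β·x)` using the proportional components as
log-scale variances (constant components must be zero — the case where a log
transform stabilises the variance). Defaults mirror the packaged studies:
8-block two-level designs, `p = 1`, concentration grids and truth components
taken from the packaged studies' published estimates. One base seed expands
to per-replicate substreams (`seed + r`), so experiments are reproducible and
independent of replication order.

What the generator does *not* emulate: non-normal effect distributions (other
than the lognormal mode), drift or carry-over within blocks, correlation
between a term's constant and proportional parts, calibration-standard error
in the known concentrations. Passing Monte-Carlo tests therefore demonstrate
internal consistency of estimator and intervals under the stated model, not
robustness to those violations.

## Experiment sizes and numerical choices

Coverage experiments use R = 10000 replicates (binomial SE ≈ 0.2% at 95%);
recovery experiments use R = 200 study refits on the 8-block design — enough
to pin medians of `C` and `P` to well within their ±30% check while keeping
the full suite comfortably fast on one CPU. Unit-level Monte-Carlo checks use
smaller R with fixed seeds. Percentages in report tables are rounded to one
decimal and SDs/limits to two (full precision kept internally), matching how
such validation tables are conventionally printed.

## Known limitations

- Normal-quantile prediction limits ignore estimation uncertainty in
  `(α, β, C, P)`; no t-type degrees-of-freedom inflation is applied, so
  real-world coverage is slightly below nominal for small studies.
- Per-factor variance components are reported but barely identified in
  two-level designs; interpret them qualitatively.
- Interlaboratory (reproducibility-between-labs) variance functions and
  design catalogues beyond two-level plans are out of scope.
- Concentration units are carried as opaque strings; no conversion.
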