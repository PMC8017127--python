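# Methods

This document specifies the statistical models implemented in `timeirt`,
the estimation framework, the scope of the synthetic data generator, the
numerical choices, and the package's limitations.

## Models

The package jointly models two observations per person *p* and item *i*:
an ordinal response score `X_pi` in `{0, …, K_i − 1}` and a time-on-task
`T_pi > 0` (minutes). Two person-level latent variables drive both:
proficiency `θ_p` and speed `τ_p`.

### Accuracy: graded response model (M1)

Cumulative category probabilities are logistic with a common
discrimination per item:

```
Pr(X_pi ≥ k | θ_p) = logistic(a_i (θ_p − b_ik)),   k = 1, …, K_i − 1,
```

with `a_i > 0` and strictly increasing thresholds `b_i1 < … < b_i,K_i−1`.
Category probabilities follow by differencing adjacent cumulative curves.
For dichotomous items (`K_i = 2`) the model reduces exactly to the
two-parameter logistic model. M1 uses only the responses; `θ ~ N(μ_θ,
σ²_θ)`.

### Times, simple structure (M2)

Log response times are normal around an item- and person-specific mean:

```
log T_pi ~ N(ξ_i − λ_i τ_p,  σ²_i),
```

where `ξ_i` is the item's time intensity (expected log-time at zero
speed), `λ_i ≥ 0` is its speed loading, and `σ²_i > 0` the residual
variance. `(θ_p, τ_p)` are bivariate normal with correlation `ρ`; this
correlation is the only link between accuracy and speed (van der Linden's
hierarchical structure).

### Times with cross-loadings (M3)

M3 adds a direct effect of proficiency on log-times:

```
log T_pi ~ N(ξ_i − λ_i τ*_p + φ_i θ_p,  σ²_i).
```

With `φ_i` free, a correlation between `θ` and `τ*` is not identified
jointly with the cross-loadings, so the model is identified by fixing
`corr(θ, τ*) = 0`: `τ*` is the part of speed orthogonal to proficiency.
Setting all `φ_i = 0` recovers M2 exactly.

### Rotation of M3

To compare M3 with M2's single correlation, the latent space of a fitted
M3 is rotated: in the standardized basis the item log-times load with
`B = [−λ_i sd_τ, φ_i sd_θ]`, and the rotated speed factor is the
unit-variance direction maximizing the common log-time variance — the top
eigenvector of `B'B` (2×2 closed form). The sign is chosen so the rotated
speed loadings sum positive (higher speed ⇒ shorter times). The rotated
factor's correlation with proficiency is the M2-`ρ` analogue. The rotation
only re-expresses the basis: the implied log-time covariance and the
marginal likelihood are unchanged (verified in the test suite via a
general two-factor evaluator).

## Estimation

### Marginal maximum likelihood

Parameters are estimated by maximizing the marginal log-likelihood, with
the latent variables integrated out by prior-adapted Gauss–Hermite product
quadrature. The grid is parameterized as `θ = μ_θ + σ_θ u` and
`τ = μ_τ + σ_τ (ρ u + √(1−ρ²) v)` over standard-normal nodes `(u, v)`, so
latent-distribution parameters move the node positions and remain
estimable. Missing entries contribute nothing to the likelihood
(ignorable/FIML under MAR). Persons with no observed entries contribute a
constant.

Free parameters are optimized with L-BFGS-B after transforming to an
unconstrained scale (log for variances and discriminations, atanh for
`ρ`). For M2/M3 the gradient is analytic, assembled from per-person
posterior moments of `(θ, τ)`; for M1 (only used for the accuracy
calibration) finite differences over the cheap one-dimensional quadrature
are used. Standard errors come from the observed information matrix,
obtained by central finite differences of the score.

### Two-step framework

Estimation mirrors a two-step international/country design:

1. **International step** (pooled sample): M1 with `θ ~ N(0,1)` fixed;
   then M2 and M3 with the accuracy parameters fixed at the M1 estimates
   (`μ_θ, σ²_θ` free; `μ_τ = 0, σ²_τ = 1` fixed for identification).
2. **Country step** (per group, accuracy parameters still fixed): a ladder
   of four nested invariance levels for the time parameters —

   | level  | ξ      | λ      | σ²   | latent moments |
   |--------|--------|--------|------|----------------|
   | Full   | fixed  | fixed  | fixed| all free       |
   | Strong | fixed  | fixed  | free | all free       |
   | Weak   | free   | fixed  | free | `μ_τ = 0` fixed|
   | Struct | free   | free   | free | `μ_τ = 0, σ²_τ = 1` fixed |

   Freed item intercepts (Weak) absorb a speed-mean shift, and freed
   loadings (Struct) absorb a speed-variance rescaling, hence the
   progressive anchoring of the latent speed moments. For M3's Struct
   level, `σ²_θ` is additionally fixed at the group's accuracy-only (M1)
   estimate so `θ` keeps its M1 interpretation; `ρ` is fixed at 0 where
   `φ` is free and free otherwise.

Levels are compared by BIC (`−2·loglik + n_free·ln n`), per group and by
the total across groups; ties resolve toward the more constrained level.

### Scoring

Person scores are EAP (posterior mean) estimates of `θ` (and `τ`) with
posterior SDs from the same quadrature grid. Precision is summarized by
EAP reliability, `var(EAP) / (var(EAP) + mean(PSD²))` (sample variance,
`ddof = 1`), and the average posterior SD.

### GRM approximate fit

Limited-information statistics from univariate and bivariate response
margins:

- **SRMR**: root mean squared difference between observed and
  model-implied inter-item Pearson correlations of the scores (pairwise
  complete observations).
- **RMSEA**: from the bivariate-margin chi-square
  `X² = Σ_pairs n_pair Σ_cells (p_obs − p_exp)²/p_exp` with
  `df = Σ_pairs (cells kept − 1) − n_item_params`, as
  `√(max(X² − df, 0)/(df · n))`. Near-empty implied cells (< 1e−10) are
  excluded and logged.

Conventional acceptability guidelines of 0.08 (SRMR) and 0.06 (RMSEA) are
exposed as constants.

## Synthetic data generator

The generator draws multi-group datasets from the models above, with known
ground truth returned for recovery studies. The packaged default scenario
(`paper_like_scenario`) uses 8 groups of ~600 persons and 10 items (3
polytomous with two thresholds) arranged in three blocks; time intensities
are calibrated so item mean times fall in roughly 0.8–2.2 minutes;
per-item response missingness grows with position within each block
(≈0.8%–9%, a few percent overall) and is missing-at-random given item
position and the observed standardized log-time, so likelihood-based
estimation remains valid. Group proficiency means are spread over about
one standard deviation. Three invariance scenarios are supported: `full`
(identical item parameters in every group), `weak` (group-specific `ξ` and
`σ²` only), and `struct` (additionally group-specific `λ`, and `φ` under
M3). All randomness derives from one master seed with deterministic
per-group substreams; identical seeds give identical datasets.

## Numerical choices

- Quadrature: Gauss–Hermite, default 21 nodes per dimension (15 in the
  pipeline default for speed); weights normalized for the standard normal.
- Likelihood evaluation is fully vectorized (persons × nodes); the time
  part is decomposed into two matrix products, so one M2/M3 evaluation at
  n = 2000 and 21² nodes takes ~10 ms on one CPU.
- Optimizer defaults: L-BFGS-B, `maxiter 500`, projected-gradient
  tolerance `1e−5`; convergence is declared on optimizer success or a
  small final gradient norm.
- Missing data are NaN-coded internally and written as the token `NA`.

## Limitations

- The latent distribution is assumed bivariate normal and log-times
  homoscedastic normal; no fat-tailed or mixture alternatives.
- The two-step design conditions on the first-step accuracy estimates;
  reported standard errors in later steps do not propagate first-step
  uncertainty.
- The generator starts at scored responses and total time-on-task; raw
  event-level log data (keystrokes, navigation) are out of scope.
- BIC is the only model-selection criterion implemented; no likelihood
  ratio tests across non-nested levels.
- Operational large-scale assessment data are not bundled; all empirical
  statements in the documentation refer to simulated data generated by
  this package.
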