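# Methods

## Model and likelihood

`nestlmm` fits the two-group linear growth model

y_it = β₀ + β₁·group_i + β₂·t + β₃·group_i·t + Σ_levels z_it'γ + ε_it

where the random effects γ at each grouping level (cluster, e.g. donor;
subject, e.g. mouse) are zero-mean Gaussian with a free covariance matrix G
(1×1 or 2×2; intercept and slope correlated within a level, levels mutually
independent), and the residual vector within a subject is either independent,
N(0, σ²I), or AR(1): corr(ε_j, ε_k) = φ^|j−k| over **observation order**
within the subject. Units: response in outcome units (the demo uses % weight
change), time in days, intercept variances in outcome², slope variances in
outcome²/day², σ² in outcome², φ unitless in (−1, 1).

Estimation maximises the exact marginal likelihood evaluated cluster block by
cluster block with β profiled out by GLS:

-2 ℓ_ML = N log 2π + log|V| + (y − Xβ̂)'V⁻¹(y − Xβ̂),
-2 ℓ_REML = (N−p) log 2π + log|V| + log|X'V⁻¹X| + (y − Xβ̂)'V⁻¹(y − Xβ̂),

with V = Σ Z G Z' + R per block. This convention matches statsmodels
`MixedLM` (verified in the test suite to ~1e-6 in the log-likelihood).
Coefficients and their standard errors — cov(β̂) = (X'V̂⁻¹X)⁻¹ — are reported
from REML fits; likelihood-ratio tests refit by ML.

### AR(1) lag convention

The autoregression runs over successive observations in time order within a
subject, giving correlation φ^|j−k| for observation ranks j, k. On an uneven
day grid (0, 1, 3, …, 32) a continuous-time kernel φ^|t_j − t_k| is a
defensible alternative; the order-based convention was chosen because it is
the direct reading of the recursion ε_t = φ·ε_{t−1} + Z_t over measurement
occasions, and it is what the test oracles implement. Mixing the two
conventions changes φ̂'s meaning but not the model-comparison logic.

## Parameterization and optimisation

Variance parameters are optimised unconstrained: each G through the
log-Cholesky factor (logs of the diagonal, free off-diagonal), σ² through
log σ², φ through atanh φ. Every iterate therefore maps to a valid
(PSD, |φ|<1) parameter point. The objective is minimised with bound-
constrained L-BFGS-B (finite-difference gradients; bounds ±15 on log-scale
coordinates, i.e. variances in [e⁻³⁰, e³⁰]) from a deterministic
method-of-moments start (OLS residual variance split equally between the
random-effect terms and the residual; slope variances scaled by mean t²).
A Nelder–Mead polish runs from the best point if L-BFGS-B does not report
convergence; `powell`, `nelder-mead` and `tnc` are selectable, and
`refit_all_optimizers` compares fixed effects across optimizers (stable when
the maximum relative discrepancy among converged fits is below 1e-4).

Blocks sharing a covariance pattern (identical time grid and subject
partition) are factorised once per likelihood evaluation and their quadratic
forms accumulated with stacked matrix products, so balanced designs cost one
small Cholesky per evaluation regardless of the number of subjects. σ² is
estimated jointly rather than profiled, keeping the AR(1) and independent
families on one code path.

### Boundary handling and singular fits

The log parameterization approaches zero variances only asymptotically, so
after optimisation each variance below 1e-3·σ̂² is trial-floored (its G
row/column zeroed) and the floored point is kept whenever the objective does
not worsen by more than 1e-8. This snaps boundary solutions onto the
boundary, making the singular-fit flag (any variance < 1e-8·σ̂², any
within-level |correlation| > 1−1e-6, or |φ̂| > 1−1e-6) reliable, and making
boundary LRT statistics exactly zero rather than numerical noise.

Non-positive-definite covariance evaluations return a large finite penalty
(1e10 scale) so derivative-free optimizers can recover.

## Inference

* **Wald test** (default effect: group × time): z = β̂/se(β̂) against the
  standard normal. The plain z reference is deliberate — its small-sample
  failure at few independent subjects is exactly the behaviour the
  calibration study quantifies; Satterthwaite/Kenward–Roger corrections are
  out of scope.
* **LRT** between structurally nested ML fits, χ² with df = difference in
  free parameters, statistic clamped at 0. When the tested parameters are
  variances the result carries a boundary warning, since the null lies on
  the edge of the parameter space and χ² is conservative there.
* **Parametric bootstrap**: simulate B datasets from the fitted null, refit
  both models per replicate, p = (1 + #{LRT* ≥ LRT_obs})/(B_ok + 1), where
  B_ok excludes failed refits (a >20% failure rate flags the result).
  Replicate streams are pre-split from one root seed. Note the null LRT
  distribution for a variance test is approximately a 50:50 mixture of a
  point mass at 0 and χ²₁; whenever the observed statistic is exactly 0 the
  bootstrap p is exactly 1, so the p-value distribution under the null has
  an atom at 1 of mass ≈ ½ **by construction**, while P(p ≤ α) = α holds
  for α below the atom. "Approximately uniform" is therefore asserted (and
  tested) as uniform calibration at conventional α levels, not as a
  whole-distribution KS statement.
* **Confidence intervals**: β̂ ± z·se, normal theory, any level in [0, 1).

The model ladder fixes the nesting edges a priori (II⊂I, III⊂II, IV⊂III,
V⊂IV, VIII⊂VI, VIII⊂VII, V⊂VIII); non-nested pairs are refused. ML fits
along the ladder are warm-started from nested solutions (embedding the
smaller model's parameters with floored new variances) and the better of the
cold/warm fits is kept, which enforces the nesting monotonicity
ℓ(I) ≥ ℓ(II) ≥ … ≥ ℓ(V) at convergence.

## Synthetic data

### Simulation scenarios

Each subject's response vector is drawn from a multivariate normal with mean
Xβ and covariance Z G Z' + σ²I over the subject's timepoints; subjects are
independent and share one covariance matrix. Three scenarios: random
intercept+slope, random intercept, none. The effect fraction ∈ [0, 1]
multiplies β₃ only, tracing the power curve while the group and time main
effects stay fixed.

The generating parameters ship as the versioned default set
**blanton-like-v1**: β = (0, −1, 0.75, −0.5) (intercept; group offset in %;
healthy slope 0.75 %/day; interaction −0.5 %/day so the second group gains at
0.25 %/day), G_intercept = 4 (%²), G_slope = 0.01 (%²/day²), σ² = 4 (%²),
intercept–slope covariance 0 by default (configurable). Rationale: over a
32-day experiment these give clearly separated group trajectories (24% vs 8%
final weight gain), subject trajectories spread by a few percent at baseline
and by ±~3% in final slope-induced spread, and residual noise of ±2% — the
magnitudes a percent-weight-change transplantation experiment produces. The
fitted values from the original re-analysis are not published, so these are
the package's own documented defaults; every calibration property asserted
in the tests is either parameter-free (type I error at effect fraction 0) or
stated relative to this configuration.

Designs: the re-analysed layout (3 healthy + 5 undernourished donors × 5
mice × days 0,1,3,4,7,11,14,18,21,25,28,32 → 480 cells), the simulation
layout (4+4 donors × 5 mice × 12 days), and independent layouts (n donors,
one mouse each, equal groups; n = 40, 100, 1000).

### Demo dataset

`make_demo_dataset` emulates the re-analysed experiment: growth is change
from baseline, so day-0 responses are exactly 0 and the random effects are
donor- and mouse-level **slopes** (SDs 0.15 and 0.10 %/day) with residual SD
1.5%; 43 of the 480 records are then removed completely at random (MCAR,
reproducible per seed, never emptying a subject), leaving 437. The original
missingness pattern is unpublished; MCAR is a generator convention, not a
claim about the source data.

### What the generator does not emulate

Real weight-change data are not exactly Gaussian, missingness is typically
not MCAR (deaths, censoring), trajectories can be nonlinear in time, and
residual variance can grow with time. Passing calibration tests on this
generator therefore demonstrates correctness of the estimator and the test
machinery under the stated model, not robustness to those violations.

## Monte-Carlo harness

Each rejection-rate cell simulates replicate datasets, fits the requested
model by REML, applies the α = 0.05 Wald test to β₃, and reports the
rejection proportion over converged replicates with an exact Clopper–Pearson
interval; non-converged replicates are counted and excluded, and a cell with
>10% failures is flagged. Within a table row all fitted models see identical
replicate datasets (common random numbers, verifiable via dataset hashes),
so model contrasts are paired. Replicate seed streams are pre-split from the
root seed with a process-independent hash, so results do not depend on
execution order.

Problem sizes used by the shipped study-level tests: 2,000 replicates for
the matched random-intercept condition, 10,000 for the ordinary-linear-model
condition, 1,000 for the directional misspecification contrasts and the
confidence-interval coverage check, 200×199 for the bootstrap calibration —
sizes at which the exact binomial bands are decisive for the qualitative
claims being tested while the whole suite stays desk-scale. The library
defaults mirror the conventional 10,000 (type I error) / 1,000 (power)
replicate counts, and the CLI exposes `--reps`.

## Known limitations

* Random-effect levels are limited to two (cluster ⊃ subject), strictly
  nested; crossed designs are out of scope.
* Gaussian responses only; no heteroscedastic residual variance; AR(1) is
  the only serial-correlation family.
* Wald inference uses the normal reference; no Satterthwaite df, no
  chi-bar-square boundary corrections (the bootstrap covers that need).
* The AR(1)-by-observation-order convention ignores gap lengths on uneven
  grids (see above).
* The simulation study draws independent subjects; AR(1)-correlated
  scenario data are not generated.
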