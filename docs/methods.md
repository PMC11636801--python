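# Methods

This note documents the statistical model, the search machinery, the
synthetic-data generator, and the numerical and design choices behind
`countspec`, in the spirit of a model-description vignette.

## The model

Counts per unit (the motivating case is crashes per road segment over a
fixed period) follow a log-linear rate

    lambda_i = exp(X_i' beta + offset_i),

where the optional offset carries log-exposure with a unit coefficient.  The
conditional law of `y_i` given `lambda_i` is one of:

* **Poisson** — equidispersed baseline, no extra parameter;
* **Negative Binomial (NB2)** — gamma-mixed Poisson; with `r = 1/phi`,
  `P(y) = Γ(r+y)/(Γ(r) y!) (r/(r+λ))^r (λ/(r+λ))^y`; variance `λ(1+φλ)`;
* **Generalized Poisson** (restricted form) —
  `P(y) = (λ/(1+φλ))^y (1+φy)^{y-1}/y! · exp(-λ(1+φy)/(1+φλ))`;
  accommodates overdispersion and collapses to Poisson as `φ → 0`.

Both NB2 and GP are evaluated in log space with log-gamma terms and switch to
the Poisson branch below `φ = 1e-10` for numerical stability.  The linear
predictor is clamped so that `λ ∈ [1e-10, 1e10]`; the optimizer treats any
non-finite likelihood as a rejected step.

### Random parameters

A coefficient declared random varies across observations,

    beta_ik = b_k + f_k(omega_k; u_ik),

with the deviate a deterministic map from a uniform draw:

| law        | deviate                              | role of `omega` |
|------------|--------------------------------------|-----------------|
| Normal     | `ω Φ⁻¹(u)`                           | standard deviation |
| Uniform    | `ω (2u − 1)`                         | half-width |
| Triangular | `ω T⁻¹(u)`, symmetric on [−1, 1]     | half-width |
| Gamma      | quantile of Gamma(shape=ω, scale=1)  | shape (mean ω) |
| Lindley    | quantile of Lindley(θ=ω)             | rate-like θ |

Normal/Uniform/Triangular are symmetric about zero, so `b_k` is the mean
coefficient.  Gamma and Lindley enter **uncentered**: they add a strictly
positive, right-skewed shift, which is the point — the Lindley's long tail
lets a subset of observations carry a much larger effect.  The Lindley
quantile uses the closed-form Lambert-W inversion of
`F(x) = 1 − (1 + θx/(1+θ)) e^{−θx}`.

The simulated log-likelihood averages over `H` quasi-random draws before
taking logs (the default `H = 200`):

    ln L = Σ_i ln[ (1/H) Σ_h P(y_i | λ_i^{(h)}, m) ].

With zero random coefficients this reduces exactly to the closed form.

### Halton draws

One prime base per random dimension in order (2, 3, 5, …), a burn-in of 100
points to reduce start-up correlation, no scrambling (bit-reproducibility
across runs and platforms), and observation `i` consuming the `i`-th
consecutive block of `H` points.  **Accuracy caveat:** the per-observation
integration error of any equal-weight 200-point rule grows with the
variation of the integrand, roughly `ω·|x|·y`.  Measured against adaptive
Gauss–Hermite quadrature, per-observation errors are ~6e-4 for a spread of
0.1 and rise to ~5e-3–2e-2 for spreads of 0.3–0.5; analyses in which large
scale parameters matter to third-decimal log-likelihood precision should
raise `hdraws`.

## Estimation

`MixedCountModel.fit()` maximizes the simulated log-likelihood with L-BFGS-B
from a deterministic start: the fixed part at the Poisson GLM solution,
scales at 0.1 (Lindley at 1.0, since small θ means *huge* deviates), the
dispersion at 0.5.  Bounds keep `ω ≥ 0` for symmetric laws, `ω ≥ 1e-3` for
the positive laws (a Gamma shape or Lindley rate of zero is degenerate), and
`φ ≥ 1e-6`.  Up to two deterministic-jitter restarts are attempted on
optimizer failure.  Defaults: 500 iterations, objective tolerance 1e-9
(relative), gradient tolerance 1e-6.

The objective gradient is analytic: the score of the simulated likelihood is
the softmax-weighted (over draws) conditional score, with
`∂logP/∂λ` closed-form for all three laws, `∂logP/∂φ` closed-form for NB2
(digamma) and GP, and `∂deviate/∂ω` closed-form for the linear laws, by the
implicit-function theorem for Lindley, and by a tight central difference of
the regularized incomplete gamma for the Gamma shape.  The Gamma/Lindley
quantiles themselves are refined by damped Newton iterations on the CDF,
warm-started from the previous scale value (tolerance 1e-10 on the quantile,
exact inversion as a fallback) — this keeps a full fit of a multi-random-
parameter NB model in the hundreds of milliseconds instead of minutes.

Standard errors: inverse central-difference Hessian of the simulated
log-likelihood at the optimum (default), or the outer product of the
analytic per-observation scores (`se_method="opg"`, BHHH); the search uses
OPG for its internal significance decisions because it costs one score pass.
Unavailable standard errors surface as p-value 1 so that repair removes the
weakest terms.  z-statistics use the standard normal reference.

### Repair

After each fit, terms with two-sided `p > alpha_sig` (default 0.1, the
significance convention of the rendered tables) are pruned and the model
re-fit, warm-started from the surviving estimates, until all retained terms
are significant or only the intercept remains.  The hierarchy: an
insignificant scale demotes the factor to a fixed effect (randomness implies
inclusion, so the fixed part stays); an insignificant mean coefficient
removes the factor entirely.  The intercept and the dispersion are exempt —
reported models always carry them.  Two pruning policies are offered:
drop the single worst offender per pass (default — dropping everything at
once can discard jointly significant terms) or drop all offenders per pass
(`drop_all=True`, cheaper; the search experiments use it).

## The search

A specification is a chromosome: per factor an inclusion flag, a randomness
flag, a mixing-law gene and a transformation gene, plus the model-type
selector.  Constraints (randomness implies inclusion; exactly one model
type; analyst clamps) are enforced by a normalization that also zeroes
inactive genes to canonical values, so equal models have equal encodings —
that canonical form keys the evaluation cache and duplicate detection.
Transformations are applied to the raw column (standardization is an opt-in
preprocessing flag) and are feasible only when the domain is respected and
all transformed values fall in `[−c, c]` (default `c = 1e5`); an infeasible
transformation marks the whole proposal infeasible, which the search
penalizes with an infinite objective rather than raising.

All three algorithms share: evaluation = normalize → cache → fit → repair →
objective of the repaired model, with the repaired chromosome replacing the
proposal; a wall-clock stop (`max_time`, checked between evaluations) plus
an optional evaluation-count stop (`max_evaluations`) that makes run length
machine-independent; and trajectory logging (iteration, incumbent, best,
accepted).

* **Harmony search** — memory of `HMS=20` elites; each candidate gene copies
  a random memory member with probability `HMCR=0.8`, else redraws; a
  uniform draw ≥ `PAR=0.5` triggers the index shift toward the memory's
  per-gene modal index, capped at `PAI=2` positions (a configuration switch
  restores the classical `< PAR` trigger direction).
* **Simulated annealing** — `T0 = ΔĒ/(−ln χ)` with `χ = 0.5`, where `ΔĒ` is
  the mean absolute objective gap over a seeded population of 20 random
  repaired specifications, so an average uphill move starts ~50% acceptable;
  `Ts=5` Metropolis steps per plateau; geometric cooling `Tα=0.975`;
  neighbors are 1–3 random gene changes (U(1,3)).
* **Differential evolution** — population `PS=20`; per gene with probability
  `CR=0.6` the trial index is `(ℓ_p + PAI(ℓ_p′ − ℓ_p″)) mod |L_j|`; the
  trial replaces its parent when strictly better.

The decision sets keep their listed order (models: Poisson, NB, GP;
distributions: Gamma, Uniform, Normal, Triangular, Lindley; transformations:
identity first) for all index arithmetic.  Ties between equal-objective
specifications keep the first found.

## Synthetic data

`SyntheticTruth`/`generate` emulate a cross-sectional crash-count design:
independent normal covariates, a constant, fixed effects, random
coefficients drawn **once per observation** (they are characteristics of the
unit), pure-noise columns with true coefficient exactly zero, and counts
from the chosen law.  The reference scenario has 2,000 observations, three
fixed effects (−1.02, 2.65, −2.66), two Normal random coefficients (means
−2.87 and −1.25; spreads 1.64 and 0.93), intercept 2.19 and five noise
factors — coefficient magnitudes follow the estimates of the package's
reference recovery experiment (estimates-as-truth).  At those magnitudes
standard-normal covariates would push `exp(X'b)` to astronomic counts, so
the default covariate law is N(0, 0.2²), which keeps simulated counts in a
realistic 0–60 range; the scaled-down recovery scenario
(`SyntheticTruth.small_recovery`: 2 fixed effects 0.8/−0.6, one Normal
random coefficient 0.5 with spread 0.4, 3 noise factors) uses standard
normal covariates directly.

Two response modes:

* `single_draw` (default) — one count realization per observation.  The
  generating specification is then the correctly specified likelihood; both
  coefficients and scales are recovered with calibrated standard errors.
* `averaged` — the rounded mean count over `n_repetitions` (default 100)
  repeated count draws with the rates held fixed.  This stabilizes the
  response around each unit's rate but strips the count-level noise, and a
  fitted mixing scale is then systematically shrunk: the count model's own
  variance over-accounts for the spread of the data (measured: a true
  spread of 0.4 estimated at ~0.25 regardless of sample size or draw
  count).  The mode is retained for variance-reduction studies; recovery
  claims should use `single_draw`.

What the generator does **not** emulate about real crash data: correlated
covariates, spatial/temporal correlation between segments, panel structure,
excess zeros beyond what the mixing induces, and measurement error.  Passing
recovery tests therefore demonstrate internal consistency of estimator and
search, not robustness to those field conditions.

`score_recovery` reports model-type match, per-factor inclusion, spurious
noise inclusions, random-effect detection, and distribution identity —
recording a same-shape alternative (Normal vs Triangular/Uniform; Gamma vs
Lindley) as "shape-confusable" rather than a hard miss, since symmetric
short-tailed laws are empirically near-indistinguishable at moderate sample
sizes.  Coefficient accuracy is reported in estimated-standard-error units;
the headline 2-SE coverage check applies to the regression coefficients
(intercept, fixed effects, random means), with the scales assessed separately
for detection and sign, matching the coefficients/scales vocabulary of the
reported tables.

## Verification battery and problem sizes

The acceptance tests and `scripts/acceptance.py` run desk-scale versions of
the full battery; sizes were chosen so the whole battery runs on one CPU in
minutes:

* pmf normalization over a 36-point `(λ, φ)` grid (truncation 20,000) and
  `φ → 0` Poisson limits;
* intercept-only Poisson against the closed-form MLE;
* simulated likelihood (H=200) against 150-node Gauss–Hermite quadrature on
  a deterministic 20-observation fixture with spread 0.10 (see the accuracy
  caveat above for why larger spreads are not held to the same bound);
* oracle equivalence: 20 randomly restricted spaces of ≤ 64 specifications
  (n=80, H=30), each algorithm given 4×|space|+40 evaluations, compared with
  exhaustive enumeration at a 1e-3 BIC tolerance (different warm-start paths
  to the same repaired chromosome can differ by ~1e-6);
* recovery: SA with full decision sets on `small_recovery` data (n=500,
  H=25 during the search, OPG significance, drop-all repair, 1,200
  evaluations per run — the cooling schedule needs on the order of a
  thousand steps to pass from exploration to exploitation), 5 seeded runs in
  the test suite; plus 10 direct fits of the true specification (H=200) for
  coefficient coverage and scale detection.

## Known limitations

* No zero-inflated, COM-Poisson, NB-Lindley-mixture or Bayesian estimation;
  no spatial/temporal correlation, no correlated random parameters, no
  heterogeneity-in-means — the decision space is deliberately the one the
  three count laws and five mixing laws span.
* No categorical encoding or interaction terms: the analyst prepares the
  candidate-factor table.
* Time-based stopping makes the truncation point of a run hardware-
  dependent; use `max_evaluations` when bit-identical run lengths matter.
* BIC with the literal parameter count `ζ = Σ(α_k + r_k) + q + 1` is the
  selection objective; AIC and raw log-likelihood are selectable
  alternatives.
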