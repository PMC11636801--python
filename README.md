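# countspec

Automated, extensive hypothesis testing for count-data regression.

Crash-frequency analysts (and anyone modelling event counts per unit —
road-segment crashes, disease cases, equipment failures) face a combinatorial
modelling problem: which contributing factors enter the model, under which
variable transformation, which coefficients should be random to capture
unobserved heterogeneity, under which mixing distribution, and which count
law (Poisson, Negative Binomial, Generalized Poisson) fits the dispersion.
`countspec` treats that whole decision space as a discrete optimization
problem: candidate specifications are encoded as chromosomes, estimated by
maximum simulated likelihood, pruned to statistically significant terms, and
selected by minimum BIC with one of three metaheuristics — discrete harmony
search, simulated annealing, or discrete differential evolution.

## Model

For observation *i* with count *y_i* and transformed covariates *X_i*:

    lambda_i = exp(X_i' beta + offset_i)
    beta_k   = alpha_k * b_k + r_k * f_k(omega_k)        (random coefficients)
    y_i | lambda_i ~ Poisson | NB2(phi) | Generalized Poisson(phi)

`alpha_k` selects factor *k*, `r_k` declares its coefficient random under
mixing law `f_k` in {Gamma, Uniform, Normal, Triangular, Lindley} with scale
`omega_k`, and each selected factor may be transformed by one of
{ln, sqrt, exp, squared, cubed, factorial (as Γ(x+1)), arcsinh}.  The
simulated log-likelihood averages the conditional probability over H = 200
Halton draws per observation:

    ln L = sum_i ln[ (1/H) sum_h P(y_i | lambda_i^(h), m) ]

and the search minimizes `BIC = -2 ln L + zeta ln n`, where `zeta` counts the
estimated parameters (included factors + random scales + dispersion +
intercept).  Every proposal is *repaired* before it competes: insignificant
terms (two-sided p > 0.1) are pruned and the model re-fit until every
retained effect is significant.

## Worked example

Simulate a dataset with a known generating model (two fixed effects, one
Normal random coefficient, three pure-noise factors), then let simulated
annealing find the specification:

```python
import countspec as cs

truth = cs.SyntheticTruth.small_recovery(n_obs=500, seed=0)
data, truth = cs.generate(truth)

res = cs.fit(data, truth.true_spec())     # estimate the generating spec
print(res.summary())
```

```
Effect                  tau            Coeff   Std.Err       z Prob|z|>Z
------------------------------------------------------------------------
CONSTANT                no             0.477     0.044   10.79      0.00 ***
FIXED1                  no             0.826     0.034   24.11      0.00 ***
FIXED2                  no            -0.607     0.035  -17.35      0.00 ***
RANDOM1                 no             0.484     0.043   11.36      0.00 ***
Scale Parameters for Distributions of Random Parameters
RANDOM1 (Std. Dev.)     normal         0.411     0.043    9.66      0.00 ***
------------------------------------------------------------------------
Model Type              Poisson
Log-Likelihood          -891.97
BIC                     1815.01
***p<0.01; **p<0.05; *p<0.1
```

Every generating coefficient (0.5, 0.8, −0.6, 0.5; scale 0.4) is recovered
within two standard errors, and the Normal scale is strongly significant —
the data are genuinely overdispersed through the random coefficient.  A full
search over factors, transformations, mixing laws and model types:

```python
space  = cs.SearchSpace(data.factor_names)
config = cs.SearchConfig(algorithm="SA", objective="BIC", max_time=300, seed=0)
result = cs.run_search(data, space, config)
print(result.best_results.summary())
```

The same pipeline is scriptable from the shell (`countspec simulate`,
`countspec search --config run.yaml`, `countspec fit`, `countspec report`);
a search run archives its configuration, seed, convergence trajectory CSV and
best-model table so it can be reproduced exactly.

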