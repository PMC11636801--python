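"""Numeric engine: count pmfs, Halton draws, mixing deviates, simulated log-likelihood.

The observation-level model is a log-linear rate

    lambda_i = exp(X_i' beta + offset_i),

with the count Y_i distributed Poisson, Negative Binomial (NB2) or Famoye's
restricted Generalized Poisson given lambda_i.  A coefficient declared random
varies across observations as

    beta_k^(h) = b_k + deviate(f_k, omega_k; u_{i,h,k}),

where u are quasi-random uniforms from a Halton sequence (one prime base per
random dimension) and f_k is one of five mixing laws.  The simulated
log-likelihood averages the conditional probability over H draws before taking
logs:

    ln L = sum_i ln[ (1/H) sum_h P(y_i | lambda_i^(h), m) ].

With zero random parameters this reduces exactly to the closed-form
log-likelihood.  All pmf arithmetic is in log space; the linear predictor is
clamped so lambda stays within [1e-10, 1e10].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import gammaln, lambertw, logsumexp, ndtri

from .errors import ConfigurationError, ValidationError

__all__ = [
    "MODEL_TYPES",
    "DISTRIBUTIONS",
    "halton_sequence",
    "make_draws",
    "DrawSet",
    "deviate",
    "lindley_ppf",
    "lindley_cdf",
    "rate",
    "count_logpmf",
    "count_pmf",
    "simulated_loglik",
    "information_criterion",
]

#: Model types in the paper-stated order; Poisson has no dispersion parameter.
MODEL_TYPES: tuple[str, ...] = ("Poisson", "NB", "GP")

#: Mixing distributions for random parameters, in the stated order.
DISTRIBUTIONS: tuple[str, ...] = ("Gamma", "Uniform", "Normal", "Triangular", "Lindley")

_PRIMES = (2, 3, 5, 7, 11, 13, 17, 19, 23, 29, 31, 37, 41, 43, 47, 53, 59, 61, 67, 71)

_LOG_LAM_MIN = np.log(1e-10)
_LOG_LAM_MAX = np.log(1e10)


def has_dispersion(model: str) -> bool:
    """q of the parameter count: 0 for Poisson, 1 for NB/GP."""
    if model not in MODEL_TYPES:
        raise ConfigurationError(f"unknown model type {model!r}")
    return model != "Poisson"


def _is_prime(n: int) -> bool:
    if n < 2:
        return False
    return all(n % d for d in range(2, int(n**0.5) + 1))


def halton_sequence(base: int, n: int, burn_in: int = 0) -> np.ndarray:
    """Radical-inverse (van der Corput) sequence in a prime base.

    Returns entries ``burn_in + 1 .. burn_in + n`` of the sequence, all
    strictly inside (0, 1); deterministic across runs and platforms.
    """
    if not _is_prime(int(base)):
        raise ConfigurationError(f"Halton base must be prime, got {base}")
    if n < 1:
        raise ValidationError("n must be >= 1")
    idx = np.arange(burn_in + 1, burn_in + n + 1, dtype=np.int64)
    out = np.zeros(n)
    f = 1.0
    while idx.any():
        f /= base
        out += f * (idx % base)
        idx //= base
    return out


def make_draws(n_obs: int, hdraws: int, n_random: int, burn_in: int = 100) -> np.ndarray:
    """Uniform draw array of shape (n_obs, hdraws, n_random).

    Dimension d uses the d-th prime as its Halton base; observation i consumes
    the i-th consecutive block of ``hdraws`` points.  No scrambling, so the
    array is bit-identical for fixed bases and burn-in.
    """
    if n_random == 0:
        return np.empty((n_obs, hdraws, 0))
    if n_random > len(_PRIMES):
        raise ConfigurationError(f"at most {len(_PRIMES)} random parameters supported")
    cols = [
        halton_sequence(_PRIMES[d], n_obs * hdraws, burn_in).reshape(n_obs, hdraws)
        for d in range(n_random)
    ]
    return np.stack(cols, axis=-1)


@dataclass(frozen=True)
class DrawSet:
    """Quasi-random uniforms for simulated likelihood, plus their provenance."""

    hdraws: int
    burn_in: int = 100
    n_obs: int = 0
    n_random: int = 0
    uniforms: np.ndarray = field(default=None, repr=False)

    @classmethod
    def build(cls, n_obs: int, hdraws: int = 200, n_random: int = 0, burn_in: int = 100):
        u = make_draws(n_obs, hdraws, n_random, burn_in)
        return cls(hdraws=hdraws, burn_in=burn_in, n_obs=n_obs, n_random=n_random, uniforms=u)


def lindley_cdf(x, theta):
    """Lindley(theta) CDF, F(x) = 1 - (1 + theta x / (1 + theta)) e^{-theta x}."""
    x = np.asarray(x, dtype=float)
    return np.where(x <= 0, 0.0, 1.0 - (1.0 + theta * x / (1.0 + theta)) * np.exp(-theta * x))


def lindley_ppf(u, theta):
    """Lindley(theta) quantile by closed-form Lambert-W inversion.

    Q(u) = -1 - 1/theta - W_{-1}((1+theta)(u-1) e^{-(1+theta)}) / theta.
    """
    if theta <= 0:
        raise ValidationError("Lindley theta must be positive")
    u = np.asarray(u, dtype=float)
    arg = (1.0 + theta) * (u - 1.0) * np.exp(-(1.0 + theta))
    w = lambertw(arg, k=-1).real
    return -1.0 - 1.0 / theta - w / theta


def deviate(dist: str, omega: float, u) -> np.ndarray:
    """Deterministic map from uniform draw(s) to a mixing-law deviate.

    Normal/Uniform/Triangular are symmetric about zero with spread omega;
    Gamma(shape=omega, scale=1) and Lindley(theta=omega) enter as strictly
    positive, uncentered deviates (their long right tails are the point).
    """
    if omega < 0:
        raise ValidationError("scale parameter omega must be >= 0")
    u = np.asarray(u, dtype=float)
    if np.any(u <= 0) or np.any(u >= 1):
        raise ValidationError("uniform draws must lie strictly inside (0, 1)")
    if dist == "Normal":
        return omega * ndtri(u)
    if dist == "Uniform":
        return omega * (2.0 * u - 1.0)
    if dist == "Triangular":
        # inverse CDF of the symmetric triangular law on [-1, 1]
        t = np.where(u < 0.5, -1.0 + np.sqrt(2.0 * u), 1.0 - np.sqrt(2.0 * (1.0 - u)))
        return omega * t
    if dist == "Gamma":
        if omega == 0:
            return np.zeros_like(u)
        return stats.gamma.ppf(u, a=omega, scale=1.0)
    if dist == "Lindley":
        if omega == 0:
            raise ValidationError("Lindley theta must be positive")
        return lindley_ppf(u, omega)
    raise ConfigurationError(f"unknown mixing distribution {dist!r}")


def rate(X_i, beta, offset_i: float = 0.0) -> float:
    """Mean events lambda_i = exp(X_i . beta + offset_i), overflow-guarded."""
    lp = float(np.dot(X_i, beta)) + offset_i
    if not np.isfinite(lp):
        raise ValidationError("non-finite linear predictor")
    return float(np.exp(np.clip(lp, _LOG_LAM_MIN, _LOG_LAM_MAX)))


def count_logpmf(y, lam, phi: float, model: str):
    """Log pmf of the selected count model, vectorized over y/lam.

    Poisson ignores phi.  NB is the standard NB2 with r = 1/phi.  GP is
    Famoye's restricted Generalized Poisson; both collapse to Poisson as
    phi -> 0 and are evaluated in the Poisson branch below that threshold for
    numerical stability.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y < 0) or np.any(y != np.rint(y)):
        raise ValidationError("counts must be non-negative integers")
    lam = np.asarray(lam, dtype=float)
    if model == "Poisson" or (model in ("NB", "GP") and phi < 1e-10):
        return y * np.log(lam) - lam - gammaln(y + 1.0)
    if model == "NB":
        if phi <= 0:
            raise ValidationError("NB requires dispersion phi > 0")
        r = 1.0 / phi
        return (
            gammaln(r + y) - gammaln(r) - gammaln(y + 1.0)
            + r * (np.log(r) - np.log(r + lam))
            + y * (np.log(lam) - np.log(r + lam))
        )
    if model == "GP":
        if phi <= 0:
            raise ValidationError("GP requires dispersion phi > 0")
        one_p_py = 1.0 + phi * y
        one_p_pl = 1.0 + phi * lam
        return (
            y * (np.log(lam) - np.log(one_p_pl))
            + (y - 1.0) * np.log(one_p_py)
            - gammaln(y + 1.0)
            - lam * one_p_py / one_p_pl
        )
    raise ConfigurationError(f"unknown model type {model!r}")


def count_pmf(y, lam, phi: float, model: str):
    """Probability-scale pmf (thin wrapper over :func:`count_logpmf`)."""
    return np.exp(count_logpmf(y, lam, phi, model))


def simulated_loglik(
    y,
    X,
    b,
    model: str = "Poisson",
    phi: float = 0.0,
    random_cols=(),
    dists=(),
    omega=(),
    draws: np.ndarray | None = None,
    offset=None,
) -> float:
    """Simulated log-likelihood averaged over quasi-random coefficient draws.

    Parameters
    ----------
    y : counts, length n.
    X : design matrix (n, p) whose columns align with ``b``.
    b : mean coefficients, length p.
    random_cols : column indices of X whose coefficients are random.
    dists, omega : mixing law name and scale per random column, aligned with
        ``random_cols`` and with the last axis of ``draws``.
    draws : uniforms of shape (n, H, len(random_cols)); required when any
        coefficient is random.
    offset : optional log-exposure, length n.

    Returns ``-inf`` when the likelihood degenerates (the optimizer treats the
    step as rejected).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    b = np.asarray(b, dtype=float)
    lp = X @ b
    if offset is not None:
        lp = lp + np.asarray(offset, dtype=float)
    if len(random_cols) == 0:
        lam = np.exp(np.clip(lp, _LOG_LAM_MIN, _LOG_LAM_MAX))
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = np.sum(count_logpmf(y, lam, phi, model))
        return float(ll) if np.isfinite(ll) else -np.inf
    if draws is None:
        raise ValidationError("draws are required when random parameters are present")
    lp = lp[:, None] + np.zeros((1, draws.shape[1]))
    for d, (col, dist, w) in enumerate(zip(random_cols, dists, omega)):
        try:
            dev = deviate(dist, float(w), draws[:, :, d])
        except ValidationError:
            return -np.inf
        lp = lp + X[:, col][:, None] * dev
    lam = np.exp(np.clip(lp, _LOG_LAM_MIN, _LOG_LAM_MAX))
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = count_logpmf(y[:, None], lam, phi, model)   # (n, H)
        per_obs = logsumexp(logp, axis=1) - np.log(draws.shape[1])
        ll = float(np.sum(per_obs))
    return ll if np.isfinite(ll) else -np.inf


def information_criterion(loglik: float, zeta: int, n_obs: int, kind: str = "BIC") -> float:
    """Model-selection objective, oriented for minimization.

    BIC = -2 lnL + zeta ln n; AIC = -2 lnL + 2 zeta; LL = -lnL.
    ``zeta`` counts estimated parameters: one per included factor plus one per
    random scale, the dispersion when the model has one, and the intercept.
    """
    if n_obs < 1:
        raise ValidationError("n_obs must be >= 1")
    kind = kind.upper()
    if kind == "BIC":
        return -2.0 * loglik + zeta * np.log(n_obs)
    if kind == "AIC":
        return -2.0 * loglik + 2.0 * zeta
    if kind == "LL":
        return -loglik
    raise ConfigurationError(f"unknown objective kind {kind!r}; choose BIC, AIC or LL")
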