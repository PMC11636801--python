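"""Maximum simulated likelihood estimation for one specification, plus repair.

:class:`MixedCountModel` pairs a :class:`~countspec.data.CountData` with a
:class:`~countspec.specification.Specification`; :meth:`MixedCountModel.fit`
maximizes the (simulated) log-likelihood by quasi-Newton search from a
deterministic start and returns a :class:`MixedCountResults` carrying the
estimates, their standard errors, z statistics, two-sided normal p-values,
and the information criteria.

The objective gradient is computed analytically where the chain rule permits
— the simulated likelihood's score is a softmax-weighted average over draws of
the conditional score — with central finite differences only for the
coordinates whose deviate map has no convenient derivative (Gamma and Lindley
scales).  Standard errors come from the inverse of a central-difference
Hessian of the simulated log-likelihood ("hessian", the default) or from the
outer product of the analytic per-observation scores ("opg", much cheaper;
the search uses it for its significance decisions).

:func:`repair` is the significance-driven pruning loop used inside the
specification search: while any estimate is insignificant at ``alpha_sig``,
the worst offender(s) are removed — an insignificant random scale demotes the
factor to a fixed effect (its fixed part stays, honoring the
randomness-implies-inclusion constraint); an insignificant mean coefficient
removes the factor entirely — and the model is re-fit (warm-started from the
surviving estimates) until every retained term is significant or only the
intercept remains.  The intercept and the dispersion parameter are exempt.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats
from scipy.special import digamma, gammainc, gammaln, logsumexp, ndtri
from statsmodels.api import GLM
from statsmodels.genmod.families import Poisson
from statsmodels.tools.numdiff import approx_hess3

from .data import CountData, TransformedDesign, build_design
from .likelihoods import (
    DrawSet,
    deviate,
    has_dispersion,
    information_criterion,
)
from .specification import SearchSpace, Specification, normalize

__all__ = ["EstimationOptions", "MixedCountModel", "MixedCountResults", "fit", "repair"]

_PHI_MIN = 1e-6
_LOG_LAM_MIN = np.log(1e-10)
_LOG_LAM_MAX = np.log(1e10)
_BIG = 1e12

#: mixing laws whose deviate is linear in omega (deviate = omega * base)
_LINEAR_DISTS = {"Normal", "Uniform", "Triangular"}


@dataclass(frozen=True)
class EstimationOptions:
    """Optimizer and simulation settings for one fit."""

    hdraws: int = 200
    burn_in: int = 100
    bound: float = 1e5
    objective: str = "BIC"
    maxiter: int = 500
    gtol: float = 1e-6
    ftol: float = 1e-9
    restarts: int = 2
    omega_start: float = 0.1
    phi_start: float = 0.5
    se_method: str = "hessian"      # "hessian" | "opg"


@dataclass
class MixedCountResults:
    """Estimates and diagnostics for one fitted specification.

    ``term_labels`` orders the packed parameter vector: intercept, mean
    coefficients of included factors, random scales (omega), and the
    dispersion phi when the model has one.  ``params``, ``bse``, ``zvalues``
    and ``pvalues`` align with that order.
    """

    spec: Specification
    term_labels: tuple[str, ...]
    term_kinds: tuple[str, ...]      # "const" | "beta" | "omega" | "phi"
    params: np.ndarray
    bse: np.ndarray
    zvalues: np.ndarray
    pvalues: np.ndarray
    llf: float
    zeta: int
    nobs: int
    converged: bool
    se_method: str = "hessian"
    objective_kind: str = "BIC"
    niter: int = 0
    n_restarts: int = 0
    fit_time: float = 0.0
    design: TransformedDesign | None = field(default=None, repr=False)

    @property
    def bic(self) -> float:
        return information_criterion(self.llf, self.zeta, self.nobs, "BIC")

    @property
    def aic(self) -> float:
        return information_criterion(self.llf, self.zeta, self.nobs, "AIC")

    @property
    def objective(self) -> float:
        if not self.converged:
            return np.inf
        return information_criterion(self.llf, self.zeta, self.nobs, self.objective_kind)

    def coef(self, label: str) -> float:
        return float(self.params[self.term_labels.index(label)])

    def se(self, label: str) -> float:
        return float(self.bse[self.term_labels.index(label)])

    def pvalue(self, label: str) -> float:
        return float(self.pvalues[self.term_labels.index(label)])

    def summary(self) -> str:
        from .report import render_report

        return render_report(self)


def _infeasible_results(spec, design, nobs, kind) -> MixedCountResults:
    return MixedCountResults(
        spec=spec, term_labels=(), term_kinds=(), params=np.empty(0),
        bse=np.empty(0), zvalues=np.empty(0), pvalues=np.empty(0),
        llf=-np.inf, zeta=0, nobs=nobs, converged=False,
        se_method="none", objective_kind=kind, design=design,
    )


class MixedCountModel:
    """Count regression with optional random coefficients, estimated by MSL.

    Parameters
    ----------
    data : CountData
    spec : Specification
        Which factors enter, how each is transformed, which coefficients are
        random (and under which mixing law), and the count model type.
    space : SearchSpace, optional
        Used only to normalize the specification; a bare spec is accepted.
    options : EstimationOptions
    """

    def __init__(self, data: CountData, spec: Specification,
                 space: SearchSpace | None = None,
                 options: EstimationOptions = EstimationOptions()):
        if space is not None:
            spec = normalize(spec, space)
        self.data = data
        self.spec = spec
        self.options = options
        self.design = build_design(data, spec, c=options.bound)
        self.random_names = spec.random_factors
        sel = self.design.names
        # indices of random factors among exog columns (intercept is column 0)
        self.random_cols = tuple(1 + sel.index(k) for k in self.random_names)
        self.random_dists = tuple(
            spec.dist[spec.factor_names.index(k)] for k in self.random_names
        )
        self.model_type = spec.model
        self.nrand = len(self.random_names)
        self.draws = (
            DrawSet.build(data.nobs, options.hdraws, self.nrand, options.burn_in)
            if self.nrand else None
        )
        self._X = self.design.exog()
        self._y = data.response.astype(float)
        self._gammaln_y = gammaln(self._y + 1.0)
        self._offset = data.offset
        # per-dimension deviate bases for linear-in-omega mixing laws, and a
        # bounded cache for the Gamma/Lindley quantiles keyed by omega
        self._bases: dict[int, np.ndarray] = {}
        self._dev_cache: dict[tuple[int, float], np.ndarray] = {}
        self._warm: dict[int, tuple[float, np.ndarray]] = {}
        if self.draws is not None:
            for d, dist in enumerate(self.random_dists):
                u = self.draws.uniforms[:, :, d]
                if dist == "Normal":
                    self._bases[d] = ndtri(u)
                elif dist == "Uniform":
                    self._bases[d] = 2.0 * u - 1.0
                elif dist == "Triangular":
                    self._bases[d] = np.where(
                        u < 0.5, -1.0 + np.sqrt(2.0 * u), 1.0 - np.sqrt(2.0 * (1.0 - u))
                    )

    # -- parameter packing ---------------------------------------------------
    @property
    def term_labels(self) -> tuple[str, ...]:
        labels = ["CONSTANT", *self.design.names]
        labels += [f"{k} (Std. Dev.)" for k in self.random_names]
        if has_dispersion(self.model_type):
            labels.append("DISPERSION")
        return tuple(labels)

    @property
    def term_kinds(self) -> tuple[str, ...]:
        kinds = ["const"] + ["beta"] * len(self.design.names)
        kinds += ["omega"] * self.nrand
        if has_dispersion(self.model_type):
            kinds.append("phi")
        return tuple(kinds)

    @property
    def zeta(self) -> int:
        """Parameter count: sum_k (alpha_k + r_k) + dispersion + intercept."""
        return (
            sum(self.spec.alpha) + sum(self.spec.r)
            + int(has_dispersion(self.model_type)) + 1
        )

    @property
    def n_params(self) -> int:
        return (1 + len(self.design.names) + self.nrand
                + int(has_dispersion(self.model_type)))

    def _unpack(self, params):
        p = len(self.design.names) + 1
        b = params[:p]
        omega = params[p:p + self.nrand]
        phi = params[p + self.nrand] if has_dispersion(self.model_type) else 0.0
        return b, omega, phi

    # -- deviates ------------------------------------------------------------
    def _dev(self, d: int, omega_d: float) -> np.ndarray:
        """Deviates for random dimension d at scale omega_d.

        Linear laws scale a precomputed base.  The positive laws (Gamma,
        Lindley) need a quantile inversion per scale value; because the
        optimizer moves the scale a little at a time, the quantiles are
        refined by Newton iterations on the CDF warm-started from the
        previous scale's deviates (exact inversion is used for the first call
        and for any point Newton fails to converge).
        """
        dist = self.random_dists[d]
        if dist in _LINEAR_DISTS:
            return omega_d * self._bases[d]
        omega_d = float(omega_d)
        key = (d, omega_d)
        out = self._dev_cache.get(key)
        if out is not None:
            return out
        u = self.draws.uniforms[:, :, d]
        warm = self._warm.get(d)
        if warm is not None and abs(omega_d - warm[0]) <= 0.5 * (0.1 + warm[0]):
            x0 = warm[1]
        else:
            x0 = _quantile_guess(dist, omega_d, u, self._bases.setdefault(d, ndtri(u)))
        out = _newton_quantiles(dist, omega_d, u, x0)
        if out is None:
            out = deviate(dist, omega_d, u)
        if len(self._dev_cache) > 128:
            self._dev_cache.clear()
        self._dev_cache[key] = out
        self._warm[d] = (omega_d, out)
        return out

    def _dev_grad(self, d: int, omega_d: float) -> np.ndarray:
        """d deviate / d omega per draw.

        Linear laws: the base deviate.  Lindley: implicit-function derivative
        of the quantile, dQ/dtheta = -(dF/dtheta)/f evaluated at Q.  Gamma
        (shape parameter): same construction with the shape-derivative of the
        regularized incomplete gamma taken by a tight central difference on
        gammainc (direct C evaluations, no quantile iterations).
        """
        dist = self.random_dists[d]
        if dist in _LINEAR_DISTS:
            return self._bases[d]
        x = self._dev(d, omega_d)
        if dist == "Lindley":
            th = omega_d
            with np.errstate(invalid="ignore", over="ignore", divide="ignore"):
                ratio = (1.0 + th * x / (1.0 + th) - 1.0 / (1.0 + th) ** 2) \
                    * x * (1.0 + th) / (th**2 * (1.0 + x))
                out = -ratio
            return np.where(np.isfinite(out), out, 0.0)
        # Gamma, shape a = omega, scale 1
        a = omega_d
        h = 1e-6 * max(1.0, a)
        dF = (gammainc(a + h, x) - gammainc(max(a - h, 1e-12), x)) / (h + min(h, a - 1e-12))
        with np.errstate(divide="ignore", over="ignore"):
            log_pdf = (a - 1.0) * np.log(x) - x - gammaln(a)
            pdf = np.exp(log_pdf)
        out = -dF / np.maximum(pdf, 1e-300)
        return np.where(np.isfinite(out), out, 0.0)

    # -- likelihood core -----------------------------------------------------
    def _lambda(self, b, omega):
        lp = self._X @ b
        if self._offset is not None:
            lp = lp + self._offset
        lp = lp[:, None]
        if self.nrand:
            for d, col in enumerate(self.random_cols):
                lp = lp + self._X[:, col][:, None] * self._dev(d, omega[d])
        clipped = np.clip(lp, _LOG_LAM_MIN, _LOG_LAM_MAX)
        mask = (lp > _LOG_LAM_MIN) & (lp < _LOG_LAM_MAX)
        return np.exp(clipped), mask

    def _logpmf(self, lam, phi):
        """Conditional log pmf per (observation, draw)."""
        y = self._y[:, None]
        m = self.model_type
        if m == "Poisson" or phi < 1e-10:
            return y * np.log(lam) - lam - self._gammaln_y[:, None]
        if m == "NB":
            r = 1.0 / phi
            log_r_lam = np.log(r + lam)
            return (
                (gammaln(r + y) - gammaln(r) - self._gammaln_y[:, None])
                + r * (np.log(r) - log_r_lam)
                + y * (np.log(lam) - log_r_lam)
            )
        one_p_py = 1.0 + phi * y
        one_p_pl = 1.0 + phi * lam
        return (
            y * (np.log(lam) - np.log(one_p_pl))
            + (y - 1.0) * np.log(one_p_py)
            - self._gammaln_y[:, None]
            - lam * one_p_py / one_p_pl
        )

    def _per_obs(self, params) -> np.ndarray:
        b, omega, phi = self._unpack(np.asarray(params, dtype=float))
        if np.any(omega < 0) or (has_dispersion(self.model_type) and phi <= 0):
            return np.full(self.data.nobs, -np.inf)
        lam, _ = self._lambda(b, omega)
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            logp = self._logpmf(lam, float(phi))
            return logsumexp(logp, axis=1) - np.log(lam.shape[1])

    def loglike(self, params) -> float:
        per_obs = self._per_obs(params)
        ll = float(np.sum(per_obs))
        return ll if np.isfinite(ll) else -np.inf

    def loglikeobs(self, params) -> np.ndarray:
        """Per-observation log-likelihood contributions."""
        return self._per_obs(params)

    def _conditional_scores(self, lam, phi):
        """g = lam * dlogpmf/dlam and (for NB/GP) dlogpmf/dphi, per (obs, draw)."""
        y = self._y[:, None]
        m = self.model_type
        if m == "Poisson" or phi < 1e-10:
            return y - lam, None
        if m == "NB":
            r = 1.0 / phi
            g = y - lam * (r + y) / (r + lam)
            dldr = (
                digamma(r + y) - digamma(r) + np.log(r) + 1.0
                - np.log(r + lam) - (r + y) / (r + lam)
            )
            return g, -(r * r) * dldr
        one_p_py = 1.0 + phi * y
        one_p_pl = 1.0 + phi * lam
        g = y - y * phi * lam / one_p_pl - lam * one_p_py / one_p_pl**2
        dphi = (
            -y * lam / one_p_pl
            + y * (y - 1.0) / one_p_py
            - lam * (y - lam) / one_p_pl**2
        )
        return g, dphi

    def score_obs(self, params) -> np.ndarray:
        """Analytic per-observation score of the simulated log-likelihood,
        shape (nobs, n_params); Gamma/Lindley scale columns by central
        finite differences."""
        params = np.asarray(params, dtype=float)
        b, omega, phi = self._unpack(params)
        lam, mask = self._lambda(b, omega)
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            logp = self._logpmf(lam, float(phi))
            w = np.exp(logp - logsumexp(logp, axis=1, keepdims=True))
        g, dphi = self._conditional_scores(lam, float(phi))
        g = np.where(mask, g, 0.0)
        wg = np.sum(w * g, axis=1)                       # (n,)
        p_mean = len(self.design.names) + 1
        cols = [self._X[:, j] * wg for j in range(p_mean)]
        for d in range(self.nrand):
            cols.append(self._X[:, self.random_cols[d]]
                        * np.sum(w * g * self._dev_grad(d, omega[d]), axis=1))
        if has_dispersion(self.model_type):
            cols.append(np.sum(w * dphi, axis=1))
        return np.column_stack(cols)

    def _value_and_grad(self, params):
        """(negative loglik, negative gradient) for the optimizer."""
        params = np.asarray(params, dtype=float)
        b, omega, phi = self._unpack(params)
        if np.any(omega < 0) or (has_dispersion(self.model_type) and phi <= 0):
            return _BIG, np.zeros_like(params)
        lam, mask = self._lambda(b, omega)
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            logp = self._logpmf(lam, float(phi))
            lse = logsumexp(logp, axis=1)
            ll = float(np.sum(lse) - self.data.nobs * np.log(lam.shape[1]))
            if not np.isfinite(ll):
                return _BIG, np.zeros_like(params)
            w = np.exp(logp - lse[:, None])
        g, dphi = self._conditional_scores(lam, float(phi))
        g = np.where(mask, g, 0.0)
        wg = np.sum(w * g, axis=1)
        grad = [self._X.T @ wg]
        omega_grad = np.empty(self.nrand)
        for d in range(self.nrand):
            omega_grad[d] = float(
                self._X[:, self.random_cols[d]]
                @ np.sum(w * g * self._dev_grad(d, omega[d]), axis=1)
            )
        grad.append(omega_grad)
        if has_dispersion(self.model_type):
            grad.append([float(np.sum(w * dphi))])
        grad = np.concatenate([np.atleast_1d(np.asarray(x, dtype=float)) for x in grad])
        if not np.all(np.isfinite(grad)):
            return _BIG, np.zeros_like(params)
        return -ll, -grad

    def _start_params(self) -> np.ndarray:
        """Deterministic start: Poisson fixed-effect solution, omegas at 0.1,
        phi at 0.5."""
        try:
            glm = GLM(self.data.response, self._X, family=Poisson(), offset=self._offset)
            b0 = np.asarray(glm.fit(maxiter=100).params, dtype=float)
            if not np.all(np.isfinite(b0)):
                raise ValueError
        except Exception:
            b0 = np.zeros(self._X.shape[1])
            b0[0] = np.log(max(self.data.response.mean(), 1e-3))
        start = list(b0)
        for dist in self.random_dists:
            start.append(1.0 if dist == "Lindley" else self.options.omega_start)
        if has_dispersion(self.model_type):
            start.append(self.options.phi_start)
        return np.asarray(start)

    def _bounds(self):
        p = len(self.design.names) + 1
        bounds = [(None, None)] * p
        for dist in self.random_dists:
            # Lindley's theta -> 0 sends the deviates to infinity and the
            # Gamma quantile degenerates at shape 0, so the positive-deviate
            # laws are kept away from zero; the symmetric laws admit omega = 0.
            lo = 1e-3 if dist in ("Lindley", "Gamma") else 0.0
            bounds.append((lo, None))
        if has_dispersion(self.model_type):
            bounds.append((_PHI_MIN, None))
        return bounds

    # -- fitting -------------------------------------------------------------
    def fit(self, start_params=None) -> MixedCountResults:
        t0 = time.perf_counter()
        kind = self.options.objective
        if not self.design.feasible:
            return _infeasible_results(self.spec, self.design, self.data.nobs, kind)
        start = np.asarray(start_params, dtype=float) if start_params is not None \
            else self._start_params()
        bounds = self._bounds()
        best = None
        n_restarts = 0
        for attempt in range(self.options.restarts + 1):
            x0 = start if attempt == 0 else _perturb(start, attempt)
            x0 = np.array([np.clip(v, lo if lo is not None else -np.inf,
                                   hi if hi is not None else np.inf)
                           for v, (lo, hi) in zip(x0, bounds)])
            res = optimize.minimize(
                self._value_and_grad, x0, jac=True, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": self.options.maxiter,
                         "ftol": self.options.ftol, "gtol": self.options.gtol},
            )
            ok = np.isfinite(res.fun) and res.fun < _BIG / 10
            if ok and (best is None or res.fun < best.fun):
                best = res
            if ok and res.success:
                break
            n_restarts = attempt
        if best is None:
            return _infeasible_results(self.spec, self.design, self.data.nobs, kind)

        params = np.asarray(best.x, dtype=float)
        llf = -float(best.fun)
        bse, se_method = self._standard_errors(params)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = params / bse
        pvals = 2.0 * stats.norm.sf(np.abs(z))
        pvals = np.where(np.isfinite(pvals), pvals, 1.0)
        z = np.where(np.isfinite(z), z, 0.0)
        return MixedCountResults(
            spec=self.spec, term_labels=self.term_labels, term_kinds=self.term_kinds,
            params=params, bse=bse, zvalues=z, pvalues=pvals,
            llf=llf, zeta=self.zeta, nobs=self.data.nobs,
            converged=bool(np.isfinite(llf)), se_method=se_method,
            objective_kind=kind, niter=int(best.nit), n_restarts=n_restarts,
            fit_time=time.perf_counter() - t0, design=self.design,
        )

    def _opg_bse(self, params):
        S = self.score_obs(params)
        cov = np.linalg.inv(S.T @ S)
        diag = np.diag(cov)
        if np.all(np.isfinite(diag)) and np.all(diag > 0):
            return np.sqrt(diag)
        return None

    def _standard_errors(self, params):
        """Inverse curvature of the simulated log-likelihood; unavailable SEs
        surface as NaN (p-values become 1 so repair removes the weakest
        terms)."""
        if self.options.se_method == "opg":
            try:
                bse = self._opg_bse(params)
                if bse is not None:
                    return bse, "opg"
            except Exception:
                pass
        try:
            H = approx_hess3(params, lambda p: -self.loglike(p))
            cov = np.linalg.inv(H)
            diag = np.diag(cov)
            if np.all(np.isfinite(diag)) and np.all(diag > 0):
                return np.sqrt(diag), "hessian"
        except Exception:
            pass
        try:
            bse = self._opg_bse(params)
            if bse is not None:
                return bse, "opg"
        except Exception:
            pass
        return np.full(params.size, np.nan), "unavailable"


def _quantile_guess(dist: str, omega: float, u: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Cheap analytic starting point for the positive-law quantile solve.

    Gamma: Wilson-Hilferty for moderate shapes, the small-shape power
    asymptotic otherwise.  Lindley: the Exponential(theta) quantile (a lower
    bound with the right tail rate).  ``z`` is ndtri(u).
    """
    if dist == "Gamma":
        a = omega
        if a >= 0.2:
            t = 1.0 - 1.0 / (9.0 * a) + z / (3.0 * np.sqrt(a))
            x0 = a * np.maximum(t, 0.05) ** 3
        else:
            with np.errstate(over="ignore"):
                x0 = np.exp((np.log(u) + gammaln(a + 1.0)) / a)
        return np.maximum(x0, 1e-12)
    return np.maximum(-np.log1p(-u) / omega, 1e-12)


def _newton_quantiles(dist: str, omega: float, u: np.ndarray, x0: np.ndarray):
    """Solve F(x; omega) = u by damped Newton.

    Convergence is measured on the quantile itself (relative step below
    1e-10), so the inversion is as tight as exact evaluation and the
    simulated objective stays smooth in omega.  Returns None if any point
    fails to converge (caller falls back to exact inversion); non-finite
    start points (quantiles at u ~ 1) pass through unchanged.
    """
    shape = x0.shape
    x0 = x0.ravel()
    uf = u.ravel()
    finite = np.isfinite(x0)
    out = x0.copy()
    x = np.maximum(x0[finite], 1e-300)
    t = uf[finite]
    idx = np.arange(x.size)
    for _ in range(30):
        if idx.size == 0:
            break
        xa, ta = x[idx], t[idx]
        with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
            if dist == "Gamma":
                F = gammainc(omega, xa)
                pdf = np.exp((omega - 1.0) * np.log(xa) - xa - gammaln(omega))
            else:  # Lindley
                e = np.exp(-omega * xa)
                F = 1.0 - (1.0 + omega * xa / (1.0 + omega)) * e
                pdf = omega**2 / (1.0 + omega) * (1.0 + xa) * e
            step = (F - ta) / np.maximum(pdf, 1e-300)
        x_new = np.where(xa - step > 0, xa - step, 0.5 * xa)
        done = np.abs(x_new - xa) < 1e-10 * (1.0 + np.abs(xa))
        x[idx] = x_new
        idx = idx[~done]
    else:
        if idx.size:
            return None
    if idx.size:
        return None
    out[finite] = x
    return out.reshape(shape)


def _perturb(start: np.ndarray, attempt: int) -> np.ndarray:
    # deterministic restart jitter so refits stay bit-reproducible
    rng = np.random.default_rng(7_654_321 + attempt)
    return start * (1.0 + 0.2 * rng.standard_normal(start.size)) + 0.05 * attempt


def fit(data: CountData, spec: Specification, space: SearchSpace | None = None,
        options: EstimationOptions = EstimationOptions(),
        start_params=None) -> MixedCountResults:
    """Convenience wrapper: build the model and fit it."""
    return MixedCountModel(data, spec, space=space, options=options).fit(start_params)


def repair(data: CountData, spec: Specification, space: SearchSpace | None = None,
           alpha_sig: float = 0.1, drop_all: bool = False,
           options: EstimationOptions = EstimationOptions()) -> MixedCountResults:
    """Significance-driven pruning: fit, drop insignificant terms, re-fit.

    ``drop_all=False`` (default) removes the single term with the largest
    p-value each pass — the conservative reading, since dropping everything at
    once can discard jointly significant terms; ``drop_all=True`` removes all
    offenders per pass.  Returns the final fitted model; its ``spec`` is the
    repaired chromosome that replaces the original proposal inside the search
    algorithms.  On non-convergence mid-loop the best converged predecessor is
    returned.
    """
    current = normalize(spec, space) if space is not None else spec
    best_prev: MixedCountResults | None = None
    warm: dict[str, float] | None = None
    max_steps = 2 * len(current.factor_names) + 2
    for _ in range(max_steps):
        model = MixedCountModel(data, current, space=space, options=options)
        start = None
        if warm is not None:
            start = np.array([warm.get(lab, dflt) for lab, dflt in
                              zip(model.term_labels, model._start_params())])
        results = model.fit(start_params=start)
        if not results.converged:
            return best_prev if best_prev is not None else results
        best_prev = results
        offenders = [
            (p, lab, kind)
            for p, lab, kind in zip(results.pvalues, results.term_labels, results.term_kinds)
            if kind in ("beta", "omega") and (p > alpha_sig or not np.isfinite(p))
        ]
        if not offenders:
            return results
        offenders.sort(key=lambda t: (-(t[0] if np.isfinite(t[0]) else 2.0), t[1]))
        to_drop = offenders if drop_all else offenders[:1]
        current = _drop_terms(current, to_drop)
        if space is not None:
            current = normalize(current, space)
        warm = dict(zip(results.term_labels, results.params))
    return best_prev


def _drop_terms(spec: Specification, offenders) -> Specification:
    alpha, r = list(spec.alpha), list(spec.r)
    for _, label, kind in offenders:
        if kind == "omega":
            name = label.replace(" (Std. Dev.)", "")
            r[spec.factor_names.index(name)] = 0
        else:
            i = spec.factor_names.index(label)
            alpha[i] = 0
            r[i] = 0
    return replace(spec, alpha=tuple(alpha), r=tuple(r))
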