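"""Estimation: fit, standard errors, analytic gradient, and repair."""

import numpy as np
import pytest
from statsmodels.tools.numdiff import approx_fprime

import countspec as cs
from countspec.model import MixedCountModel


def _spec(names, alpha, r=None, dist=None, tau=None, model="Poisson"):
    k = len(names)
    return cs.Specification(
        tuple(names), tuple(alpha),
        tuple(r or (0,) * k),
        tuple(dist or ("Gamma",) * k),
        tuple(tau or ("no",) * k),
        model,
    )


class TestFit:
    def test_intercept_only_poisson_oracle(self):
        # closed form: lambda-hat = mean(y) = 2, lnL = sum y ln 2 - 6 - ln 12
        data = cs.CountData(np.array([1, 2, 3]), {})
        res = cs.fit(data, _spec((), ()))
        assert res.converged
        assert res.coef("CONSTANT") == pytest.approx(np.log(2), abs=1e-6)
        assert res.llf == pytest.approx(-4.326024, abs=1e-5)
        assert res.zeta == 1
        assert res.objective == pytest.approx(res.bic)

    def test_matches_statsmodels_poisson_glm(self, poisson_data):
        import statsmodels.api as sm

        spec = _spec(("A", "B", "C"), (1, 1, 0))
        res = cs.fit(poisson_data, spec)
        X = np.column_stack(
            [np.ones(poisson_data.nobs), poisson_data.factors["A"], poisson_data.factors["B"]]
        )
        ref = sm.GLM(poisson_data.response, X, family=sm.families.Poisson()).fit()
        np.testing.assert_allclose(res.params, ref.params, atol=1e-6)
        np.testing.assert_allclose(res.bse, ref.bse, rtol=1e-3)
        assert res.llf == pytest.approx(ref.llf, abs=1e-8)

    def test_same_inputs_give_identical_results(self, poisson_data):
        spec = _spec(("A", "B", "C"), (1, 1, 0), r=(1, 0, 0), dist=("Normal",) * 3)
        r1 = cs.fit(poisson_data, spec, options=cs.EstimationOptions(hdraws=50))
        r2 = cs.fit(poisson_data, spec, options=cs.EstimationOptions(hdraws=50))
        np.testing.assert_array_equal(r1.params, r2.params)
        np.testing.assert_array_equal(r1.bse, r2.bse)
        assert r1.llf == r2.llf

    def test_infeasible_design_returns_inf_objective(self, poisson_data):
        res = cs.fit(poisson_data, _spec(("A", "B", "C"), (1, 0, 0), tau=("ln", "no", "no")))
        assert not res.converged
        assert res.objective == np.inf

    def test_nb_detects_overdispersion(self):
        rng = np.random.default_rng(11)
        n = 400
        x = rng.normal(size=n)
        lam = np.exp(0.5 + 0.6 * x)
        y = rng.poisson(rng.gamma(shape=2.0, scale=lam / 2.0))  # NB with phi=0.5
        data = cs.CountData(y, {"X": x})
        res = cs.fit(data, _spec(("X",), (1,), model="NB"))
        assert res.converged
        assert res.coef("DISPERSION") == pytest.approx(0.5, abs=0.2)
        assert res.zeta == 3                      # intercept + X + dispersion

    def test_spurious_random_parameter_shrinks_to_zero(self):
        # equidispersed Poisson data: the scale of a declared Normal random
        # parameter should estimate near zero and cost BIC relative to the
        # fixed-effect specification
        rng = np.random.default_rng(21)
        n = 500
        x = rng.normal(size=n)
        y = rng.poisson(np.exp(0.4 + 0.5 * x))
        data = cs.CountData(y, {"X": x})
        fixed = cs.fit(data, _spec(("X",), (1,)))
        mixed = cs.fit(data, _spec(("X",), (1,), r=(1,), dist=("Normal",)),
                       options=cs.EstimationOptions(hdraws=100))
        assert mixed.coef("X (Std. Dev.)") < 0.1
        assert mixed.bic > fixed.bic

    def test_offset_is_honored(self):
        rng = np.random.default_rng(3)
        n = 300
        expo = rng.uniform(0.5, 4.0, size=n)
        y = rng.poisson(2.0 * expo)
        data = cs.CountData(y, {}, offset=np.log(expo))
        res = cs.fit(data, _spec((), ()))
        assert res.coef("CONSTANT") == pytest.approx(np.log(2.0), abs=0.1)

    def test_zeta_counts_parameters(self, poisson_data):
        spec = _spec(("A", "B", "C"), (1, 1, 1), r=(1, 0, 0),
                     dist=("Normal",) * 3, model="NB")
        m = MixedCountModel(poisson_data, spec)
        # 3 included + 1 random + dispersion + intercept
        assert m.zeta == 3 + 1 + 1 + 1


class TestGradient:
    @pytest.mark.parametrize(
        "model_type, dists",
        [
            ("Poisson", ("Normal", "Gamma")),
            ("NB", ("Triangular", "Lindley")),
            ("GP", ("Uniform", "Gamma")),
        ],
    )
    def test_analytic_gradient_matches_numeric(self, poisson_data, model_type, dists):
        spec = _spec(("A", "B", "C"), (1, 1, 1),
                     r=(1, 1, 0), dist=(dists[0], dists[1], "Gamma"), model=model_type)
        m = MixedCountModel(poisson_data, spec, options=cs.EstimationOptions(hdraws=40))
        p0 = m._start_params() + 0.05
        _, grad = m._value_and_grad(p0)
        num = approx_fprime(p0, lambda p: -m.loglike(p), centered=True)
        np.testing.assert_allclose(grad, num, rtol=1e-5, atol=1e-6)

    def test_score_obs_sums_to_gradient(self, poisson_data):
        spec = _spec(("A", "B", "C"), (1, 1, 0), r=(1, 0, 0),
                     dist=("Lindley", "Gamma", "Gamma"), model="NB")
        m = MixedCountModel(poisson_data, spec, options=cs.EstimationOptions(hdraws=40))
        p0 = m._start_params() + 0.03
        _, grad = m._value_and_grad(p0)
        np.testing.assert_allclose(m.score_obs(p0).sum(axis=0), -grad, rtol=1e-6, atol=1e-8)

    def test_engine_matches_reference_simulated_loglik(self, poisson_data):
        spec = _spec(("A", "B", "C"), (1, 1, 0), r=(1, 1, 0),
                     dist=("Normal", "Lindley", "Gamma"), model="GP")
        m = MixedCountModel(poisson_data, spec, options=cs.EstimationOptions(hdraws=60))
        p0 = m._start_params() + 0.02
        b, omega, phi = m._unpack(p0)
        ref = cs.simulated_loglik(
            poisson_data.response, m._X, b, model="GP", phi=float(phi),
            random_cols=m.random_cols, dists=m.random_dists, omega=omega,
            draws=m.draws.uniforms,
        )
        assert m.loglike(p0) == pytest.approx(ref, abs=1e-7)


class TestRepair:
    def test_all_significant_leaves_spec_unchanged(self, poisson_data):
        spec = _spec(("A", "B", "C"), (1, 1, 0))
        res = cs.repair(poisson_data, spec, alpha_sig=0.1)
        assert res.spec.alpha == (1, 1, 0)
        assert all(
            p <= 0.1 for p, k in zip(res.pvalues, res.term_kinds) if k in ("beta", "omega")
        )

    def test_insignificant_factor_dropped(self, poisson_data):
        # C is pure noise: it must be pruned, the real effects retained
        spec = _spec(("A", "B", "C"), (1, 1, 1))
        res = cs.repair(poisson_data, spec, alpha_sig=0.1)
        assert res.spec.alpha == (1, 1, 0)

    def test_insignificant_scale_demotes_to_fixed_effect(self):
        # no heterogeneity in the data: the random declaration on X is
        # dropped but its fixed effect is retained
        rng = np.random.default_rng(8)
        n = 400
        x = rng.normal(size=n)
        y = rng.poisson(np.exp(0.5 + 0.7 * x))
        data = cs.CountData(y, {"X": x})
        spec = _spec(("X",), (1,), r=(1,), dist=("Normal",))
        res = cs.repair(data, spec, alpha_sig=0.1,
                        options=cs.EstimationOptions(hdraws=100))
        assert res.spec.alpha == (1,)
        assert res.spec.r == (0,)

    def test_repair_terminates_at_intercept_for_pure_noise(self):
        rng = np.random.default_rng(17)
        n = 150
        data = cs.CountData(
            rng.poisson(1.0, size=n), {"N1": rng.normal(size=n), "N2": rng.normal(size=n)}
        )
        res = cs.repair(data, _spec(("N1", "N2"), (1, 1)), alpha_sig=0.05)
        assert sum(res.spec.alpha) <= 1  # at most one lucky noise survivor

    def test_drop_all_removes_every_offender_per_pass(self, poisson_data):
        spec = _spec(("A", "B", "C"), (1, 1, 1))
        res = cs.repair(poisson_data, spec, alpha_sig=0.1, drop_all=True)
        assert res.spec.alpha[2] == 0
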