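"""Numeric engine: Halton draws, mixing deviates, pmfs, simulated likelihood."""

import numpy as np
import pytest
from scipy import stats
from scipy.stats import qmc

import countspec as cs
from countspec.likelihoods import lindley_cdf, lindley_ppf


class TestHalton:
    def test_base2_prefix(self):
        np.testing.assert_allclose(
            cs.halton_sequence(2, 4), [0.5, 0.25, 0.75, 0.125], rtol=0, atol=1e-15
        )

    def test_base3_prefix(self):
        np.testing.assert_allclose(
            cs.halton_sequence(3, 3), [1 / 3, 2 / 3, 1 / 9], rtol=1e-15
        )

    def test_burn_in_shifts_sequence(self):
        full = cs.halton_sequence(5, 30)
        np.testing.assert_array_equal(cs.halton_sequence(5, 20, burn_in=10), full[10:])

    def test_matches_scipy_qmc(self):
        # scipy's unscrambled Halton starts at index 0 (the zero point);
        # the radical inverse here starts at index 1
        engine = qmc.Halton(d=1, scramble=False, seed=None)
        ref = engine.random(41).ravel()[1:]
        np.testing.assert_allclose(cs.halton_sequence(2, 40), ref, atol=1e-14)

    def test_open_interval_and_determinism(self):
        for base in (2, 3, 5, 7):
            seq = cs.halton_sequence(base, 500, burn_in=100)
            assert np.all((seq > 0) & (seq < 1))
            np.testing.assert_array_equal(seq, cs.halton_sequence(base, 500, burn_in=100))

    def test_non_prime_base_rejected(self):
        with pytest.raises(cs.ConfigurationError):
            cs.halton_sequence(4, 10)

    def test_draw_array_shape(self):
        u = cs.make_draws(7, 11, 3)
        assert u.shape == (7, 11, 3)
        assert np.all((u > 0) & (u < 1))


class TestDeviates:
    def test_symmetric_medians_are_zero(self):
        for dist in ("Normal", "Uniform", "Triangular"):
            assert cs.deviate(dist, 1.0, np.array([0.5]))[0] == pytest.approx(0.0, abs=1e-12)

    def test_uniform_example(self):
        assert cs.deviate("Uniform", 2.0, np.array([0.75]))[0] == pytest.approx(1.0)

    def test_triangular_quantile(self):
        # symmetric triangular on [-1,1]: F(-1/2) = 1/8
        assert cs.deviate("Triangular", 1.0, np.array([0.125]))[0] == pytest.approx(-0.5)

    def test_gamma_matches_scipy(self):
        u = np.linspace(0.05, 0.95, 10)
        np.testing.assert_allclose(
            cs.deviate("Gamma", 0.7, u), stats.gamma.ppf(u, a=0.7), rtol=1e-10
        )

    def test_lindley_quantile_inverts_cdf(self):
        u = np.linspace(0.01, 0.99, 25)
        for theta in (0.3, 1.0, 2.5):
            x = lindley_ppf(u, theta)
            np.testing.assert_allclose(lindley_cdf(x, theta), u, atol=1e-10)

    def test_lindley_mean_oracle(self):
        # closed-form Lindley mean (theta+2)/(theta(theta+1)) against the
        # empirical mean of quantile deviates over 1e5 Halton draws
        u = cs.halton_sequence(2, 100_000, burn_in=100)
        for theta in (0.5, 1.0, 2.0):
            mean = cs.deviate("Lindley", theta, u).mean()
            exact = (theta + 2) / (theta * (theta + 1))
            assert mean == pytest.approx(exact, rel=2e-3)

    def test_negative_scale_rejected(self):
        with pytest.raises(cs.ValidationError):
            cs.deviate("Normal", -0.1, np.array([0.5]))

    def test_draws_must_be_interior(self):
        with pytest.raises(cs.ValidationError):
            cs.deviate("Normal", 1.0, np.array([0.0]))


class TestRate:
    def test_identity_cases(self):
        assert cs.rate(np.array([0.0]), np.array([1.0])) == pytest.approx(1.0)
        assert cs.rate(np.array([1.0]), np.array([np.log(3)])) == pytest.approx(3.0)

    def test_monotone_in_coefficient(self):
        x = np.array([2.0])
        assert cs.rate(x, np.array([0.5])) > cs.rate(x, np.array([0.4]))

    def test_offset_enters_linearly(self):
        assert cs.rate(np.array([0.0]), np.array([0.0]), offset_i=np.log(7)) == pytest.approx(7.0)


class TestCountPmf:
    def test_closed_form_examples(self):
        assert cs.count_pmf(0, 1.0, 0.0, "Poisson") == pytest.approx(np.exp(-1), rel=1e-12)
        assert cs.count_pmf(0, 1.0, 1.0, "NB") == pytest.approx(0.5, rel=1e-12)
        assert cs.count_pmf(3, 2.0, 1e-12, "GP") == pytest.approx(
            stats.poisson.pmf(3, 2.0), rel=1e-8
        )

    def test_nb_matches_scipy(self):
        y = np.arange(0, 30)
        lam, phi = 3.0, 0.4
        r = 1 / phi
        ref = stats.nbinom.pmf(y, r, r / (r + lam))
        np.testing.assert_allclose(cs.count_pmf(y, lam, phi, "NB"), ref, rtol=1e-10)

    @pytest.mark.parametrize("model", ["Poisson", "NB", "GP"])
    @pytest.mark.parametrize("lam", [0.3, 1.0, 4.0, 8.0])
    @pytest.mark.parametrize("phi", [0.05, 0.5, 1.5])
    def test_normalization(self, model, lam, phi):
        # GP keeps a long geometric-like tail when phi*lam is large, so the
        # truncation point is generous
        y = np.arange(0, 20_000)
        total = cs.count_pmf(y, lam, phi, model).sum()
        assert total == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize("model", ["NB", "GP"])
    def test_poisson_limit(self, model):
        y = np.arange(0, 51)
        for lam in (0.5, 2.0, 8.0):
            diff = np.abs(
                cs.count_pmf(y, lam, 1e-8, model) - stats.poisson.pmf(y, lam)
            )
            assert diff.max() < 1e-6

    def test_negative_count_rejected(self):
        with pytest.raises(cs.ValidationError):
            cs.count_pmf(-1, 1.0, 0.0, "Poisson")


class TestSimulatedLoglik:
    def _fixture(self, n=15, seed=3):
        rng = np.random.default_rng(seed)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.poisson(np.exp(0.2 + 0.4 * X[:, 1]))
        return y, X

    def test_zero_random_equals_closed_form(self):
        y, X = self._fixture()
        b = np.array([0.2, 0.4])
        ll = cs.simulated_loglik(y, X, b, model="Poisson")
        lam = np.exp(X @ b)
        np.testing.assert_allclose(ll, stats.poisson.logpmf(y, lam).sum(), rtol=1e-12)

    def test_single_median_draw_equals_fixed_effect(self):
        # H=1 with u=0.5: the Normal deviate is exactly zero
        y, X = self._fixture()
        b = np.array([0.2, 0.4])
        draws = np.full((len(y), 1, 1), 0.5)
        ll = cs.simulated_loglik(
            y, X, b, random_cols=(1,), dists=("Normal",), omega=(0.7,), draws=draws
        )
        np.testing.assert_allclose(ll, cs.simulated_loglik(y, X, b), rtol=1e-12)

    def test_permutation_invariance(self):
        y, X = self._fixture(n=20)
        b = np.array([0.1, 0.3])
        draws = cs.make_draws(len(y), 64, 1)
        ll = cs.simulated_loglik(
            y, X, b, random_cols=(1,), dists=("Normal",), omega=(0.5,), draws=draws
        )
        perm = np.random.default_rng(0).permutation(len(y))
        ll_p = cs.simulated_loglik(
            y[perm], X[perm], b, random_cols=(1,), dists=("Normal",),
            omega=(0.5,), draws=draws[perm],
        )
        np.testing.assert_allclose(ll, ll_p, rtol=1e-12)

    def test_factor_order_invariance(self):
        rng = np.random.default_rng(9)
        n = 18
        X = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
        y = rng.poisson(np.exp(0.1 + 0.3 * X[:, 1] - 0.2 * X[:, 2]))
        draws = cs.make_draws(n, 32, 2)
        ll = cs.simulated_loglik(
            y, X, np.array([0.1, 0.3, -0.2]), random_cols=(1, 2),
            dists=("Normal", "Uniform"), omega=(0.4, 0.6), draws=draws,
        )
        X2 = X[:, [0, 2, 1]]
        ll2 = cs.simulated_loglik(
            y, X2, np.array([0.1, -0.2, 0.3]), random_cols=(2, 1),
            dists=("Normal", "Uniform"), omega=(0.4, 0.6), draws=draws,
        )
        np.testing.assert_allclose(ll, ll2, rtol=1e-12)


class TestInformationCriterion:
    def test_examples(self):
        assert cs.information_criterion(-100, 5, 100, "BIC") == pytest.approx(
            200 + 5 * np.log(100)
        )
        assert cs.information_criterion(-100, 5, 100, "AIC") == pytest.approx(210)
        assert cs.information_criterion(-100, 5, 100, "LL") == pytest.approx(100)

    def test_bad_inputs(self):
        with pytest.raises(cs.ValidationError):
            cs.information_criterion(-1, 1, 0, "BIC")
        with pytest.raises(cs.ConfigurationError):
            cs.information_criterion(-1, 1, 10, "WAIC")
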