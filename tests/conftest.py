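"""Shared fixtures: small deterministic datasets and search spaces."""

import numpy as np
import pytest

import countspec as cs


@pytest.fixture(scope="session")
def poisson_data():
    """80 observations, two real effects (A: +0.8, B: -0.5) and one pure-noise
    column C; counts are a single Poisson draw per observation."""
    rng = np.random.default_rng(42)
    n = 80
    x = {k: rng.normal(size=n) for k in ("A", "B", "C")}
    lam = np.exp(0.3 + 0.8 * x["A"] - 0.5 * x["B"])
    return cs.CountData(rng.poisson(lam), x, name="poisson-fixture")


@pytest.fixture(scope="session")
def tiny_space():
    """Fixed-effects-only space over {A, B, C} with identity transforms and
    two model types: 16 feasible specifications."""
    ps = cs.PreSpecification(
        random={k: 0 for k in "ABC"},
        allowed_models=("Poisson", "NB"),
        allowed_transformations=("no",),
    )
    return cs.SearchSpace(("A", "B", "C"), prespec=ps)


@pytest.fixture(scope="session")
def full_space():
    """Unrestricted space over {A, B, C}."""
    return cs.SearchSpace(("A", "B", "C"))


@pytest.fixture()
def fast_options():
    return cs.EstimationOptions(hdraws=50, se_method="opg", ftol=1e-7, maxiter=100)
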