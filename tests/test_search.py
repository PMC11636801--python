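"""Metaheuristics: operators, temperature calibration, cache, determinism, oracle."""

import numpy as np
import pytest

import countspec as cs
from countspec.search import Evaluator, de_index, initial_temperature, pitch_adjust


def small_config(**kw):
    defaults = dict(
        max_time=300.0, seed=0, max_evaluations=120,
        estimation=cs.EstimationOptions(hdraws=30, se_method="opg", ftol=1e-7, maxiter=80),
    )
    defaults.update(kw)
    return cs.SearchConfig(**defaults)


class TestOperators:
    @pytest.mark.parametrize(
        "current, mode, pai, expected",
        [(1, 5, 2, 3), (5, 5, 7, 5), (4, 2, 5, 2), (0, 7, 3, 3), (6, 0, 2, 4)],
    )
    def test_pitch_adjust(self, current, mode, pai, expected):
        assert pitch_adjust(current, mode, pai, 8) == expected

    @pytest.mark.parametrize(
        "lp, l1, l2, pai, size, expected",
        [(2, 4, 1, 1, 5, 0), (3, 2, 2, 4, 9, 3), (0, 1, 3, 2, 5, 1)],
    )
    def test_de_index_modulo(self, lp, l1, l2, pai, size, expected):
        assert de_index(lp, l1, l2, pai, size) == expected

    def test_initial_temperature_example(self):
        # mean gap 20 at chi=0.5: T0 = 20/ln 2, and an average-sized uphill
        # move is accepted with probability exactly chi
        t0 = initial_temperature([100.0, 120.0], 0.5)
        assert t0 == pytest.approx(28.8539, abs=1e-3)
        assert np.exp(-20.0 / t0) == pytest.approx(0.5, abs=1e-12)

    def test_initial_temperature_needs_two_finite(self):
        with pytest.raises(cs.ConfigurationError):
            initial_temperature([np.inf, 100.0], 0.5)

    def test_chi_near_one_is_capped(self):
        assert np.isfinite(initial_temperature([0.0, 1e6], 1 - 1e-15))


class TestEvaluator:
    def test_cache_one_fit_for_repeated_spec(self, poisson_data, tiny_space):
        ev = Evaluator(poisson_data, tiny_space, small_config())
        spec = cs.enumerate_space(tiny_space)[3]
        first = ev.evaluate(spec)
        second = ev.evaluate(spec)
        assert ev.n_evaluations == 2 and ev.n_fits == 1
        assert first is second

    def test_infeasible_transform_evaluates_to_inf(self, poisson_data, full_space):
        ev = Evaluator(poisson_data, full_space, small_config())
        spec = cs.Specification(("A", "B", "C"), (1, 0, 0), (0, 0, 0),
                                ("Gamma",) * 3, ("ln", "no", "no"), "Poisson")
        assert ev.evaluate(spec)[0] == np.inf

    def test_objective_equals_information_criterion_of_model(self, poisson_data, tiny_space):
        ev = Evaluator(poisson_data, tiny_space, small_config())
        obj, spec, results = ev.evaluate(cs.enumerate_space(tiny_space)[5])
        assert obj == pytest.approx(
            cs.information_criterion(results.llf, results.zeta, results.nobs, "BIC")
        )

    def test_repaired_chromosome_replaces_proposal(self, poisson_data, tiny_space):
        ev = Evaluator(poisson_data, tiny_space, small_config())
        proposal = cs.Specification(("A", "B", "C"), (1, 1, 1), (0, 0, 0),
                                    ("Gamma",) * 3, ("no",) * 3, "Poisson")
        _, repaired, _ = ev.evaluate(proposal)
        assert repaired.alpha == (1, 1, 0)     # the noise factor C is pruned


class TestAlgorithms:
    @pytest.mark.parametrize("algorithm", ["HS", "SA", "DE"])
    def test_best_sequence_monotone_and_best_is_min(self, poisson_data, tiny_space, algorithm):
        res = cs.run_search(poisson_data, tiny_space, small_config(algorithm=algorithm))
        bests = [row[2] for row in res.trajectory]
        assert all(b2 <= b1 for b1, b2 in zip(bests, bests[1:]))
        assert res.best_objective == bests[-1]
        assert res.best_results is not None
        assert res.best_objective == pytest.approx(res.best_results.objective)

    @pytest.mark.parametrize("algorithm", ["HS", "SA", "DE"])
    def test_fixed_seed_reproduces_trajectory(self, poisson_data, tiny_space, algorithm):
        cfg = small_config(algorithm=algorithm, seed=7, max_evaluations=60)
        r1 = cs.run_search(poisson_data, tiny_space, cfg)
        r2 = cs.run_search(poisson_data, tiny_space, cfg)
        assert r1.trajectory == r2.trajectory
        assert r1.best_spec == r2.best_spec
        np.testing.assert_array_equal(r1.best_results.params, r2.best_results.params)

    @pytest.mark.parametrize("algorithm", ["HS", "SA", "DE"])
    def test_tiny_space_reaches_exhaustive_minimum(self, poisson_data, tiny_space, algorithm):
        ev = Evaluator(poisson_data, tiny_space, small_config())
        oracle = min(ev.evaluate(s)[0] for s in cs.enumerate_space(tiny_space))
        res = cs.run_search(poisson_data, tiny_space, small_config(algorithm=algorithm, seed=1))
        assert res.best_objective == pytest.approx(oracle)

    def test_initial_solution_seeds_trajectory(self, poisson_data, tiny_space):
        initial = cs.Specification(("A", "B", "C"), (1, 0, 0), (0, 0, 0),
                                   ("Gamma",) * 3, ("no",) * 3, "Poisson")
        cfg = small_config(algorithm="SA", max_evaluations=40)
        res = cs.simulated_annealing(poisson_data, tiny_space, cfg, initial=initial)
        ev = Evaluator(poisson_data, tiny_space, cfg)
        assert res.trajectory[0][1] == pytest.approx(ev.evaluate(initial)[0])

    def test_de_requires_population_of_four(self, poisson_data, tiny_space):
        with pytest.raises(cs.ConfigurationError, match="PS"):
            cs.differential_evolution(poisson_data, tiny_space, small_config(ps=3))

    def test_sa_first_plateau_acceptance_near_chi(self, poisson_data, tiny_space):
        # by construction of T0, an average-sized uphill move is accepted
        # with probability chi; the overall first-plateau acceptance rate
        # (downhill always accepted) should exceed chi and stay near it
        cfg = small_config(algorithm="SA", seed=3, max_evaluations=100, t_steps=60)
        res = cs.simulated_annealing(poisson_data, tiny_space, cfg)
        frame = res.trajectory_frame()
        plateau = frame[(frame.iteration >= 1) & (frame.iteration <= 60)]
        rate = plateau.accepted.mean()
        assert 0.35 <= rate <= 0.95

    def test_hyperparameter_validation(self):
        with pytest.raises(cs.ConfigurationError):
            cs.SearchConfig(hmcr=1.5)
        with pytest.raises(cs.ConfigurationError):
            cs.SearchConfig(t_alpha=1.0)
        with pytest.raises(cs.ConfigurationError):
            cs.SearchConfig(max_time=0)
        with pytest.raises(cs.ConfigurationError):
            cs.SearchConfig(algorithm="GA")

    def test_trajectory_csv_round_trip(self, poisson_data, tiny_space, tmp_path):
        import pandas as pd

        res = cs.run_search(poisson_data, tiny_space, small_config(max_evaluations=30))
        path = tmp_path / "trajectory.csv"
        res.save_trajectory(path)
        frame = pd.read_csv(path)
        assert list(frame.columns) == ["iteration", "incumbent", "best", "accepted"]
        assert len(frame) == len(res.trajectory)
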