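"""Specification search: harmony search, simulated annealing, differential evolution.

All three algorithms minimize the same objective (BIC by default) over the
discrete chromosome space, share a time/evaluation-based stopping criterion,
an evaluation cache keyed on the canonical chromosome (one MSL fit dominates
runtime, so duplicates must never be re-fit), and per-iteration trajectory
logging of the incumbent and the best-so-far objective.  Every proposal is
repaired before it enters a population or memory: the repaired chromosome
replaces the proposal.
"""

from __future__ import annotations

import csv
import time
from dataclasses import dataclass, field

import numpy as np

from .data import CountData
from .errors import ConfigurationError
from .model import EstimationOptions, MixedCountResults, repair
from .specification import (
    SearchSpace,
    Specification,
    mutate,
    normalize,
    random_specification,
)

__all__ = [
    "SearchConfig",
    "SearchResult",
    "Evaluator",
    "pitch_adjust",
    "de_index",
    "initial_temperature",
    "harmony_search",
    "simulated_annealing",
    "differential_evolution",
    "run_search",
]

_T0_CAP = 1e12


@dataclass
class SearchConfig:
    """Hyperparameters for the three solution algorithms.

    Defaults: SA cooling 0.975 with 5 steps per temperature (the
    recommendation that emerged from the hyperparameter sweep); HS memory 20,
    HMCR 0.8, PAR 0.5; DE population 20, CR 0.6; pitch-adjustment index 2.
    ``max_time`` is wall-clock seconds checked between evaluations; an
    optional ``max_evaluations`` budget gives bit-reproducible run lengths.
    """

    algorithm: str = "SA"
    objective: str = "BIC"
    max_time: float = 60.0
    seed: int = 0
    max_evaluations: int | None = None
    # harmony search
    hms: int = 20
    hmcr: float = 0.8
    par: float = 0.5
    pai: int = 2
    classical_par: bool = False   # True: adjust when U < PAR (classical HS direction)
    # simulated annealing
    t_alpha: float = 0.975
    t_steps: int = 5
    chi: float = 0.5
    calibration_size: int = 20
    # differential evolution
    ps: int = 20
    cr: float = 0.6
    # repair / estimation
    alpha_sig: float = 0.1
    drop_all: bool = False
    estimation: EstimationOptions = field(default_factory=EstimationOptions)

    def __post_init__(self):
        checks = [
            (0 < self.hmcr < 1, "HMCR must be in (0,1)"),
            (0 < self.par < 1, "PAR must be in (0,1)"),
            (0 < self.cr <= 1, "CR must be in (0,1]"),
            (0 < self.t_alpha < 1, "Talpha must be in (0,1)"),
            (self.t_steps >= 1, "Ts must be >= 1"),
            (self.pai >= 1, "PAI must be >= 1"),
            (self.max_time > 0, "MaxTime must be > 0"),
            (0 < self.chi < 1, "chi must be in (0,1)"),
            (self.hms >= 1, "HMS must be >= 1"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigurationError(msg)
        if self.algorithm.upper() not in ("HS", "SA", "DE"):
            raise ConfigurationError("algorithm must be one of HS, SA, DE")
        self.algorithm = self.algorithm.upper()
        if self.estimation.objective != self.objective:
            self.estimation = EstimationOptions(
                **{**self.estimation.__dict__, "objective": self.objective}
            )


@dataclass
class SearchResult:
    """Outcome of one search run."""

    best_results: MixedCountResults | None
    best_spec: Specification | None
    best_objective: float
    trajectory: list[tuple[int, float, float, bool]]  # (iteration, incumbent, best, accepted)
    n_evaluations: int
    wall_time: float
    algorithm: str
    seed: int

    def trajectory_frame(self):
        import pandas as pd

        return pd.DataFrame(self.trajectory,
                            columns=["iteration", "incumbent", "best", "accepted"])

    def save_trajectory(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["iteration", "incumbent", "best", "accepted"])
            w.writerows(self.trajectory)


class Evaluator:
    """Normalize -> cache lookup -> fit -> repair -> objective.

    The cache maps canonical chromosomes to (objective, repaired spec,
    results); both the proposal and its repaired form are cached, so a spec
    evaluated twice costs one fit.  Infeasible or non-convergent proposals
    evaluate to +inf.
    """

    def __init__(self, data: CountData, space: SearchSpace, config: SearchConfig):
        self.data = data
        self.space = space
        self.config = config
        self.cache: dict[tuple, tuple[float, Specification, MixedCountResults | None]] = {}
        self.n_evaluations = 0
        self.n_fits = 0

    def evaluate(self, spec: Specification):
        spec = normalize(spec, self.space)
        key = spec.key()
        self.n_evaluations += 1
        if key in self.cache:
            return self.cache[key]
        self.n_fits += 1
        results = repair(self.data, spec, space=self.space,
                         alpha_sig=self.config.alpha_sig,
                         drop_all=self.config.drop_all,
                         options=self.config.estimation)
        if results is None or not results.converged:
            entry = (np.inf, spec, None)
        else:
            repaired = normalize(results.spec, self.space)
            entry = (float(results.objective), repaired, results)
            self.cache[repaired.key()] = entry
        self.cache[key] = entry
        return entry


def de_index(l_p: int, l_p1: int, l_p2: int, pai: int, set_size: int) -> int:
    """Differential index move: (l_p + PAI (l_p' - l_p'')) mod |L_j|."""
    return (l_p + pai * (l_p1 - l_p2)) % set_size


def pitch_adjust(current_index: int, mode_index: int, pai: int, set_size: int) -> int:
    """Shift an index toward the modal index by at most PAI positions."""
    diff = mode_index - current_index
    step = int(np.sign(diff)) * min(abs(diff), pai)
    out = current_index + step
    if not 0 <= out < set_size:
        raise ValueError("pitch-adjusted index out of range")
    return out


def initial_temperature(sample_objectives, chi: float) -> float:
    """T0 = mean |successive objective difference| / (-ln chi).

    Calibrated so a Metropolis move of average uphill size is accepted with
    probability ~chi at the start.  The sample comes from evaluating a random
    initial population.
    """
    objs = [o for o in np.asarray(sample_objectives, dtype=float) if np.isfinite(o)]
    if len(objs) < 2:
        raise ConfigurationError(
            "temperature calibration needs >= 2 finite objectives; "
            "use a larger calibration population"
        )
    diffs = np.abs(np.diff(objs))
    de = float(np.mean(diffs))
    if de == 0.0:
        de = 1.0  # flat sample: any positive temperature is equivalent
    return min(de / (-np.log(chi)), _T0_CAP)


class _Clock:
    def __init__(self, config: SearchConfig, evaluator: Evaluator):
        self.t0 = time.monotonic()
        self.config = config
        self.evaluator = evaluator

    def expired(self) -> bool:
        if time.monotonic() - self.t0 >= self.config.max_time:
            return True
        me = self.config.max_evaluations
        return me is not None and self.evaluator.n_evaluations >= me

    @property
    def elapsed(self) -> float:
        return time.monotonic() - self.t0


def _result(best_entry, trajectory, evaluator, clock, config) -> SearchResult:
    obj, spec, results = best_entry
    return SearchResult(
        best_results=results, best_spec=spec, best_objective=obj,
        trajectory=trajectory, n_evaluations=evaluator.n_evaluations,
        wall_time=clock.elapsed, algorithm=config.algorithm, seed=config.seed,
    )


def harmony_search(data: CountData, space: SearchSpace, config: SearchConfig,
                   initial: Specification | None = None) -> SearchResult:
    """Discrete harmony search over the chromosome space.

    Memory members are recombined gene-wise with probability HMCR; per the
    stated trigger, a uniform draw >= PAR applies the index-based pitch
    adjustment toward the memory's per-gene modal index (switchable to the
    classical < PAR direction).
    """
    rng = np.random.default_rng(config.seed)
    evaluator = Evaluator(data, space, config)
    clock = _Clock(config, evaluator)
    members = []
    if initial is not None:
        members.append(evaluator.evaluate(initial))
    while len(members) < config.hms and not clock.expired():
        members.append(evaluator.evaluate(random_specification(space, rng)))
    if not members:
        members.append(evaluator.evaluate(random_specification(space, rng)))
    members.sort(key=lambda e: e[0])
    best = members[0]
    trajectory = [(0, members[0][0], best[0], True)]
    genes = space.genes
    it = 0
    while not clock.expired():
        it += 1
        index_mat = np.array([space.to_indices(m[1]) for m in members])
        candidate = []
        for j, (_, _, opts) in enumerate(genes):
            if rng.random() <= config.hmcr:
                idx = int(index_mat[rng.integers(len(members)), j])
            else:
                idx = int(rng.integers(len(opts)))
            u = rng.random()
            adjust = (u < config.par) if config.classical_par else (u >= config.par)
            if adjust and len(opts) > 1:
                counts = np.bincount(index_mat[:, j], minlength=len(opts))
                mode = int(np.argmax(counts))
                idx = pitch_adjust(idx, mode, config.pai, len(opts))
            candidate.append(idx)
        entry = evaluator.evaluate(space.from_indices(candidate))
        accepted = entry[0] < members[-1][0]
        if accepted:
            members[-1] = entry
            members.sort(key=lambda e: e[0])
        if entry[0] < best[0]:
            best = entry
        trajectory.append((it, entry[0], best[0], accepted))
    return _result(best, trajectory, evaluator, clock, config)


def simulated_annealing(data: CountData, space: SearchSpace, config: SearchConfig,
                        initial: Specification | None = None) -> SearchResult:
    """Simulated annealing with calibrated initial temperature.

    A seeded random population of repaired specifications calibrates T0 so an
    average uphill move is accepted with probability chi; the walk then takes
    ``t_steps`` mutate-propose-accept steps per temperature plateau, cooling
    geometrically by ``t_alpha``.  Neighbors are U(1,3)-gene mutations;
    acceptance is Metropolis.
    """
    rng = np.random.default_rng(config.seed)
    evaluator = Evaluator(data, space, config)
    clock = _Clock(config, evaluator)
    pop = []
    while len(pop) < config.calibration_size and not clock.expired():
        pop.append(evaluator.evaluate(random_specification(space, rng)))
    finite = [e for e in pop if np.isfinite(e[0])]
    if initial is not None:
        current = evaluator.evaluate(initial)
    elif finite:
        current = min(finite, key=lambda e: e[0])
    else:
        current = evaluator.evaluate(random_specification(space, rng))
    try:
        t = initial_temperature([e[0] for e in pop], config.chi)
    except ConfigurationError:
        t = max(abs(current[0]), 1.0) if np.isfinite(current[0]) else 1.0
    best = min([current] + finite, key=lambda e: e[0]) if finite else current
    trajectory = [(0, current[0], best[0], True)]
    it = 0
    while not clock.expired():
        for _ in range(config.t_steps):
            if clock.expired():
                break
            it += 1
            neighbor = evaluator.evaluate(mutate(current[1], space, rng))
            delta = neighbor[0] - current[0]
            if delta <= 0:
                accepted = True
            elif not np.isfinite(delta) or t <= 0:
                accepted = False
            else:
                accepted = rng.random() < np.exp(-delta / t)
            if accepted:
                current = neighbor
            if neighbor[0] < best[0]:
                best = neighbor
            trajectory.append((it, current[0], best[0], accepted))
        t *= config.t_alpha
    return _result(best, trajectory, evaluator, clock, config)


def differential_evolution(data: CountData, space: SearchSpace, config: SearchConfig,
                           initial: Specification | None = None) -> SearchResult:
    """Discrete differential evolution with modulo index arithmetic.

    For each member p and gene j, with probability CR the trial index is
    (l_p + PAI (l_p' - l_p'')) mod |L_j| for distinct random members p', p'';
    the trial replaces p when strictly better.
    """
    if config.ps < 4:
        raise ConfigurationError("DE needs population size PS >= 4")
    rng = np.random.default_rng(config.seed)
    evaluator = Evaluator(data, space, config)
    clock = _Clock(config, evaluator)
    pop = []
    if initial is not None:
        pop.append(evaluator.evaluate(initial))
    while len(pop) < config.ps and not clock.expired():
        pop.append(evaluator.evaluate(random_specification(space, rng)))
    while len(pop) < 4:
        pop.append(evaluator.evaluate(random_specification(space, rng)))
    best = min(pop, key=lambda e: e[0])
    trajectory = [(0, pop[0][0], best[0], True)]
    genes = space.genes
    it = 0
    while not clock.expired():
        for p in range(len(pop)):
            if clock.expired():
                break
            it += 1
            others = [q for q in range(len(pop)) if q != p]
            p1, p2 = rng.choice(others, size=2, replace=False)
            lp = space.to_indices(pop[p][1])
            l1 = space.to_indices(pop[int(p1)][1])
            l2 = space.to_indices(pop[int(p2)][1])
            trial = list(lp)
            for j, (_, _, opts) in enumerate(genes):
                if rng.random() < config.cr:
                    trial[j] = de_index(lp[j], l1[j], l2[j], config.pai, len(opts))
            entry = evaluator.evaluate(space.from_indices(trial))
            accepted = entry[0] < pop[p][0]
            if accepted:
                pop[p] = entry
            if entry[0] < best[0]:
                best = entry
            trajectory.append((it, pop[p][0], best[0], accepted))
    return _result(best, trajectory, evaluator, clock, config)


_ALGORITHMS = {
    "HS": harmony_search,
    "SA": simulated_annealing,
    "DE": differential_evolution,
}


def run_search(data: CountData, space: SearchSpace, config: SearchConfig,
               initial: Specification | None = None) -> SearchResult:
    """Dispatch to the configured algorithm."""
    return _ALGORITHMS[config.algorithm](data, space, config, initial=initial)
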