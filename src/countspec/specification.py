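"""Specification chromosome, constraints, pre-specification, and neighborhood moves.

A :class:`Specification` encodes one candidate model: per candidate factor an
inclusion flag ``alpha_k``, a randomness flag ``r_k``, a mixing-distribution
gene ``f_k`` and a transformation gene ``tau_k``, plus the model-type selector.
The constraint system is: a random coefficient implies inclusion of its fixed
effect (``alpha_k >= r_k``); exactly one model type is active; analyst
pre-specifications clamp individual genes or restrict the decision sets.

:func:`normalize` maps any raw chromosome to a canonical feasible encoding
(inactive genes are zeroed to a canonical value) so that equal models compare
equal — this canonical form is the identity used by the evaluation cache and
harmony-memory duplicate detection.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .data import TRANSFORMATIONS
from .errors import ConfigurationError
from .likelihoods import DISTRIBUTIONS, MODEL_TYPES

__all__ = [
    "Specification",
    "PreSpecification",
    "SearchSpace",
    "random_specification",
    "normalize",
    "mutate",
    "mutate_indices",
    "enumerate_space",
    "count_space",
]


@dataclass(frozen=True)
class Specification:
    """One point of the model search space (the chromosome)."""

    factor_names: tuple[str, ...]
    alpha: tuple[int, ...]          # inclusion flags
    r: tuple[int, ...]              # randomness flags
    dist: tuple[str, ...]           # mixing law per factor (meaningful iff r=1)
    tau: tuple[str, ...]            # transformation per factor (meaningful iff alpha=1)
    model: str = "Poisson"

    def __post_init__(self):
        k = len(self.factor_names)
        for name, val in (("alpha", self.alpha), ("r", self.r), ("dist", self.dist), ("tau", self.tau)):
            if len(val) != k:
                raise ConfigurationError(f"{name} must have one entry per factor")
        if self.model not in MODEL_TYPES:
            raise ConfigurationError(f"unknown model type {self.model!r}")

    @property
    def included(self) -> tuple[str, ...]:
        return tuple(k for k, a in zip(self.factor_names, self.alpha) if a)

    @property
    def random_factors(self) -> tuple[str, ...]:
        return tuple(k for k, rr in zip(self.factor_names, self.r) if rr)

    def key(self) -> tuple:
        """Canonical identity tuple (assumes the spec is normalized)."""
        return (self.factor_names, self.alpha, self.r, self.dist, self.tau, self.model)

    def describe(self) -> str:
        parts = []
        for k, a, rr, f, t in zip(self.factor_names, self.alpha, self.r, self.dist, self.tau):
            if not a:
                continue
            s = k if t == "no" else f"{t}({k})"
            if rr:
                s += f"~{f}"
            parts.append(s)
        return f"{self.model}: 1 + " + " + ".join(parts) if parts else f"{self.model}: 1"


@dataclass
class PreSpecification:
    """Analyst clamps on the chromosome and global decision-set restrictions.

    ``include``/``random`` map factor name -> 0/1 (absent means free);
    ``distribution``/``transformation`` force the corresponding gene;
    ``model`` forces the model type; the ``allowed_*`` tuples restrict the
    ordered decision sets globally.
    """

    include: dict[str, int] = field(default_factory=dict)
    random: dict[str, int] = field(default_factory=dict)
    distribution: dict[str, str] = field(default_factory=dict)
    transformation: dict[str, str] = field(default_factory=dict)
    model: str | None = None
    allowed_models: tuple[str, ...] = MODEL_TYPES
    allowed_distributions: tuple[str, ...] = DISTRIBUTIONS
    allowed_transformations: tuple[str, ...] = TRANSFORMATIONS

    def validate(self, factor_names):
        known = set(factor_names)
        for mapping, label in (
            (self.include, "include"), (self.random, "random"),
            (self.distribution, "distribution"), (self.transformation, "transformation"),
        ):
            for k in mapping:
                if k not in known:
                    raise ConfigurationError(f"pre-specification {label} names unknown factor {k!r}")
        for k, v in self.random.items():
            if v == 1 and self.include.get(k, 1) == 0:
                raise ConfigurationError(
                    f"factor {k!r}: forced exclusion contradicts forced random parameter"
                )
        for m in (self.model,) if self.model else ():
            if m not in self.allowed_models:
                raise ConfigurationError(f"forced model {m!r} is not in the allowed set")
        for k, d in self.distribution.items():
            if d not in self.allowed_distributions:
                raise ConfigurationError(f"forced distribution {d!r} for {k!r} not allowed")
        for k, t in self.transformation.items():
            if t not in self.allowed_transformations:
                raise ConfigurationError(f"forced transformation {t!r} for {k!r} not allowed")
        if not self.allowed_models or not self.allowed_distributions or not self.allowed_transformations:
            raise ConfigurationError("decision sets must be non-empty")


# Gene descriptor: (kind, factor index or None, ordered option tuple)
_Gene = tuple[str, int | None, tuple]


@dataclass
class SearchSpace:
    """The decision space: factor universe, decision sets, clamps, bound c.

    Decision-set ordering follows the listed order of the sets (models,
    distributions, transformations) — this is the index criterion used by the
    pitch-adjustment and differential-mutation operators.
    """

    factor_names: tuple[str, ...]
    prespec: PreSpecification = field(default_factory=PreSpecification)
    bound: float = 1e5

    def __post_init__(self):
        self.factor_names = tuple(self.factor_names)
        self.prespec.validate(self.factor_names)
        self.models = tuple(self.prespec.allowed_models)
        self.distributions = tuple(self.prespec.allowed_distributions)
        self.transformations = tuple(self.prespec.allowed_transformations)
        self._genes = self._build_genes()
        if count_space(self) < 1:
            raise ConfigurationError("pre-specifications leave no feasible specification")

    def _options(self, kind: str, k: int | None) -> tuple:
        ps = self.prespec
        if kind == "alpha":
            name = self.factor_names[k]
            if name in ps.include:
                return (ps.include[name],)
            if ps.random.get(name) == 1:
                return (1,)                      # randomness forces inclusion
            return (0, 1)
        if kind == "r":
            name = self.factor_names[k]
            if name in ps.random:
                return (ps.random[name],)
            return (0, 1)
        if kind == "dist":
            name = self.factor_names[k]
            if name in ps.distribution:
                return (ps.distribution[name],)
            return self.distributions
        if kind == "tau":
            name = self.factor_names[k]
            if name in ps.transformation:
                return (ps.transformation[name],)
            return self.transformations
        if kind == "model":
            if ps.model is not None:
                return (ps.model,)
            return self.models
        raise ConfigurationError(f"unknown gene kind {kind!r}")

    def _build_genes(self) -> list[_Gene]:
        genes: list[_Gene] = []
        for k in range(len(self.factor_names)):
            for kind in ("alpha", "r", "dist", "tau"):
                genes.append((kind, k, self._options(kind, k)))
        genes.append(("model", None, self._options("model", None)))
        return genes

    @property
    def genes(self) -> list[_Gene]:
        return self._genes

    def to_indices(self, spec: Specification) -> list[int]:
        """Chromosome as per-gene indices into the ordered option sets."""
        idx = []
        for kind, k, opts in self._genes:
            if kind == "alpha":
                val = spec.alpha[k]
            elif kind == "r":
                val = spec.r[k]
            elif kind == "dist":
                val = spec.dist[k]
            elif kind == "tau":
                val = spec.tau[k]
            else:
                val = spec.model
            idx.append(opts.index(val) if val in opts else 0)
        return idx

    def from_indices(self, indices) -> Specification:
        """Inverse of :meth:`to_indices` (result is not yet normalized)."""
        kf = len(self.factor_names)
        alpha, r, dist, tau = [0] * kf, [0] * kf, [None] * kf, [None] * kf
        model = self.models[0]
        for (kind, k, opts), i in zip(self._genes, indices):
            val = opts[int(i) % len(opts)]
            if kind == "alpha":
                alpha[k] = val
            elif kind == "r":
                r[k] = val
            elif kind == "dist":
                dist[k] = val
            elif kind == "tau":
                tau[k] = val
            else:
                model = val
        return Specification(self.factor_names, tuple(alpha), tuple(r),
                             tuple(dist), tuple(tau), model)


def normalize(spec: Specification, space: SearchSpace) -> Specification:
    """Canonical feasible form of a chromosome.

    Enforces randomness => inclusion, re-applies every pre-specification
    clamp, and zeroes meaningless genes (distribution when not random,
    transformation when excluded) to the first admissible option.  Idempotent.
    """
    ps = space.prespec
    kf = len(space.factor_names)
    alpha, r = list(spec.alpha), list(spec.r)
    dist, tau = list(spec.dist), list(spec.tau)
    model = spec.model if spec.model in space.models else space.models[0]
    if ps.model is not None:
        model = ps.model
    for k in range(kf):
        name = space.factor_names[k]
        if name in ps.random:
            r[k] = ps.random[name]
        if name in ps.include:
            alpha[k] = ps.include[name]
            if alpha[k] == 0:
                r[k] = 0
        if r[k]:
            alpha[k] = 1
        d_opts = space._options("dist", k)
        t_opts = space._options("tau", k)
        dist[k] = dist[k] if (r[k] and dist[k] in d_opts) else d_opts[0]
        tau[k] = tau[k] if (alpha[k] and tau[k] in t_opts) else t_opts[0]
        if not r[k]:
            dist[k] = d_opts[0]
        if not alpha[k]:
            tau[k] = t_opts[0]
    return Specification(space.factor_names, tuple(alpha), tuple(r),
                         tuple(dist), tuple(tau), model)


def random_specification(space: SearchSpace, rng: np.random.Generator) -> Specification:
    """Uniform draw over each free decision, constraints enforced by normalize."""
    indices = [rng.integers(len(opts)) for _, _, opts in space.genes]
    return normalize(space.from_indices(indices), space)


def mutate_indices(indices: list[int], space: SearchSpace,
                   rng: np.random.Generator) -> list[int]:
    """Raw chromosome move: U(1,3) distinct gene positions each reassigned to
    a different admissible value; no constraint normalization applied."""
    indices = list(indices)
    mutable = [j for j, (_, _, opts) in enumerate(space.genes) if len(opts) > 1]
    if not mutable:
        return indices
    m = min(int(rng.integers(1, 4)), len(mutable))
    positions = rng.choice(len(mutable), size=m, replace=False)
    for pos in np.atleast_1d(positions):
        j = mutable[int(pos)]
        n_opts = len(space.genes[j][2])
        shift = int(rng.integers(1, n_opts))
        indices[j] = (indices[j] + shift) % n_opts
    return indices


def mutate(spec: Specification, space: SearchSpace, rng: np.random.Generator) -> Specification:
    """Neighbor move: U(1,3) distinct single-gene changes, then normalize.

    Each change picks a random chromosome position with more than one
    admissible value and reassigns it to a *different* admissible value
    (add/remove a factor, toggle randomness, change a distribution,
    transformation, or the model type).
    """
    indices = mutate_indices(space.to_indices(spec), space, rng)
    return normalize(space.from_indices(indices), space)


def _factor_combos(space: SearchSpace, k: int):
    """All canonical (alpha, r, dist, tau) choices for factor k."""
    a_opts = space._options("alpha", k)
    r_opts = space._options("r", k)
    d_opts = space._options("dist", k)
    t_opts = space._options("tau", k)
    combos = []
    if 0 in a_opts and space.prespec.random.get(space.factor_names[k]) != 1:
        combos.append((0, 0, d_opts[0], t_opts[0]))
    if 1 in a_opts:
        for t in t_opts:
            if 0 in r_opts:
                combos.append((1, 0, d_opts[0], t))
            if 1 in r_opts:
                combos.extend((1, 1, d, t) for d in d_opts)
    return combos


def count_space(space: SearchSpace) -> int:
    """Cardinality of the feasible normalized specification set."""
    total = len(space._options("model", None))
    for k in range(len(space.factor_names)):
        total *= len(_factor_combos(space, k))
    return total


def enumerate_space(space: SearchSpace, limit: int = 100_000) -> list[Specification]:
    """Exhaustive, duplicate-free enumeration of all feasible normalized specs.

    Refuses (with the computed cardinality in the message) when the space
    exceeds ``limit``.
    """
    n = count_space(space)
    if n > limit:
        raise ConfigurationError(f"search space has {n} feasible specifications (> limit {limit})")
    per_factor = [_factor_combos(space, k) for k in range(len(space.factor_names))]
    models = space._options("model", None)
    out = []
    for combo in itertools.product(*per_factor) if per_factor else [()]:
        alpha = tuple(c[0] for c in combo)
        r = tuple(c[1] for c in combo)
        dist = tuple(c[2] for c in combo)
        tau = tuple(c[3] for c in combo)
        for m in models:
            out.append(Specification(space.factor_names, alpha, r, dist, tau, m))
    assert len({s.key() for s in out}) == len(out)
    return out
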