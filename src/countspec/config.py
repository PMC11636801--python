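"""Run configuration: one YAML file that makes a search reproducible.

Schema (all blocks optional except ``data``)::

    data:
      path: crashes.csv
      response: Y
      offset: LOG_AADT        # optional log-exposure column
      sep: ","
      standardize: false
      allow: [...]            # factor allow-list
      deny: [...]             # factor deny-list
    bound_c: 1.0e5
    sets:                     # global decision-set restrictions (ordered)
      models: [Poisson, NB, GP]
      distributions: [Gamma, Uniform, Normal, Triangular, Lindley]
      transformations: [no, ln, sqrt, exp, squared, cubed, factorial, arcsinh]
    prespec:
      model: NB               # force the model type
      factors:
        AADT: {include: 1, random: 1, distribution: Normal, transformation: ln}
    initial_solution: start_model.yaml
    search:
      algorithm: SA           # HS | SA | DE
      objective: BIC          # BIC | AIC | LL
      max_time: 600
      seed: 1
      hdraws: 200
      # algorithm hyperparameters: hms, hmcr, par, pai, t_alpha, t_steps,
      # chi, ps, cr, alpha_sig, max_evaluations ...
    output_dir: runs/example
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .data import DEFAULT_BOUND, CountData, load_dataset
from .errors import ConfigurationError
from .model import EstimationOptions
from .report import load_spec
from .search import SearchConfig
from .specification import PreSpecification, SearchSpace, Specification

__all__ = ["RunConfig", "load_run_config"]

def _tf_name(value) -> str:
    # bare "no" in YAML parses as boolean False; map it back to the
    # identity-transformation name
    if value is False or value is None:
        return "no"
    return str(value)


_SEARCH_KEYS = {
    "algorithm", "objective", "max_time", "seed", "max_evaluations",
    "hms", "hmcr", "par", "pai", "classical_par",
    "t_alpha", "t_steps", "chi", "calibration_size",
    "ps", "cr", "alpha_sig", "drop_all",
}


@dataclass
class RunConfig:
    """Everything needed to reproduce a search run (plus the seed)."""

    data_path: str
    response: str
    offset: str | None = None
    sep: str = ","
    standardize: bool = False
    allow: list[str] | None = None
    deny: list[str] | None = None
    bound_c: float = DEFAULT_BOUND
    hdraws: int = 200
    sets: dict = field(default_factory=dict)
    prespec_raw: dict = field(default_factory=dict)
    initial_solution: str | None = None
    search: SearchConfig = field(default_factory=SearchConfig)
    output_dir: str = "countspec_run"

    def load_data(self) -> CountData:
        return load_dataset(self.data_path, self.response, sep=self.sep,
                            offset=self.offset, allow=self.allow, deny=self.deny,
                            standardize=self.standardize)

    def build_space(self, data: CountData) -> SearchSpace:
        ps_kwargs = {}
        factors = self.prespec_raw.get("factors", {})
        include, random, distribution, transformation = {}, {}, {}, {}
        for name, entry in factors.items():
            if "include" in entry:
                include[name] = int(entry["include"])
            if "random" in entry:
                random[name] = int(entry["random"])
            if "distribution" in entry:
                distribution[name] = entry["distribution"]
            if "transformation" in entry:
                transformation[name] = _tf_name(entry["transformation"])
        ps_kwargs.update(include=include, random=random,
                         distribution=distribution, transformation=transformation,
                         model=self.prespec_raw.get("model"))
        if "models" in self.sets:
            ps_kwargs["allowed_models"] = tuple(self.sets["models"])
        if "distributions" in self.sets:
            ps_kwargs["allowed_distributions"] = tuple(self.sets["distributions"])
        if "transformations" in self.sets:
            ps_kwargs["allowed_transformations"] = tuple(
                _tf_name(t) for t in self.sets["transformations"]
            )
        prespec = PreSpecification(**ps_kwargs)
        return SearchSpace(data.factor_names, prespec=prespec, bound=self.bound_c)

    def load_initial(self, data: CountData) -> Specification | None:
        if self.initial_solution is None:
            return None
        return load_spec(self.initial_solution, data.factor_names)

    def to_dict(self) -> dict:
        search = {k: v for k, v in dataclasses.asdict(self.search).items()
                  if k != "estimation"}
        return {
            "data": {"path": self.data_path, "response": self.response,
                     "offset": self.offset, "sep": self.sep,
                     "standardize": self.standardize,
                     "allow": self.allow, "deny": self.deny},
            "bound_c": self.bound_c,
            "hdraws": self.hdraws,
            "sets": self.sets,
            "prespec": self.prespec_raw,
            "initial_solution": self.initial_solution,
            "search": search,
            "output_dir": self.output_dir,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def load_run_config(path, **overrides) -> RunConfig:
    """Parse a YAML run configuration; keyword overrides win over the file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    data = raw.get("data") or {}
    if "path" not in data or "response" not in data:
        raise ConfigurationError(f"{path}: the data block needs 'path' and 'response'")
    search_raw = dict(raw.get("search") or {})
    unknown = set(search_raw) - _SEARCH_KEYS
    if unknown:
        raise ConfigurationError(f"{path}: unknown search keys {sorted(unknown)}")
    search_raw.update({k: v for k, v in overrides.items() if k in _SEARCH_KEYS and v is not None})
    hdraws = int(raw.get("hdraws", 200))
    bound_c = float(raw.get("bound_c", DEFAULT_BOUND))
    est = EstimationOptions(hdraws=hdraws, bound=bound_c,
                            objective=search_raw.get("objective", "BIC"))
    config = SearchConfig(estimation=est, **search_raw)
    data_path = data["path"]
    if not Path(data_path).is_absolute():
        data_path = str((Path(path).parent / data_path).resolve())
    return RunConfig(
        data_path=data_path,
        response=data["response"],
        offset=data.get("offset"),
        sep=data.get("sep", ","),
        standardize=bool(data.get("standardize", False)),
        allow=data.get("allow"),
        deny=data.get("deny"),
        bound_c=bound_c,
        hdraws=hdraws,
        sets=raw.get("sets") or {},
        prespec_raw=raw.get("prespec") or {},
        initial_solution=raw.get("initial_solution"),
        search=config,
        output_dir=str(raw.get("output_dir", "countspec_run")),
    )
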