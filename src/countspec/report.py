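"""Coefficient-table rendering and specification serialization.

The rendered table mirrors the layout analysts expect from crash-frequency
studies: one row per effect (with its transformation), a separate block for
the scale parameters of the random-coefficient distributions, and a footer
with the dispersion, model type, log-likelihood and BIC.  Significance stars:
*** p<0.01, ** p<0.05, * p<0.1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .model import MixedCountResults
from .specification import Specification

__all__ = ["stars", "render_report", "report_frame", "spec_to_dict", "spec_from_dict",
           "save_spec", "load_spec"]


def stars(p: float) -> str:
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.1:
        return "*"
    return ""


def report_frame(results: MixedCountResults) -> pd.DataFrame:
    """Tidy coefficient table as a DataFrame (one row per estimated term)."""
    spec = results.spec
    taus = dict(zip(spec.factor_names, spec.tau))
    dists = dict(zip(spec.factor_names, spec.dist))
    rows = []
    for label, kind, est, se, z, p in zip(
        results.term_labels, results.term_kinds, results.params,
        results.bse, results.zvalues, results.pvalues,
    ):
        if kind == "omega":
            factor = label.replace(" (Std. Dev.)", "")
            tau = dists[factor].lower()
            block = "scale"
        elif kind == "phi":
            tau, block = "", "dispersion"
        else:
            tau = taus.get(label, "no") if kind == "beta" else "no"
            block = "mean"
        rows.append(
            {"Effect": label, "tau": tau, "Coeff": est, "Std.Err": se,
             "z": z, "Prob|z|>Z": p, "sig": stars(p), "block": block}
        )
    return pd.DataFrame(rows)


def render_report(results: MixedCountResults) -> str:
    """Human-readable coefficient table with significance stars."""
    if not results.converged:
        return f"<non-converged specification: {results.spec.describe()}>"
    frame = report_frame(results)
    width = max(24, max(len(e) for e in frame["Effect"]) + 2)

    def fmt(row):
        return (f"{row['Effect']:<{width}}{row['tau']:<10}"
                f"{row['Coeff']:>10.3f}{row['Std.Err']:>10.3f}"
                f"{row['z']:>8.2f} {row['Prob|z|>Z']:>9.2f} {row['sig']}")

    header = (f"{'Effect':<{width}}{'tau':<10}{'Coeff':>10}{'Std.Err':>10}"
              f"{'z':>8} {'Prob|z|>Z':>9}")
    lines = [header, "-" * len(header)]
    lines += [fmt(r) for _, r in frame[frame.block == "mean"].iterrows()]
    scale = frame[frame.block == "scale"]
    if len(scale):
        lines.append("Scale Parameters for Distributions of Random Parameters")
        lines += [fmt(r) for _, r in scale.iterrows()]
    disp = frame[frame.block == "dispersion"]
    lines.append("-" * len(header))
    if len(disp):
        lines.append(f"{'Dispersion':<{width}}{disp.iloc[0]['Coeff']:.3f}")
    lines.append(f"{'Model Type':<{width}}{_model_long_name(results.spec.model)}")
    lines.append(f"{'Log-Likelihood':<{width}}{results.llf:.2f}")
    lines.append(f"{'BIC':<{width}}{results.bic:.2f}")
    lines.append("***p<0.01; **p<0.05; *p<0.1")
    return "\n".join(lines)


def _model_long_name(model: str) -> str:
    return {"Poisson": "Poisson", "NB": "Negative Binomial",
            "GP": "Generalized Poisson"}[model]


# -- specification (de)serialization, also used for initial solutions --------

def spec_to_dict(spec: Specification) -> dict:
    return {
        "model": spec.model,
        "factors": {
            k: {"include": int(a), "random": int(r), "distribution": d, "transformation": t}
            for k, a, r, d, t in zip(spec.factor_names, spec.alpha, spec.r, spec.dist, spec.tau)
        },
    }


def spec_from_dict(payload: dict, factor_names) -> Specification:
    factors = payload.get("factors", {})
    unknown = set(factors) - set(factor_names)
    if unknown:
        raise ConfigurationError(f"specification references unknown factors: {sorted(unknown)}")
    alpha, r, dist, tau = [], [], [], []
    for k in factor_names:
        entry = factors.get(k, {})
        alpha.append(int(entry.get("include", 0)))
        r.append(int(entry.get("random", 0)))
        dist.append(entry.get("distribution", "Gamma"))
        tau_val = entry.get("transformation", "no")
        # bare "no" in hand-written YAML parses as boolean False
        tau.append("no" if tau_val in (False, None) else str(tau_val))
    return Specification(tuple(factor_names), tuple(alpha), tuple(r),
                         tuple(dist), tuple(tau), payload.get("model", "Poisson"))


def save_spec(spec: Specification, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(spec_to_dict(spec), fh, sort_keys=False)


def load_spec(path, factor_names) -> Specification:
    with open(path) as fh:
        return spec_from_dict(yaml.safe_load(fh), factor_names)
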