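"""Observed data, variable transformations, and design construction.

A :class:`CountData` holds one non-negative integer response per observation
(events per unit, e.g. crashes per road segment), a universe of numeric
candidate contributing factors, and an optional log-exposure offset.  Candidate
factors may be passed through one of a small set of monotone or polynomial
transformations before entering the log-linear rate; a transformation is only
admissible if its domain is respected and every transformed value stays inside
the bound ``[-c, c]``.  Inadmissible transformations are a *normal* outcome of
the specification search (the proposal is marked infeasible and penalized),
not an error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .errors import ConfigurationError, ValidationError

__all__ = [
    "TRANSFORMATIONS",
    "DEFAULT_BOUND",
    "CountData",
    "TransformRejection",
    "TransformedDesign",
    "apply_transformation",
    "build_design",
    "load_dataset",
]

#: Admissible transformations, identity ("no") first.  The listed order is the
#: ordering criterion used by the index-based metaheuristic operators.
TRANSFORMATIONS: tuple[str, ...] = (
    "no",
    "ln",
    "sqrt",
    "exp",
    "squared",
    "cubed",
    "factorial",
    "arcsinh",
)

#: Default bound c on transformed values.
DEFAULT_BOUND: float = 1e5


@dataclass(frozen=True)
class TransformRejection:
    """Explains why a transformation was refused for a factor.

    ``rule`` is the violated requirement (domain or bound); rejection is a
    normal search outcome, so this is a value, not an exception.
    """

    transform: str
    rule: str
    factor: str | None = None

    def __bool__(self) -> bool:  # rejections are falsy design components
        return False


def _tf_ln(x):
    return np.log(x)


def _tf_factorial(x):
    # Generalized to Gamma(x+1) so non-integer covariates do not hard-fail.
    return np.exp(gammaln(x + 1.0))


_TRANSFORM_FUNCS = {
    "no": lambda x: x,
    "identity": lambda x: x,
    "ln": _tf_ln,
    "log": _tf_ln,
    "sqrt": np.sqrt,
    "exp": np.exp,
    "squared": lambda x: x**2,
    "cubed": lambda x: x**3,
    "factorial": _tf_factorial,
    "arcsinh": np.arcsinh,
}

# Domain predicates; transformations absent from this map accept any finite x.
_DOMAINS = {
    "ln": (lambda x: np.all(x > 0), "ln requires all values > 0"),
    "log": (lambda x: np.all(x > 0), "ln requires all values > 0"),
    "sqrt": (lambda x: np.all(x >= 0), "sqrt requires all values >= 0"),
    "factorial": (lambda x: np.all(x >= 0), "factorial requires all values >= 0"),
}


def apply_transformation(x, tau: str, c: float = DEFAULT_BOUND, factor: str | None = None):
    """Apply transformation ``tau`` to vector ``x`` under bound ``c``.

    Returns the transformed vector, or a :class:`TransformRejection` if the
    transformation's domain is violated or any transformed value is non-finite
    or outside ``[-c, c]``.

    Raises
    ------
    ConfigurationError
        If ``tau`` is not a known transformation name.
    ValidationError
        If ``c`` is not positive or ``x`` contains non-finite values.
    """
    if tau not in _TRANSFORM_FUNCS:
        raise ConfigurationError(f"unknown transformation {tau!r}; choose from {TRANSFORMATIONS}")
    if not c > 0:
        raise ValidationError(f"bound c must be positive, got {c}")
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValidationError("input vector contains non-finite values")
    dom = _DOMAINS.get(tau)
    if dom is not None and not dom[0](x):
        return TransformRejection(tau, dom[1], factor)
    with np.errstate(over="ignore", invalid="ignore"):
        out = _TRANSFORM_FUNCS[tau](x)
    out = np.asarray(out, dtype=float)
    if not np.all(np.isfinite(out)):
        return TransformRejection(tau, "transformed values are non-finite", factor)
    if np.max(np.abs(out)) > c:
        return TransformRejection(tau, f"transformed values exceed the bound c={c:g}", factor)
    return out


@dataclass
class CountData:
    """Cross-sectional count observations with candidate contributing factors.

    Parameters
    ----------
    response : array of non-negative integers, length n.
    factors : mapping factor name -> numeric vector of length n.
    offset : optional log-exposure vector of length n, added to the linear
        predictor with a fixed unit coefficient.
    """

    response: np.ndarray
    factors: dict[str, np.ndarray]
    offset: np.ndarray | None = None
    name: str = "counts"
    dropped_columns: list[str] = field(default_factory=list, repr=False)

    def __post_init__(self):
        y = np.asarray(self.response, dtype=float)
        if y.ndim != 1 or y.size < 1:
            raise ValidationError("response must be a 1-d vector with at least one observation")
        bad = np.flatnonzero(~np.isfinite(y) | (y < 0) | (y != np.rint(y)))
        if bad.size:
            raise ValidationError(
                f"response must contain non-negative integers; offending rows: {bad.tolist()[:10]}"
            )
        self.response = y.astype(np.int64)
        n = y.size
        clean: dict[str, np.ndarray] = {}
        for k, v in self.factors.items():
            v = np.asarray(v, dtype=float)
            if v.shape != (n,):
                raise ValidationError(f"factor {k!r} has length {v.size}, expected {n}")
            if not np.all(np.isfinite(v)):
                raise ValidationError(f"factor {k!r} contains missing or non-finite values")
            if k in clean:
                raise ValidationError(f"duplicate factor name {k!r}")
            clean[k] = v
        self.factors = clean
        if self.offset is not None:
            off = np.asarray(self.offset, dtype=float)
            if off.shape != (n,) or not np.all(np.isfinite(off)):
                raise ValidationError("offset must be a finite vector matching the response length")
            self.offset = off

    @property
    def nobs(self) -> int:
        return int(self.response.size)

    @property
    def factor_names(self) -> tuple[str, ...]:
        return tuple(self.factors)

    def factor_matrix(self, names=None) -> np.ndarray:
        names = self.factor_names if names is None else names
        return np.column_stack([self.factors[k] for k in names]) if names else np.empty((self.nobs, 0))

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        response: str,
        offset: str | None = None,
        allow: list[str] | None = None,
        deny: list[str] | None = None,
        standardize: bool = False,
        name: str = "counts",
    ) -> "CountData":
        """Build a dataset from a DataFrame; non-numeric columns are excluded
        with a warning, row order is preserved."""
        if response not in frame.columns:
            raise ConfigurationError(f"response column {response!r} not found in table")
        if offset is not None and offset not in frame.columns:
            raise ConfigurationError(f"offset column {offset!r} not found in table")
        dropped: list[str] = []
        factors: dict[str, np.ndarray] = {}
        for col in frame.columns:
            if col in (response, offset):
                continue
            series = frame[col]
            if not pd.api.types.is_numeric_dtype(series):
                coerced = pd.to_numeric(series, errors="coerce")
                if coerced.isna().any():
                    dropped.append(col)
                    continue
                series = coerced
            if deny and col in deny:
                dropped.append(col)
                continue
            if allow and col not in allow:
                dropped.append(col)
                continue
            vals = series.to_numpy(dtype=float)
            if standardize:
                sd = vals.std()
                vals = (vals - vals.mean()) / (sd if sd > 0 else 1.0)
            factors[col] = vals
        if dropped:
            warnings.warn(f"excluded non-numeric or filtered columns: {dropped}", stacklevel=2)
        off = frame[offset].to_numpy(dtype=float) if offset else None
        ds = cls(frame[response].to_numpy(), factors, offset=off, name=name)
        ds.dropped_columns = dropped
        return ds


def load_dataset(
    table_path,
    response: str,
    sep: str = ",",
    offset: str | None = None,
    allow: list[str] | None = None,
    deny: list[str] | None = None,
    standardize: bool = False,
) -> CountData:
    """Load a delimited table with a header row into a :class:`CountData`.

    All numeric columns other than the response (and offset) become candidate
    factors; non-numeric columns are rejected with a named warning list.
    """
    frame = pd.read_csv(table_path, sep=sep)
    return CountData.from_dataframe(
        frame, response=response, offset=offset, allow=allow, deny=deny,
        standardize=standardize, name=str(table_path),
    )


@dataclass
class TransformedDesign:
    """Transformed factor rows for one specification.

    ``matrix`` has one row per selected (transformed) factor plus a trailing
    intercept handled separately; rows are ordered as ``names``.  ``feasible``
    is False when any selected transformation was rejected, in which case
    ``rejections`` lists the violated rules and the design must not be used
    for estimation (the search penalizes the proposal instead).
    """

    names: tuple[str, ...]          # selected factor names, excluding the intercept
    taus: tuple[str, ...]           # transformation applied per selected factor
    matrix: np.ndarray              # shape (len(names)+1, n); last row is the intercept
    bound: float
    feasible: bool = True
    rejections: tuple[TransformRejection, ...] = ()

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    def exog(self) -> np.ndarray:
        """Design in estimation orientation: shape (n, p), intercept first."""
        return np.column_stack([self.matrix[-1], *self.matrix[:-1]])


def build_design(dataset: CountData, spec, c: float = DEFAULT_BOUND) -> TransformedDesign:
    """Build the transformed design for ``spec`` (a Specification).

    Includes exactly the factors with inclusion flag 1, transformed per the
    specification; the intercept row (all ones) is always appended.  If any
    selected transformation is rejected the design is flagged infeasible.
    """
    names, taus, rows, rejections = [], [], [], []
    for k, alpha, tau in zip(spec.factor_names, spec.alpha, spec.tau):
        if not alpha:
            continue
        if k not in dataset.factors:
            raise ConfigurationError(f"specification references unknown factor {k!r}")
        out = apply_transformation(dataset.factors[k], tau, c=c, factor=k)
        if isinstance(out, TransformRejection):
            rejections.append(out)
            rows.append(np.zeros(dataset.nobs))
        else:
            rows.append(out)
        names.append(k)
        taus.append(tau)
    matrix = np.vstack(rows + [np.ones(dataset.nobs)])
    return TransformedDesign(
        names=tuple(names),
        taus=tuple(taus),
        matrix=matrix,
        bound=c,
        feasible=not rejections,
        rejections=tuple(rejections),
    )
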