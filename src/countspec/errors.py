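"""Exception hierarchy shared across the package."""


class CountspecError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CountspecError):
    """Invalid analyst input: unknown names, contradictory pre-specifications,
    over-constrained search spaces, malformed configuration files."""


class ValidationError(CountspecError, ValueError):
    """Data violates an invariant (negative counts, missing values, bad shapes)."""


class EstimationError(CountspecError):
    """Likelihood maximization failed in a way that cannot be recovered."""
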