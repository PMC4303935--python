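"""Exception hierarchy shared across the package."""


class ExprDriftError(ValueError):
    """Base class for all exprdrift errors."""


class AlignmentError(ExprDriftError):
    """Gene or sample identifiers do not line up between two objects."""


class DegenerateDataError(ExprDriftError):
    """Input data is degenerate for the requested operation
    (all-zero vector, zero per-gene scale, constant regressor, ...)."""


class ConfigurationError(ExprDriftError):
    """An operation was requested with an inconsistent configuration,
    e.g. a Mahalanobis profile without a fitted covariance."""


class ParseError(ExprDriftError):
    """A file could not be parsed into the expected structure."""
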