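"""Exception hierarchy for fnconn.

All argument/contract violations derive from :class:`InvalidArgumentError`
(a ``ValueError``) so callers can catch one base class.
"""


class FnconnError(Exception):
    """Base class for all fnconn errors."""


class InvalidArgumentError(FnconnError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateSeriesError(InvalidArgumentError):
    """A series is constant (zero variance) where variability is required,
    so the requested statistic (distance correlation, autocorrelation,
    entropy, spectral fractions) is undefined."""


class InfeasibleMatchError(FnconnError):
    """Fewer candidate components than templates: no injective assignment
    of every template exists."""


class SchemaError(FnconnError, ValueError):
    """A delimited-text input violates the expected tabular schema
    (ragged rows, duplicate labels, malformed columns)."""
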