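"""Exception hierarchy for wclike.

All errors derive from :class:`WclikeError` so callers can catch the
package's failures with one clause; the finer classes mirror the kinds of
failure the pipeline can hit (bad configuration, bad input data, numerical
propagation, fit failure, invalid comparison, domain violations).
"""


class WclikeError(Exception):
    """Base class for all wclike errors."""


class ConfigurationError(WclikeError):
    """A model/condition is internally inconsistent (e.g. missing Δω entry)."""


class ValidationError(WclikeError, ValueError):
    """A value violates a documented invariant (negative rate, bad populations)."""


class DataError(WclikeError, ValueError):
    """Observed data cannot be used (non-positive intensities, degenerate delays)."""


class ParseError(WclikeError):
    """A tabular input file is malformed."""


class PropagationError(WclikeError):
    """Numerical failure while propagating magnetization."""


class FitFailureError(WclikeError):
    """No optimizer start converged."""


class ComparisonError(WclikeError):
    """Model-selection inputs do not refer to the same dataset."""


class DomainError(WclikeError, ValueError):
    """A quantity is outside the mathematical domain of an operation."""
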