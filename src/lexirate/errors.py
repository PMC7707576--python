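"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: usage errors -> 1, data errors -> 2,
convergence failures -> 3.
"""


class LexirateError(Exception):
    """Base class for all package errors."""


class SchemaError(LexirateError):
    """A required column or field is missing from an input table."""


class DataError(LexirateError):
    """Input rows violate a validation rule (bad ids, bad values)."""


class CapacityError(DataError):
    """A synthetic realization cannot host the requested events."""


class ConvergenceError(LexirateError):
    """MCMC diagnostics failed the configured convergence gate."""
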