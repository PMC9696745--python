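"""Exception hierarchy for BGLM.

All errors raised by the library derive from :class:`BglmError` so callers
(and the CLI) can catch the whole family at once.
"""


class BglmError(Exception):
    """Base class for all BGLM errors."""


class SchemaError(BglmError):
    """An input file is missing a required column."""


class EmptyInputError(BglmError):
    """An input yielded zero usable rows."""


class CodeNotFoundError(BglmError, KeyError):
    """A requested code id is absent from a lab-event table."""


class ContractViolationError(BglmError, ValueError):
    """A precondition of an operation was violated by the caller."""


class DegenerateRowError(BglmError):
    """A distance-matrix row is constant, so its Z-scores are undefined."""


class EvaluationError(BglmError):
    """Evaluation inputs are inconsistent (e.g. a code missing from truth)."""


class SeparationUndefinedError(EvaluationError):
    """The correct/incorrect Z-score comparison needs both groups non-empty."""


class ConfigError(BglmError):
    """A scenario or run configuration is invalid."""
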