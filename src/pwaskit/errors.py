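"""Exception hierarchy for pwaskit.

All package errors derive from :class:`PwasError` so callers can catch one
base class.  :class:`TooFewFeaturesError` doubles as the pathway-exclusion
signal: a pathway whose consensus SNP set drops below two features in any
resampling iteration is excluded from the association family rather than
treated as a failure.
"""


class PwasError(Exception):
    """Base class for all pwaskit errors."""


class ConfigurationError(PwasError, ValueError):
    """A configuration field is missing, malformed or out of range."""


class FormatError(PwasError, ValueError):
    """An input file violates its declared format (carries a line number when known)."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class DataError(PwasError, ValueError):
    """Inconsistent data: duplicate IDs, dimension mismatches, unknown SNPs."""


class EmptyDatasetError(DataError):
    """Quality control removed every sample or every SNP."""


class SimulationError(PwasError, RuntimeError):
    """The simulator could not satisfy its sampling targets."""


class ClassBalanceError(PwasError, ValueError):
    """An operation that needs both case and control labels saw only one class."""


class DegenerateInputError(PwasError, ValueError):
    """Constant vectors / zero-variance samples where variation is required."""


class SelectionError(PwasError, ValueError):
    """Feature selection invoked on an empty candidate pool."""


class TooFewFeaturesError(PwasError):
    """Fewer than two features available — the pathway-exclusion signal."""
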