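"""Exception hierarchy."""


class RbptmError(Exception):
    """Base class for all package errors."""


class ConfigurationError(RbptmError):
    """Invalid analysis configuration or unknown catalog dialect."""


class ValidationError(RbptmError):
    """A domain object or simulation spec violates its invariants.

    ``violations`` lists every violated field so callers can report all
    problems at once instead of fixing them one by one.
    """

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


class CatalogFormatError(RbptmError):
    """A malformed row or line in an input file; carries the row number."""

    def __init__(self, message, row=None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)
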