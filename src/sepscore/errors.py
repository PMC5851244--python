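"""Exception hierarchy shared across the package."""


class SepscoreError(Exception):
    """Base class for all package-specific errors."""


class IneligibleRecordError(SepscoreError):
    """A record lacks an input required by the requested score.

    Carries the missing field name so callers can route the record to the
    exclusion list with a machine-readable reason.
    """

    def __init__(self, field: str, message: str | None = None):
        self.field = field
        super().__init__(message or f"record ineligible: missing required field '{field}'")


class DegenerateInputError(SepscoreError):
    """Statistical input has no information (e.g. a single outcome class)."""


class PairingError(SepscoreError):
    """Paired-test inputs are not defined on the same records."""


class CohortParseError(SepscoreError):
    """A cohort file row could not be parsed; carries the 1-based line number."""

    def __init__(self, line: int, message: str):
        self.line = line
        super().__init__(f"line {line}: {message}")
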