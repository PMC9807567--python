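"""Exception hierarchy for the enhv toolkit."""


class EnhvError(Exception):
    """Base class for all toolkit errors."""


class FreeSurferParseError(EnhvError):
    """A FreeSurfer stats file could not be parsed.

    Carries the offending path, and where known the missing measure name
    or the 1-based line number of a malformed line.
    """

    def __init__(self, message, path=None, missing=None, line=None):
        self.path = path
        self.missing = missing
        self.line = line
        super().__init__(message)


class CohortValidationError(EnhvError):
    """A cohort table violated the data-model invariants.

    ``row`` is the 1-based data-row number (excluding the header) where the
    violation occurred, when applicable.
    """

    def __init__(self, message, row=None, column=None):
        self.row = row
        self.column = column
        super().__init__(message)


class ModelInputError(EnhvError):
    """Invalid input to model construction, fitting or prediction."""


class AnalysisError(EnhvError):
    """Invalid input to a statistical analysis routine."""
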