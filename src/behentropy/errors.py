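"""Exception hierarchy.

``InputError`` subclasses signal bad user input or configuration (CLI exit
code 2); ``AnalysisError`` subclasses signal failures arising during an
otherwise well-posed analysis (CLI exit code 1).
"""


class BehentropyError(Exception):
    """Base class for all package errors."""


class InputError(BehentropyError):
    """Malformed input data or configuration."""


class FormatError(InputError):
    """A file does not follow the expected dialect."""


class EventValidationError(InputError):
    """An event log violates a session invariant."""


class ParameterError(InputError):
    """An argument is outside its legal range."""


class AnalysisError(BehentropyError):
    """The analysis cannot be carried out on these data."""


class NoTransitionsError(AnalysisError):
    """No behavior transitions observed; transition probabilities undefined."""


class InsufficientDataError(AnalysisError):
    """Too few observations for the requested statistic."""


class MissingPhaseError(AnalysisError):
    """A phase scope was requested that the log does not contain."""


class RankDeficiencyError(AnalysisError):
    """The linear-model design matrix is rank deficient."""

    def __init__(self, message, columns=None):
        super().__init__(message)
        self.columns = list(columns) if columns is not None else []


class CalibrationError(AnalysisError):
    """An entropy target is unreachable for the given base matrix."""

    def __init__(self, message, achievable=None):
        super().__init__(message)
        self.achievable = achievable
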