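"""Exception hierarchy shared by all modules.

Data problems (bad codes, malformed files, inconsistent shapes) raise
:class:`DataError` subclasses; caller mistakes (bad parameter values)
raise :class:`ParameterError`.  The CLI maps these onto exit codes.
"""


class SsePssmError(Exception):
    """Base class for all package errors."""


class DataError(SsePssmError):
    """A problem with input data."""


class InvalidCodeError(DataError):
    """A character outside the declared alphabet (and not the gap '-')."""


class FormatError(DataError):
    """A malformed file: wrong header, wrong column count, bad row."""


class LengthMismatchError(DataError):
    """Paired strings whose lengths must agree do not."""


class MissingAnnotationError(DataError):
    """A reference protein lacks the required SSE annotation."""


class DegenerateTrainingError(DataError):
    """Training labels contain fewer than two classes."""


class GenerationError(DataError):
    """Synthetic data generation could not satisfy its constraints."""


class ParameterError(SsePssmError):
    """An invalid parameter value."""
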