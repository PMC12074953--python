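"""Exception hierarchy shared across the pipeline.

Each class maps to a distinct CLI exit code (see :mod:`enhmeth.cli`).
"""


class EnhmethError(Exception):
    """Base class for all pipeline errors."""

    exit_code = 1


class FormatError(EnhmethError):
    """Malformed input file (bad TSV/BED syntax, out-of-range values, duplicates)."""

    exit_code = 2


class ConsistencyError(EnhmethError):
    """Inputs that are individually valid but mutually inconsistent."""

    exit_code = 3


class InsufficientDataError(EnhmethError):
    """Too few observations for the requested operation."""

    exit_code = 4


class DegenerateInputError(EnhmethError):
    """Input with no variation where variation is required (e.g. constant vector)."""

    exit_code = 5


class InvalidFitError(EnhmethError):
    """A model fit that did not converge or violates its contract."""

    exit_code = 6


class CapacityError(EnhmethError):
    """Requested exact computation exceeds the enumeration bound."""

    exit_code = 7


class ConfigError(EnhmethError):
    """Invalid or inconsistent simulation/pipeline configuration."""

    exit_code = 8
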