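"""Exception hierarchy with process exit codes.

Exit codes follow the CLI contract: 0 ok, 2 configuration error,
3 data/format error, 4 insufficient data.
"""


class CawaveError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(CawaveError):
    """Invalid or inconsistent configuration."""

    exit_code = 2


class DataError(CawaveError):
    """Invalid data content (non-finite samples, bad values)."""

    exit_code = 3


class FormatError(DataError):
    """Malformed input file (missing columns, too few rows)."""


class SamplingError(DataError):
    """Time grid is not uniform, or disagrees with the configured interval."""


class InsufficientDataError(CawaveError):
    """Not enough samples/frames/gated values to run the requested analysis."""

    exit_code = 4


class UndefinedSensitivityError(InsufficientDataError):
    """Sensitivity is undefined because the baseline mean phase is not positive."""
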