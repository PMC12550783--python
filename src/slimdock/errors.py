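"""Exception hierarchy shared across the pipeline.

Exit codes follow the CLI contract: 2 configuration error, 3 data error,
4 stage failure.
"""


class SlimdockError(Exception):
    """Base class for all package errors."""

    exit_code = 4


class ConfigError(SlimdockError):
    """Invalid parameter, selection, or configuration value."""

    exit_code = 2


class DataError(SlimdockError):
    """Malformed or inconsistent input data."""

    exit_code = 3


class AlignmentShapeError(DataError):
    """Ragged alignment, duplicate ids, or mismatched sequence lengths."""


class FormatError(DataError):
    """Unparseable or empty input file."""


class StageError(SlimdockError):
    """A pipeline stage failed; partial outputs may have been retained."""
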