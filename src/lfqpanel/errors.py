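"""Exception hierarchy shared across the package.

Each error class carries the process exit code the command-line layer maps
it to, so library errors translate to stable shell semantics.
"""


class LfqPanelError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigurationError(LfqPanelError):
    """Invalid configuration value; the message names the offending field."""

    exit_code = 2


class ParameterError(ConfigurationError):
    """An operation parameter outside its documented domain."""


class FormatError(LfqPanelError):
    """A malformed input file (missing columns, unparseable cells)."""

    exit_code = 3


class AlignmentError(LfqPanelError):
    """Sample identifiers do not line up between two inputs."""

    exit_code = 4


class PreconditionError(LfqPanelError):
    """An operation called on data that violates its stated precondition."""

    exit_code = 5
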