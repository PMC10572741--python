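"""Exception hierarchy shared by all pipeline stages.

Exit-code mapping used by the CLI: input/format problems exit 2,
violated internal invariants exit 3.
"""


class IndigofermError(Exception):
    """Base class for all errors raised by this package."""

    exit_code = 1


class InputError(IndigofermError):
    """Invalid user-supplied value, table, or configuration."""

    exit_code = 2


class FormatError(InputError):
    """A file does not conform to its expected dialect.

    The message names the first offending line, row, or column.
    """


class InvariantError(IndigofermError):
    """An internal consistency condition was violated."""

    exit_code = 3
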