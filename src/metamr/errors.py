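"""Exception hierarchy shared across the package.

The three leaf classes map onto distinct process exit codes in the CLI,
so callers can distinguish malformed files from bad values from misuse.
"""


class MetamrError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class SchemaError(MetamrError):
    """Input file does not have the expected columns/structure."""

    exit_code = 3


class ValidationError(MetamrError):
    """A value violates a domain invariant (negative count, duplicate id...)."""

    exit_code = 4


class UsageError(MetamrError):
    """An operation was called with arguments outside its contract."""

    exit_code = 5
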