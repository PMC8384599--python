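"""Exception hierarchy shared across the package."""


class KgrankError(Exception):
    """Base class for all package-specific errors."""


class FormatError(KgrankError):
    """A file could not be parsed in the expected dialect."""


class GraphValidationError(KgrankError):
    """A graph violates a structural invariant (dangling edge, duplicate id)."""


class NodeLookupError(KgrankError, KeyError):
    """A node or gene id does not resolve (or is not indexed)."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message plain
        return Exception.__str__(self)


class ArgumentError(KgrankError, ValueError):
    """An operation was called with semantically invalid arguments."""


class MotifSyntaxError(FormatError):
    """A semantic-motif line does not follow the path-pattern grammar."""


class QuerySyntaxError(FormatError):
    """A Boolean keyword expression is malformed."""


class ConfigError(KgrankError):
    """A generator or run configuration is inconsistent."""
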