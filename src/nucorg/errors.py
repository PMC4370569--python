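"""Exception types shared across the package."""


class NucorgError(Exception):
    """Base class for all package errors."""


class ValidationError(NucorgError, ValueError):
    """Input violates a documented precondition or invariant."""


class ParseError(NucorgError, ValueError):
    """A file could not be parsed; the message names the offending line."""
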