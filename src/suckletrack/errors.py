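"""Typed exceptions raised across the package.

Every malformed input raises one of these rather than propagating a bare
``ValueError`` or silently coercing, so callers (and the CLI) can distinguish
user data problems from programming errors.
"""


class SuckletrackError(Exception):
    """Base class for all package errors."""


class ParseError(SuckletrackError):
    """A file could not be parsed (bad syntax, non-numeric counts, ...)."""


class ValidationError(SuckletrackError):
    """Parsed data violates an invariant (duplicate IDs, bad labels, ...)."""


class AnalysisError(SuckletrackError):
    """A computation was requested on inputs it is not defined for."""
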