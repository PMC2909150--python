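"""Exception hierarchy shared across the package."""


class SnpsetError(Exception):
    """Base class for all package errors."""


class ParseError(SnpsetError):
    """A file could not be parsed under the declared dialect."""


class ValidationError(SnpsetError):
    """In-memory data violates a type invariant."""


class DegenerateInputError(SnpsetError):
    """Input is formally valid but statistically degenerate (constant vector,
    rank-deficient design, empty complete-case overlap)."""


class ConfigError(SnpsetError):
    """A configuration object is internally inconsistent."""
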