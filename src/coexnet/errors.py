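"""Exception types shared across the package."""


class CoexnetError(Exception):
    """Base class for package errors."""


class ParseError(CoexnetError, ValueError):
    """A file could not be parsed (ragged rows, non-numeric cells, ...)."""


class ValidationError(CoexnetError, ValueError):
    """An object violates a documented invariant (duplicate ids, bad sizes, ...)."""


class DomainError(CoexnetError, ValueError):
    """A value lies outside the mathematical domain of an operation."""


class ConfigurationError(CoexnetError, ValueError):
    """A parameter combination is not usable (e.g. more bins than samples)."""
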