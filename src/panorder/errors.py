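"""Exception hierarchy shared across the package.

Each class maps to one CLI exit code so shell pipelines can distinguish
configuration mistakes from malformed input and from internal invariant
violations.
"""


class PanorderError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(PanorderError):
    """Invalid configuration value (threshold out of range, missing length, ...)."""

    exit_code = 2


class ParseError(PanorderError):
    """Malformed input file; message names the offending line where possible."""

    exit_code = 3


class CatalogError(ParseError):
    """A file refers to a genome/sequence the catalog does not resolve."""


class CoordinateError(ParseError):
    """Coordinates out of bounds or inverted after conversion."""


class InvariantError(PanorderError):
    """An internal model invariant was violated (overlap, duplicate block, ...)."""

    exit_code = 4
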