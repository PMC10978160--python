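"""Exception hierarchy.

Every error raised by the library derives from :class:`AdriskError` so
callers (and the CLI) can distinguish domain failures from programming
errors.  Validation errors double as ``ValueError`` where a caller would
naturally expect one.
"""


class AdriskError(Exception):
    """Base class for all adrisk errors."""


class SchemaError(AdriskError, ValueError):
    """An input table is missing a mandatory column or has a malformed header."""


class ParseError(AdriskError, ValueError):
    """A cell value could not be parsed; the message names the offending row."""


class ReferentialError(AdriskError, ValueError):
    """A record references an entity (e.g. a drug) absent from the catalog."""


class ConfigError(AdriskError, ValueError):
    """A configuration value is out of range, inconsistent, or non-monotone."""


class IncompleteMatrixError(AdriskError, KeyError):
    """The RPN matrix is missing a cell; the message names the cell."""


class EmptyStratumError(AdriskError):
    """No monitoring records exist for the requested (group, preparation mode)."""


class UnsatisfiableTargetError(AdriskError, ValueError):
    """A requested target RPN profile cannot be realised by any campaign spec."""
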