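"""Exception hierarchy.

``ConfigError`` marks a non-physical or inconsistent configuration,
``DataError`` marks malformed or insufficient input data. Both derive from
``ValueError`` so callers can catch broadly.
"""


class HandrimError(Exception):
    """Base class for all package errors."""


class ConfigError(HandrimError, ValueError):
    """A configuration value is missing, inconsistent or non-physical."""


class DataError(HandrimError, ValueError):
    """Input data violate a schema or a precondition of an operation."""
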