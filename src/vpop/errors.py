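"""Exception hierarchy shared across the package."""


class VpopError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(VpopError):
    """A table does not conform to its variable schema."""


class FormatError(VpopError):
    """A file is malformed (duplicate columns, missing header, ...)."""


class PositivityError(VpopError):
    """A value that must be strictly positive is not."""


class InsufficientDataError(VpopError):
    """Too few rows (or known cells) to carry out the requested fit."""


class ConfigError(VpopError):
    """A configuration object references fields or options that do not exist."""
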