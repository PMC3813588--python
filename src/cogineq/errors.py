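"""Exception types shared across the package."""


class CogineqError(Exception):
    """Base class for all package errors."""


class ConfigError(CogineqError, ValueError):
    """A configuration field is invalid; the message names the field."""


class SchemaError(CogineqError, ValueError):
    """Input data do not match the expected columns/contributor sets."""


class DegenerateCellError(CogineqError, ValueError):
    """An age cell has zero score spread, so no z-score can be formed."""


class UndefinedIndexError(CogineqError, ZeroDivisionError):
    """A relative concentration index was requested for a zero-mean variable."""


class SingularDesignError(CogineqError, ValueError):
    """The regression design matrix is rank deficient."""


class UnimputableColumnError(CogineqError, ValueError):
    """A column scheduled for imputation has no observed values."""
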