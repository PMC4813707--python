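"""Exception hierarchy shared across the package."""


class BnpcpError(Exception):
    """Base class for all package-specific errors."""


class TableFormatError(BnpcpError, ValueError):
    """A quantitation table violates the expected dialect."""


class LadderError(BnpcpError, ValueError):
    """A marker ladder is malformed (too short or non-monotone)."""


class CalibrationRangeError(BnpcpError, ValueError):
    """A molecular-weight query lies outside the calibrated ladder span."""


class InsufficientDataError(BnpcpError, ValueError):
    """Not enough usable data points for a fit."""


class ConfigError(BnpcpError, ValueError):
    """A run configuration is invalid."""
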