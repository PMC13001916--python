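"""Exception types shared across the package."""


class PrefcalError(Exception):
    """Base class for package errors."""


class ConfigError(PrefcalError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class IntegrityError(PrefcalError, ValueError):
    """Stored artifact is internally inconsistent (shape/metadata mismatch)."""


class NumericError(PrefcalError, ArithmeticError):
    """Non-finite values encountered where finite numbers are required."""
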