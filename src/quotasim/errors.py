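"""Exception hierarchy.

``ValidationError`` (and its subclass ``ConfigError``) marks bad user input and
maps to CLI exit code 1; every other :class:`QuotasimError` maps to exit code 2.
"""


class QuotasimError(Exception):
    """Base class for all package errors."""


class ValidationError(QuotasimError, ValueError):
    """Invalid input data or parameter values."""


class ConfigError(ValidationError):
    """Malformed or schema-violating configuration document."""


class UndefinedStatisticError(QuotasimError, ZeroDivisionError):
    """A descriptive statistic is undefined (zero denominator)."""


class SamplingError(QuotasimError):
    """Cohort sampling cannot proceed (e.g. empty marginal category)."""


class CalibrationError(QuotasimError):
    """A calibration has no admissible solution."""


class ReportError(QuotasimError):
    """A report cannot be assembled from the supplied summary."""
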