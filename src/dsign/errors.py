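"""Exception hierarchy for dsign.

Every error raised by the library derives from :class:`DsignError` so callers
can catch the whole family with one clause.
"""


class DsignError(Exception):
    """Base class for all dsign errors."""


class FormatError(DsignError):
    """A file is structurally invalid (missing mandatory column, bad header)."""


class ParseError(DsignError):
    """A cell could not be parsed; the message cites the offending row."""


class SchemaError(DsignError):
    """Inputs do not match the expected schema (e.g. a biomarker column is absent)."""


class ValidationError(DsignError):
    """A domain object violates one of its invariants."""


class ConfigurationError(DsignError):
    """A configuration object is internally inconsistent or incomplete."""


class InsufficientDataError(DsignError):
    """Too few observations to perform the requested computation."""


class CalibrationError(DsignError):
    """Reference-population fitting failed (zero SD, singular covariance, ...)."""


class SizeError(DsignError):
    """A requested sample size exceeds what a source cohort can supply."""


class ScalingError(DsignError):
    """Per-SD scaling is impossible (zero or undefined standard deviation)."""


class FitError(DsignError):
    """A regression model failed to converge or produced unusable estimates."""
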