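"""Exception and warning types shared across the package."""


class CoxValError(Exception):
    """Base class for all coxval errors."""


class SchemaError(CoxValError, ValueError):
    """A coefficient-set document violates the schema.

    The message names the offending field.
    """


class MissingCovariateError(CoxValError, KeyError):
    """A required covariate is absent (and not flagged assume-zero)."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return self.args[0] if self.args else ""


class DomainError(CoxValError, ValueError):
    """A covariate value is outside the domain of its transform."""


class RangeError(CoxValError, ValueError):
    """A horizon or time lies outside the supported range."""


class FitError(CoxValError, RuntimeError):
    """A model fit could not be carried out on the given data."""


class ConvergenceWarning(UserWarning):
    """An iterative fit stopped without meeting its tolerance."""


class CalibrationWarning(UserWarning):
    """A calibration computation required merging or flooring a group."""


class DataWarning(UserWarning):
    """Input data triggered a non-fatal fallback (e.g. horizon clamping)."""
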