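"""Exception hierarchy shared across the package.

Every error raised by needleox derives from :class:`NeedleoxError`, so
callers (including the CLI) can catch one base class and map subclasses to
distinct exit codes.
"""


class NeedleoxError(Exception):
    """Base class for all needleox errors."""


class DomainError(NeedleoxError):
    """An input value is outside the mathematical domain of an operation
    (non-positive intensity, zero total hemoglobin, infeasible metric pair)."""


class RangeError(NeedleoxError):
    """A wavelength falls outside the tabulated spectral range."""


class ConditioningError(NeedleoxError):
    """The dual-wavelength extinction matrix is too close to singular to
    invert (e.g. both wavelengths at the isosbestic point)."""


class ConfigurationError(NeedleoxError):
    """A training or run parameter violates its documented constraints."""


class CompatibilityError(NeedleoxError):
    """Model and data disagree on shape or feature layout."""


class NotTrainedError(NeedleoxError):
    """A network was asked to predict before its weights were trained."""


class SelectionError(NeedleoxError):
    """Threshold selection found no grid point with a defined F-measure."""


class ParseError(NeedleoxError):
    """A data file could not be parsed; the message names the offending
    location."""


class NotFoundError(NeedleoxError):
    """A bracketing search (isosbestic crossing) found no sign change."""
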