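"""Exception types shared across the package.

All exceptions derive from :class:`EarlyVigorError` so callers can catch
package-specific failures with one clause; each also derives from the
closest builtin (``ValueError`` mostly) so untargeted code behaves sanely.
"""


class EarlyVigorError(Exception):
    """Base class for all errors raised by earlyvigor."""


class GridMismatchError(EarlyVigorError, ValueError):
    """Spectra that must share one wavelength grid do not."""


class BandRangeError(EarlyVigorError, ValueError):
    """A requested wavelength falls outside the spectrum's grid."""


class UndefinedIndexValue(EarlyVigorError, ArithmeticError):
    """An index formula hit a zero denominator (or zero band sum).

    Carries the name of the offending index in :attr:`index_name`.
    """

    def __init__(self, index_name: str, message: str | None = None):
        self.index_name = index_name
        super().__init__(message or f"undefined value for index {index_name!r}")


class DegenerateEndmemberError(EarlyVigorError, ValueError):
    """Endmember spectra are (near-)collinear; the unmixing fit is singular."""


class UndefinedCoverError(EarlyVigorError, ArithmeticError):
    """The two unmixing coefficients sum to zero; the cover ratio is undefined."""


class CalibrationError(EarlyVigorError, ValueError):
    """Threshold calibration received unusable reference data."""


class SampleSizeError(EarlyVigorError, ValueError):
    """Fewer paired observations than a correlation needs (n >= 3)."""


class UndefinedCorrelationError(EarlyVigorError, ArithmeticError):
    """One of the correlated variables has zero variance."""


class ConfigurationError(EarlyVigorError, ValueError):
    """Inconsistent configuration of a trial, design or endmember set."""
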