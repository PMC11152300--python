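"""Exception hierarchy.

Geometric degeneracies (poles, coincident points), statistical degeneracies
(zero resultant, zero dispersion) and I/O problems each get their own class
so callers can skip a species rather than abort a whole analysis.
"""


class MagbirdError(Exception):
    """Base class for all package errors."""


# --- geometry -------------------------------------------------------------

class InvalidCoordinateError(MagbirdError, ValueError):
    """Latitude/longitude outside its domain, or non-finite."""


class UndefinedBearingError(MagbirdError, ValueError):
    """Forward azimuth undefined: coincident points or departure from a pole."""


class TooShortTrackError(MagbirdError, ValueError):
    """Track has fewer points than the direction series requires."""


class PolarEscapeError(MagbirdError, RuntimeError):
    """Simulated track wandered too close to a pole; reduce steps or step size."""


# --- geomagnetic field ----------------------------------------------------

class CofFormatError(MagbirdError, ValueError):
    """Malformed Gauss-coefficient file; message names the offending line."""


class PoleSingularityError(MagbirdError, ValueError):
    """Field components requested exactly at a geographic pole."""


class UndefinedDeclinationError(MagbirdError, ValueError):
    """Horizontal field intensity is (numerically) zero."""


# --- circular statistics --------------------------------------------------

class UndefinedMeanError(MagbirdError, ValueError):
    """Circular mean undefined: the sample resultant vector has zero length."""


class DegenerateDispersionError(MagbirdError, ValueError):
    """A circular series has no dispersion about its mean direction."""


class TooFewObservationsError(MagbirdError, ValueError):
    """Sample smaller than the statistic's minimum size."""


class UnderdeterminedDesignError(MagbirdError, ValueError):
    """Regression design has more columns than observations."""


class DegenerateCovariateError(MagbirdError, ValueError):
    """Regression design matrix is rank deficient (e.g. constant covariate)."""


class UndefinedDirectionError(MagbirdError, ValueError):
    """Predicted direction undefined: both conditional components vanish."""


# --- pipeline I/O ---------------------------------------------------------

class SchemaError(MagbirdError, ValueError):
    """Input table is missing a mapped column or is otherwise malformed."""


class EmptyInputError(MagbirdError, ValueError):
    """Input file contains no usable rows."""


class EmptyResultError(MagbirdError, RuntimeError):
    """No species passed the analysis prerequisites."""
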