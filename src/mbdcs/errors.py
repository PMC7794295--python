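"""Exception hierarchy.

Everything raised on purpose derives from :class:`MbdcsError` so callers can
catch library errors without masking genuine bugs.
"""


class MbdcsError(Exception):
    """Base class for all errors raised by mbdcs."""


class ValidationError(MbdcsError, ValueError):
    """Invalid user input (shapes, signs, labels, grids ...)."""


class ParameterTableError(MbdcsError, KeyError):
    """Element symbol missing from the free-atom reference table."""


class SingularityError(MbdcsError):
    """Coincident atoms or a zero separation where 1/R is needed."""


class PolarizationCatastropheError(MbdcsError):
    """Non-positive eigenvalue of the coupled-oscillator matrix.

    Signals unphysically strong dipole coupling (atoms too close and/or
    too polarizable for the chosen damping)."""


class ConditioningError(MbdcsError):
    """A covariance matrix that should be positive (semi)definite is not."""


class QuadratureError(MbdcsError):
    """The Coulomb-kernel quadrature did not reach the requested tolerance."""


class GridCaptureError(MbdcsError):
    """Density grid too small to capture the Gaussian charge clouds."""
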