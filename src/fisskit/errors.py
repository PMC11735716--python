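"""Exception hierarchy.

Every error a caller may want to catch programmatically has its own class;
messages carry the offending identifiers (residues, chains, residuals) so
that batch drivers can log them per row.
"""


class FisskitError(Exception):
    """Base class for all package errors."""


class ParseError(FisskitError):
    """A coordinate file could not be parsed."""


class FormatError(FisskitError):
    """Unknown or unsupported coordinate format."""


class SelectionError(FisskitError):
    """An atom selection resolved to no atoms."""


class DegenerateGeometryError(FisskitError):
    """Too few or collinear points for a rigid superposition."""


class InsufficientPointsError(FisskitError):
    """Not enough residues/subunits to fit an axis."""


class NotACoiledCoilError(FisskitError):
    """Two helix axes diverge too much to define a common coiled-coil axis."""


class AtomMissingError(FisskitError):
    """A required atom (e.g. a beta-carbon) is absent."""


class NormalizationError(FisskitError):
    """An orientation distribution does not integrate to one."""


class InfeasibleDataError(FisskitError):
    """Measured intensities lie outside the range space of the forward model."""

    def __init__(self, message, residual=None):
        super().__init__(message)
        self.residual = residual


class NoCompatibleOrientationError(FisskitError):
    """No (beta, gamma) distribution reproduces the measured order parameters.

    This is a scientific result, not a numerical failure: it means the
    molecular fold used to relate the probes cannot be the fold adopted
    in the cell.
    """

    def __init__(self, message, residual=None):
        super().__init__(message)
        self.residual = residual


class FitError(FisskitError):
    """An optimiser failed to converge on all starts."""


class FetchError(FisskitError):
    """An accession could not be downloaded (e.g. offline)."""
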