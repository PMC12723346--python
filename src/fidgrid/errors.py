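"""Exception hierarchy shared across the package."""


class FidgridError(Exception):
    """Base class for all package errors."""


class CoordinateRangeError(FidgridError, ValueError):
    """A grid index exceeds the addressable range of the coding scheme."""


class SymbolError(FidgridError, ValueError):
    """A symbol vector contains values outside the scheme's alphabet."""


class InfeasibleSpacingError(FidgridError, ValueError):
    """The field of view cannot contain a code plus a positive quantized pitch."""


class CapacityError(FidgridError, ValueError):
    """The requested extent needs more sites than the scheme can address."""


class DegenerateGeometryError(FidgridError, ValueError):
    """Coincident or collinear control points make a transform fit singular."""


class InsufficientCorrespondenceError(FidgridError, ValueError):
    """Too few shared fiducials to estimate the requested transform."""


class SingularTransformError(FidgridError, ValueError):
    """The linear part of a mapping is not invertible."""
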