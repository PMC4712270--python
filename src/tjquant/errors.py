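"""Exception hierarchy shared across modules."""


class TJQuantError(Exception):
    """Base class for all package errors."""


class UnsupportedFormatError(TJQuantError):
    """Raster layout the reader does not handle (channel count, stacks)."""


class DegenerateInputError(TJQuantError):
    """Input on which the requested operation is mathematically undefined,
    e.g. Otsu thresholding of a constant image."""


class ParameterError(TJQuantError, ValueError):
    """Parameter outside its documented domain."""


class PlacementInfeasibleError(TJQuantError):
    """Not enough eligible positions to place the requested ROIs.

    Attributes
    ----------
    n_requested, n_possible : int
        How many rectangles were asked for and how many actually fit.
    """

    def __init__(self, message: str, n_requested: int, n_possible: int):
        super().__init__(message)
        self.n_requested = n_requested
        self.n_possible = n_possible


class CapacityError(TJQuantError):
    """Synthetic object placement exhausted its attempt budget.

    Attributes
    ----------
    n_requested, n_placed : int
    """

    def __init__(self, message: str, n_requested: int, n_placed: int):
        super().__init__(message)
        self.n_requested = n_requested
        self.n_placed = n_placed


class ValidationError(TJQuantError):
    """Tabular record failed vocabulary or uniqueness validation."""


class NormalizationError(TJQuantError):
    """Percent-of-control normalization is impossible (zero/absent control)."""
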