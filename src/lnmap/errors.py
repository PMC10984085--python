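"""Exception hierarchy shared across the package."""


class LnmapError(Exception):
    """Base class for all package-specific errors."""


class GridError(LnmapError):
    """Volumes on incompatible grids, or a grid with an invalid affine."""


class DimensionalityError(LnmapError):
    """A volume with the wrong number of dimensions for the requested loader."""


class DegenerateDataError(LnmapError):
    """Zero-variance, constant, or otherwise undefined statistical input."""


class EmptySeedError(LnmapError):
    """A seed region with no usable voxels."""


class NotEstimableError(LnmapError):
    """A quantity that cannot be estimated from the data provided."""
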