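"""Exception hierarchy for regioncontrast.

Every error raised by the package derives from :class:`RegionContrastError`
so that batch drivers can catch one base class per failed case.
"""


class RegionContrastError(Exception):
    """Base class for all regioncontrast errors."""


class GeometryError(RegionContrastError):
    """Volume and mask do not live on the same voxel grid."""


class MaskEncodingError(RegionContrastError):
    """A mask file encodes more than two distinct values."""


class EmptyRegionError(RegionContrastError):
    """An operation that requires a nonempty voxel region received none."""


class NoBoundaryError(RegionContrastError):
    """No non-tumor voxels are available to form a boundary shell."""


class DegenerateHistogramError(RegionContrastError):
    """All intensities identical: a two-class threshold is undefined."""


class UndefinedContrastError(RegionContrastError):
    """Michelson contrast denominator is zero."""


class NoiseEstimationError(RegionContrastError):
    """No noise standard deviation supplied and none estimable."""


class UndefinedCorrelationError(RegionContrastError):
    """Pearson correlation undefined (zero variance in an input)."""


class PhantomSpecError(RegionContrastError):
    """A synthetic phantom specification is geometrically invalid."""


class ConfigError(RegionContrastError):
    """A pipeline run configuration is inconsistent or incomplete."""
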