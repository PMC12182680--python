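"""Exception hierarchy shared across the pipeline stages."""


class ForestCarbonError(Exception):
    """Base class for all package errors."""


class ConfigError(ForestCarbonError):
    """Invalid configuration (bad counts, fractions outside [0, 1], missing fields)."""


class ShapeError(ForestCarbonError):
    """Raster grids that are required to align do not."""


class DataError(ForestCarbonError):
    """Input values violate a declared range or are degenerate (e.g. constant column)."""


class TypologyError(ForestCarbonError):
    """A categorical code is not part of the configured forest typology."""


class FitError(ForestCarbonError):
    """A model fit failed or the data are degenerate for fitting."""


class SelectionError(ForestCarbonError):
    """No candidate model survived for selection."""


class ExtrapolationError(ForestCarbonError):
    """A query point lies outside the tabulated range of a curve."""


class CoverageError(ForestCarbonError):
    """A trajectory does not cover all years of a requested period."""
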