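"""Exception hierarchy shared across the pipeline."""


class AdmkitError(Exception):
    """Base class for all package-specific errors."""


class AlignmentError(AdmkitError):
    """Two rasters do not share dimensions, origin, or cell size."""


class SchemaError(AdmkitError):
    """A tabular input is missing required columns."""


class ParameterError(AdmkitError, ValueError):
    """A parameter value is outside its admissible range."""


class FitError(AdmkitError):
    """A suitability engine cannot be fitted (too few presences, ...)."""


class NotFittedError(AdmkitError):
    """predict/transform called before fit."""


class SamplingError(AdmkitError):
    """Too few eligible cells to draw the requested sample."""


class SelectionError(AdmkitError):
    """No admissible candidate in a threshold-selection scan."""


class DegenerateNicheError(AdmkitError):
    """A planted virtual niche leaves too few usable cells."""


class StratificationError(AdmkitError):
    """Too few habitat-eligible cells to place the requested survey sites."""


class ScaleError(AdmkitError):
    """A suitability raster violates its declared score scale."""
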