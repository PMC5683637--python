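"""Exception hierarchy shared across the package."""


class VirtualSDMError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(VirtualSDMError, ValueError):
    """An argument violates a documented precondition."""


class GridError(VirtualSDMError, ValueError):
    """Two rasters that must share a grid do not."""


class ExtentError(VirtualSDMError, ValueError):
    """A point or target grid falls outside the source raster extent."""


class DegenerateLayerError(VirtualSDMError, ValueError):
    """A raster layer is constant where variation is required."""


class DegenerateDataError(VirtualSDMError, ValueError):
    """Input data cannot support the requested fit (e.g. one class only)."""


class UndefinedMetricError(VirtualSDMError, ValueError):
    """The requested statistic is undefined on this input."""


class SamplingError(VirtualSDMError, RuntimeError):
    """Occurrence sampling cannot satisfy the request (empty region, stall)."""
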