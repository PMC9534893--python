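"""Exception hierarchy for gabamorph.

Every error raised on a user-facing code path derives from
:class:`GabamorphError` so callers can catch the package's failures
with a single ``except`` clause.
"""


class GabamorphError(Exception):
    """Base class for all gabamorph errors."""


class DesignError(GabamorphError):
    """Invalid factorial experiment design (empty or duplicated levels)."""


class ParameterError(GabamorphError):
    """Invalid generator, calibration, or configuration parameters."""


class RenderError(GabamorphError):
    """A leaf shape does not fit on the requested canvas."""


class NoLeafError(GabamorphError):
    """Segmentation or cleaning produced no usable foreground object."""


class GeometryError(GabamorphError):
    """Degenerate mask geometry (too few pixels to locate an axis)."""


class EncodingError(GabamorphError):
    """Unknown categorical level encountered during encoding/decoding."""


class DegenerateColumnError(ParameterError):
    """A column with zero variance cannot be z-scored."""


class TrainingError(GabamorphError):
    """Model training diverged or could not be completed."""


class MetricError(GabamorphError):
    """A statistic is undefined for the given inputs (e.g. constant series)."""


class SelectionError(GabamorphError):
    """Roulette-wheel selection received invalid scores."""


class OptimizationError(GabamorphError):
    """NSGA-II failed, e.g. non-finite objectives from the surrogate."""


class PipelineError(GabamorphError):
    """A pipeline stage was invoked before its upstream artifacts exist."""
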