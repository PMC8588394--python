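"""Package exception hierarchy."""


class GlybenchError(Exception):
    """Base class for all package errors."""


class UnfillableSeriesError(GlybenchError):
    """Fewer than four glucose anchor points: no cubic spline can be fitted."""


class ExtrapolationError(GlybenchError):
    """A leading or trailing glucose gap would require spline extrapolation."""


class InvalidStatsError(GlybenchError):
    """Feature scaling statistics with max < min."""


class InvalidPredictionError(GlybenchError):
    """A model emitted a non-finite prediction."""


class AlignmentError(GlybenchError):
    """Arrays that must be aligned (members, loss matrices) disagree in shape."""


class OverMaskingError(GlybenchError):
    """A gap specification would remove more than half of the series."""


class UndefinedMetricError(GlybenchError):
    """A metric is undefined for the given prediction set (n < 2 or zero variance)."""
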