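"""Exception hierarchy.

Validation problems (bad parameters, malformed tables) and numerical problems
(solver blow-ups) are kept distinct so the CLI can map them to different exit
codes (2 and 3 respectively).
"""


class AirwayError(Exception):
    """Base class for all package errors."""


class ParameterError(AirwayError, ValueError):
    """A parameter or input value violates its documented precondition."""


class DegenerateDataError(ParameterError):
    """Input data is structurally valid but statistically unusable
    (e.g. zero variance, duplicate patient ids, missing AHI)."""


class SolverError(AirwayError):
    """The flow solver cannot run on the supplied geometry."""


class NumericalError(AirwayError):
    """A computed field contains NaN/Inf; message carries time and station indices."""


class UndefinedMetricError(AirwayError):
    """A metric is undefined for the sampled state (e.g. Cp* at zero velocity)."""
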