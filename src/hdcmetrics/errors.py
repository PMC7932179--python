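"""Exception hierarchy for hdcmetrics.

Every module raises subclasses of :class:`HdcMetricsError` so callers can
distinguish bad input data (parse / configuration errors) from degenerate
geometry or segmentation produced by otherwise well-formed data.
"""


class HdcMetricsError(Exception):
    """Base class for all package-specific errors."""


class InvalidPoseError(HdcMetricsError):
    """Sensor pose is invalid (e.g. non-unit orientation quaternion)."""


class DegenerateGeometryError(HdcMetricsError):
    """Point set too degenerate for the requested 3D construction."""


class AmbiguousAxisError(DegenerateGeometryError):
    """Fistula quadrilateral has no well-defined long axis."""


class ConfigurationError(HdcMetricsError):
    """Required configuration or annotation fields are missing/invalid."""


class OutOfRangeError(HdcMetricsError):
    """Event times fall outside the recorded trajectory span."""


class DegenerateSegmentationError(HdcMetricsError):
    """A phase contains too few samples to be analyzed."""


class DegeneratePhaseError(HdcMetricsError):
    """A phase quantity is undefined (zero duration, coincident samples)."""


class UndefinedLateralAngleError(DegeneratePhaseError):
    """In-plane displacement is zero; the lateral angle has no direction."""


class PairingError(HdcMetricsError):
    """Phase-1/phase-3 rows cannot be paired trial-by-trial."""


class CollinearityError(HdcMetricsError):
    """Regression design matrix is rank deficient."""

    def __init__(self, message, columns=None):
        super().__init__(message)
        self.columns = list(columns or [])


class InfeasibleScenarioError(HdcMetricsError):
    """Synthetic scenario cannot be realized with the given geometry."""


class TrajectoryParseError(HdcMetricsError):
    """Malformed trajectory/events/geometry file."""

    def __init__(self, message, row=None):
        super().__init__(message)
        self.row = row
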