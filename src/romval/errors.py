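"""Exception hierarchy for the ROM validation pipeline."""


class RomValError(Exception):
    """Base class for all romval errors."""


class ValidationError(RomValError, ValueError):
    """Invalid argument or parameter value."""


class SchemaError(RomValError):
    """Input table does not match the expected column schema."""


class TrajectoryParseError(RomValError):
    """A cell in a trajectory table could not be parsed."""


class GeometryError(RomValError):
    """Degenerate geometry (collinear points, coincident midpoints, ...)."""


class DataError(RomValError):
    """Data content insufficient for the requested operation."""


class AlignmentError(RomValError):
    """Temporal alignment could not be established."""


class SegmentationError(RomValError):
    """No repetitions could be segmented."""


class MetricUndefinedError(RomValError):
    """An agreement metric is undefined for the given inputs."""


class ConfigError(RomValError):
    """Unknown or inconsistent configuration."""
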