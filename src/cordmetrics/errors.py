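"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: ConfigError -> 2, DataError -> 3.
"""


class CordMetricsError(Exception):
    """Base class for all package errors."""


class ParameterError(CordMetricsError, ValueError):
    """A parameter is outside its documented range or inconsistent."""


class CapacityError(CordMetricsError):
    """A generator could not satisfy a placement/size request."""


class GeometryError(CordMetricsError, ValueError):
    """Degenerate geometry (coincident points, zero-length vectors)."""


class RuleError(CordMetricsError, ValueError):
    """A classification rule does not cover its inputs."""


class ConfigError(CordMetricsError):
    """Invalid pipeline configuration; carries the offending field name."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"config field '{field}': {message}")


class DataError(CordMetricsError):
    """Missing or malformed input data."""
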