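"""Exception hierarchy shared across the package."""


class AccessTFError(Exception):
    """Base class for all package errors."""


class ParseError(AccessTFError):
    """A file could not be parsed; message names the offending line."""


class CoordinateError(AccessTFError):
    """A genomic interval violates the 0-based half-open contract."""


class SchemaError(AccessTFError):
    """A tabular input is missing required columns or has a bad header."""


class ConfigurationError(AccessTFError):
    """A scenario or run configuration has invalid parameter values."""


class FitError(AccessTFError):
    """Model fitting failed or was handed degenerate inputs."""


class UndefinedMetricError(AccessTFError):
    """A metric is undefined for the given labels (e.g. one class only)."""
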