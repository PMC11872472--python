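"""Exception hierarchy shared across the package."""


class QtShapeError(Exception):
    """Base class for package-specific errors."""


class ParseError(QtShapeError):
    """A file could not be parsed; message names the offending line."""


class DegenerateSeriesError(QtShapeError):
    """A series with zero energy / zero variance where variation is required."""


class ConfigurationError(QtShapeError):
    """Inconsistent or incomplete configuration (e.g. missing fiducial rows)."""


class PipelineError(QtShapeError):
    """A pipeline stage was invoked without its prerequisites."""
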