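"""Exception hierarchy used across the package."""


class DyscueError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(DyscueError, ValueError):
    """An argument is outside the domain on which the operation is defined."""


class InvalidVarianceError(InvalidInputError):
    """A requested (mean, sd) pair is infeasible for the target distribution."""


class UndefinedEstimateError(DyscueError, ValueError):
    """The point estimate itself is undefined (e.g. zero reference events)."""


class CalibrationError(DyscueError, ValueError):
    """Calibration targets are inconsistent (e.g. increasing prevalence)."""


class ConfigError(DyscueError, ValueError):
    """A configuration file failed schema or cross-field validation."""
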